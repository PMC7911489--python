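"""Classify individual reads as 3' trimmed/tailed variants of a mature miRNA.

Builds one mature reference and classifies a handful of reads against it,
printing the inferred decomposition.  Trim is how many 3' bases of the
mature are missing; tail is the nontemplated 3' addition; both are capped
at 7 positions and the 5' end must match exactly.
"""

from trimtail import MatureRef, classify_read

mature = MatureRef(
    ref_id="miR173", sequence="TTCGCTTGCAGAGAGAAATCAC", kind="guide"
)

reads = [
    mature.sequence,                  # unaltered
    mature.sequence[:-3],             # trimmed by 3
    mature.sequence + "TT",           # uridylated (TT tail)
    mature.sequence[:-2] + "TTTT",    # trimmed by 2, then tailed by 4
    mature.sequence[:-1] + "G",       # trimmed by 1, tailed by 1
    "ACGTACGTACGTACGTACGT",           # unrelated sequence
]

for seq in reads:
    rec = classify_read(seq, [mature])
    print(
        f"{seq:<28} -> {rec.category:<14} trim={rec.trim_len} "
        f"tail={rec.tail_seq or '-'}"
    )

# Each read counts once regardless of degree: these records would add 1 to
# the trimming and/or tailing numerator of miR173's indexes.
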