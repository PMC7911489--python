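"""Per-locus small RNA coverage in reads-per-million.

Simulates one library, then profiles read depth over the first MIR locus
(guide + star) before genome filtering, so locus-mapping reads appear.
"""

from trimtail import SimConfig, Window, locus_coverage, simulate_library, simulate_reference

config = SimConfig(
    seed=3, n_mirnas=4, genome_len=5_000, n_background_reads=300,
    reads_per_mirna=400.0,
)
reference = simulate_reference(config)
table, _ = simulate_library(config, reference, "wt", "rep1")

guide = reference.loci[0]
star = reference.loci[1]
window = Window.from_gff(
    guide.chrom, max(1, guide.start - 10), star.end + 10, guide.strand
)
profile = locus_coverage(table, window, reference.genome, locus_id=guide.locus_id)

print(f"window {window.chrom}:{window.start}-{window.end} ({guide.locus_id})")
print(f"library total {table.total} reads; peak depth {profile.depth.max():.1f} RPM")
df = profile.to_frame()
covered = df[df["rpm"] > 0]
print(f"covered positions: {len(covered)} / {len(df)}")
print(covered.head(5).to_string(index=False))
# Depth is (reads covering the position) x 1e6 / library size; the guide
# footprint should dominate, with a second block over the star locus.
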