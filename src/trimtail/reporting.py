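"""Plot-ready exports: per-locus normalized coverage and ID boxplot data.

Coverage profiles answer "what does the small RNA population look like over
a MIR locus" — they are computed from the count table *before* the
masked-genome filter so that locus-mapping genomic reads (e.g. the miRNA*)
appear.  Depth is reads-per-million of the total deduplicated library.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from ._seq import revcomp
from .intake import SeqCountTable
from .stats import TestResult, significance_stars


@dataclass(frozen=True)
class Window:
    """Genomic window, stored 1-based inclusive."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start < 1 or self.end < self.start:
            raise ValueError(f"bad window {self.chrom}:{self.start}-{self.end}")

    @classmethod
    def from_gff(cls, chrom: str, start: int, end: int, strand: str = "+") -> "Window":
        """1-based inclusive coordinates (GFF style)."""
        return cls(chrom, start, end, strand)

    @classmethod
    def from_bed(cls, chrom: str, start: int, end: int, strand: str = "+") -> "Window":
        """0-based half-open coordinates (BED style)."""
        return cls(chrom, start + 1, end, strand)

    def __len__(self) -> int:
        return self.end - self.start + 1


@dataclass
class CoverageProfile:
    locus_id: str
    window: Window
    depth: np.ndarray  # reads-per-million, one value per window position
    sample_id: str

    def to_frame(self) -> pd.DataFrame:
        positions = np.arange(self.window.start, self.window.end + 1)
        return pd.DataFrame(
            {
                "locus_id": self.locus_id,
                "sample_id": self.sample_id,
                "chrom": self.window.chrom,
                "position": positions,
                "rpm": self.depth,
            }
        )


def locus_coverage(
    table: SeqCountTable,
    window: Window,
    genome: dict[str, str],
    locus_id: str = "",
) -> CoverageProfile:
    """Reads-per-million depth of a library over one genomic window.

    Each unique read (or its reverse complement) is placed 5'-anchored at
    every offset of the window where it matches exactly; its count is added
    to every position it covers.  depth[i] = covering reads x 1e6 / library
    total.  A window with no placed reads gives an all-zero profile.
    """
    if table.total < 1:
        raise ValueError("library_total must be >= 1 to normalize coverage")
    if window.chrom not in genome:
        raise ValueError(f"chromosome {window.chrom!r} not in genome")
    text = genome[window.chrom][window.start - 1 : window.end]
    if len(text) != len(window):
        raise ValueError(
            f"window {window.chrom}:{window.start}-{window.end} exceeds chromosome"
        )
    depth = np.zeros(len(window), dtype=float)
    for seq, count in table.counts.items():
        rc = revcomp(seq)
        queries = (seq,) if rc == seq else (seq, rc)  # palindrome: place once
        for query in queries:
            offset = text.find(query)
            while offset != -1:
                depth[offset : offset + len(query)] += count
                offset = text.find(query, offset + 1)
    depth *= 1e6 / table.total
    return CoverageProfile(
        locus_id=locus_id, window=window, depth=depth, sample_id=table.sample_id
    )


def export_id_boxplot_data(
    ids_by_line: dict[str, pd.DataFrame],
    results: list[TestResult] | None = None,
    tsv_path: str | Path | None = None,
    figure_path: str | Path | None = None,
) -> pd.DataFrame:
    """Long-format ID table for boxplots, with per-line significance stars.

    ``ids_by_line`` maps line_id -> the index-difference table of that line
    (columns ref_id, modification, id_value, ...).  Stars follow the figure
    convention * / ** / *** at q < 0.05 / 0.01 / 0.001 from the FDR-corrected
    test results.  Optionally writes a TSV and a boxplot figure (SVG/PNG by
    extension).
    """
    if not ids_by_line:
        raise ValueError("at least one line's IDs required")
    star_of: dict[tuple[str, str], str] = {}
    for res in results or []:
        star_of[(res.line_id, res.modification)] = significance_stars(res.q_value)
    frames = []
    for line_id, ids in ids_by_line.items():
        df = ids[["ref_id", "modification", "id_value"]].copy()
        df.insert(0, "line_id", line_id)
        df["stars"] = [
            star_of.get((line_id, m), "") for m in df["modification"]
        ]
        frames.append(df)
    out = pd.concat(frames, ignore_index=True)
    if tsv_path is not None:
        out.to_csv(tsv_path, sep="\t", index=False)
    if figure_path is not None:
        _draw_id_boxplot(out, figure_path)
    return out


def _draw_id_boxplot(data: pd.DataFrame, figure_path: str | Path) -> None:
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    modifications = sorted(data["modification"].unique())
    lines = list(dict.fromkeys(data["line_id"]))
    fig, axes = plt.subplots(
        1, len(modifications), figsize=(2.0 + 1.2 * len(lines) * len(modifications), 4.0),
        squeeze=False,
    )
    for ax, modification in zip(axes[0], modifications):
        sub = data[data["modification"] == modification]
        groups = [sub[sub["line_id"] == line]["id_value"].to_numpy() for line in lines]
        ax.boxplot(groups, tick_labels=lines)
        ax.axhline(0.0, color="grey", linewidth=0.8, linestyle="--")
        ax.set_title(modification)
        ax.set_ylabel("index difference (ID)")
        for i, line in enumerate(lines, start=1):
            stars = sub[sub["line_id"] == line]["stars"]
            label = stars.iloc[0] if len(stars) else ""
            if label:
                ax.annotate(
                    label,
                    xy=(i, sub["id_value"].max()),
                    ha="center",
                    va="bottom",
                    fontsize=12,
                )
        ax.tick_params(axis="x", rotation=45)
    fig.tight_layout()
    fig.savefig(figure_path)
    plt.close(fig)


def write_coverage_tsv(profiles: list[CoverageProfile], path: str | Path) -> None:
    pd.concat([p.to_frame() for p in profiles], ignore_index=True).to_csv(
        path, sep="\t", index=False
    )
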