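"""End-to-end orchestration over a sample sheet.

One invocation is one comparison set: every line in the sheet is processed
against its designated reference line and all paired t-tests share a single
FDR correction per modification.  All intermediate tables are written as
TSV and a JSON manifest records parameters, per-replicate read-count
conservation checks, and the excluded cross-mapping references.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import pandas as pd

from . import __version__
from .classify import AMBIGUOUS, UNCLASSIFIED, classify_table, write_records_tsv
from .intake import SeqCountTable, dedupe_reads, filter_genome_matching
from .refs import (
    MaskedGenome,
    find_cross_mapping,
    load_mature_refs,
    mask_genome,
    read_genome,
    read_mirna_loci,
    write_masked_fasta,
)
from .reporting import export_id_boxplot_data
from .stats import (
    MODIFICATIONS,
    compute_indexes,
    fdr_correct,
    index_differences,
    mean_indexes,
    paired_test,
    results_to_frame,
)

logger = logging.getLogger(__name__)

SHEET_COLUMNS = ["sample_id", "line_id", "replicate_id", "fastq_path", "reference_line_id"]


@dataclass
class PipelineOptions:
    max_trim: int = 7
    max_tail: int = 7
    min_pairs: int = 3
    min_total: int = 1
    min_len: int = 18
    max_len: int = 32
    write_masked_genome: bool = False
    make_figure: bool = True


def read_samplesheet(path: str | Path) -> pd.DataFrame:
    sheet = pd.read_csv(path, sep="\t", dtype=str)
    missing = set(SHEET_COLUMNS) - set(sheet.columns)
    if missing:
        raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
    return validate_samplesheet(sheet)


def validate_samplesheet(sheet: pd.DataFrame) -> pd.DataFrame:
    lines = set(sheet["line_id"])
    bad_refs = set(sheet["reference_line_id"]) - lines
    if bad_refs:
        raise ValueError(
            f"reference_line_id values never appear as line_id: {sorted(bad_refs)}"
        )
    if sheet["sample_id"].duplicated().any():
        raise ValueError("sample_id values must be unique")
    return sheet


def run_pipeline(
    samplesheet: str | Path | pd.DataFrame,
    genome: str | Path | dict[str, str],
    annotation: str | Path,
    outdir: str | Path,
    options: PipelineOptions | None = None,
    mature_fasta: str | Path | None = None,
    tables: dict[str, SeqCountTable] | None = None,
) -> dict:
    """Run reference prep, intake, classification, statistics and reporting.

    ``tables`` lets callers inject pre-deduplicated count tables keyed by
    sample_id (the simulator produces these); otherwise each sample's
    ``fastq_path`` is read.  Returns the run manifest (also written as
    manifest.json).
    """
    options = options or PipelineOptions()
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    sheet = (
        read_samplesheet(samplesheet)
        if not isinstance(samplesheet, pd.DataFrame)
        else validate_samplesheet(samplesheet)
    )

    # --- reference preparation -------------------------------------------
    if not isinstance(genome, dict):
        genome = read_genome(genome)
    loci = read_mirna_loci(annotation)
    refs = load_mature_refs(genome, annotation, mature_fasta=mature_fasta)
    masked = mask_genome(genome, loci)
    excluded, retained_refs, exclusion_report = find_cross_mapping(refs, masked)
    exclusion_report.to_csv(outdir / "excluded_crossmapping.tsv", sep="\t", index=False)
    if options.write_masked_genome:
        write_masked_fasta(masked, outdir / "masked_genome.fa")
    if not retained_refs:
        raise RuntimeError("all references cross-map; nothing to analyze")

    # --- per-sample intake, classification, indexes ----------------------
    index_tables: list[pd.DataFrame] = []
    conservation = []
    for row in sheet.itertuples(index=False):
        if tables is not None and row.sample_id in tables:
            table = tables[row.sample_id]
        else:
            table = dedupe_reads(
                row.fastq_path,
                sample_id=row.line_id,
                replicate_id=row.replicate_id,
                min_len=options.min_len,
                max_len=options.max_len,
            )
        retained, removed = filter_genome_matching(table, masked)
        records = classify_table(
            retained, retained_refs, max_trim=options.max_trim, max_tail=options.max_tail
        )
        write_records_tsv(records, outdir / f"classified_{row.sample_id}.tsv")
        n_ambiguous = sum(r.count for r in records if r.category == AMBIGUOUS)
        n_unclassified = sum(r.count for r in records if r.category == UNCLASSIFIED)
        n_classified = sum(r.count for r in records if r.ref_id is not None)
        check = {
            "sample_id": row.sample_id,
            "kept_reads": table.total,
            "genome_removed": removed.total,
            "ambiguous": n_ambiguous,
            "unclassified": n_unclassified,
            "classified": n_classified,
        }
        check["conserved"] = (
            check["kept_reads"]
            == check["genome_removed"]
            + check["ambiguous"]
            + check["unclassified"]
            + check["classified"]
        )
        if not check["conserved"]:
            raise RuntimeError(f"read-count conservation violated for {row.sample_id}")
        conservation.append(check)
        idx = compute_indexes(
            records, sample_id=row.line_id, replicate_id=row.replicate_id, refs=retained_refs
        )
        if options.min_total > 1:
            idx = idx[idx["total"] >= options.min_total].reset_index(drop=True)
        index_tables.append(idx)

    all_indexes = pd.concat(index_tables, ignore_index=True)
    all_indexes.to_csv(outdir / "indexes.tsv", sep="\t", index=False)

    # --- line means, index differences, paired tests ---------------------
    means = {
        line_id: mean_indexes(all_indexes[all_indexes["sample_id"] == line_id])
        for line_id in sheet["line_id"].unique()
    }
    contrasts = (
        sheet[sheet["line_id"] != sheet["reference_line_id"]][
            ["line_id", "reference_line_id"]
        ]
        .drop_duplicates()
        .itertuples(index=False)
    )
    results = []
    ids_by_line: dict[str, pd.DataFrame] = {}
    for contrast in contrasts:
        ids = index_differences(means[contrast.line_id], means[contrast.reference_line_id])
        ids.insert(0, "reference_line_id", contrast.reference_line_id)
        ids.insert(0, "line_id", contrast.line_id)
        ids_by_line[contrast.line_id] = ids
        for modification in MODIFICATIONS:
            results.append(
                paired_test(
                    means[contrast.line_id],
                    means[contrast.reference_line_id],
                    modification,
                    line_id=contrast.line_id,
                    reference_line_id=contrast.reference_line_id,
                    min_pairs=options.min_pairs,
                )
            )
    results = fdr_correct(results)
    results_frame = results_to_frame(results)
    results_frame.to_csv(outdir / "tests.tsv", sep="\t", index=False)
    if ids_by_line:
        pd.concat(ids_by_line.values(), ignore_index=True).to_csv(
            outdir / "index_differences.tsv", sep="\t", index=False
        )
        export_id_boxplot_data(
            ids_by_line,
            results,
            tsv_path=outdir / "id_boxplot_data.tsv",
            figure_path=(outdir / "id_boxplot.svg") if options.make_figure else None,
        )

    manifest = {
        "trimtail_version": __version__,
        "options": asdict(options),
        "n_references": len(refs),
        "n_excluded_crossmapping": len(excluded),
        "n_retained_references": len(retained_refs),
        "samples": conservation,
        "tests": results_frame.to_dict(orient="records"),
    }
    with open(outdir / "manifest.json", "w") as out:
        json.dump(manifest, out, indent=2, default=str)
    logger.info("pipeline complete: %d samples, %d tests", len(conservation), len(results))
    return manifest
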