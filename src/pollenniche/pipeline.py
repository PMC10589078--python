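"""End-to-end orchestration: clean → classify → profile.

:func:`run_pipeline` sequences the metabarcoding stages over a manifest of
per-sample per-locus read files, writing diff-able TSVs plus a machine-
readable run summary in which every threshold that shaped the outputs is
echoed (no silent defaults).
"""

from __future__ import annotations

import json
import logging
from pathlib import Path
from typing import AbstractSet, Mapping, Optional

import pandas as pd

from . import __version__
from .classify import MergedRead, classify_sample
from .io import Manifest, read_manifest, read_sequences, write_fasta, write_table
from .profiles import (
    DEFAULT_EXCLUDED_GENERA,
    DEFAULT_HOST_FAMILIES,
    dual_locus_profile,
    genus_richness,
    host_plant_proportion,
)
from .refdb import BarcodeRecord, ContrastDatabase, ContrastRecord, clean_database
from .taxonomy import Lineage, read_lineage_table

logger = logging.getLogger(__name__)


class PipelineError(RuntimeError):
    """A pipeline stage failed; the message names the stage."""


def load_barcodes(
    fasta_path, lineages: Mapping[str, Lineage], locus: str
) -> list[BarcodeRecord]:
    records = []
    for rec_id, seq in read_sequences(fasta_path):
        if rec_id not in lineages:
            raise PipelineError(
                f"references: barcode '{rec_id}' has no lineage table entry"
            )
        records.append(BarcodeRecord(rec_id, locus, seq, lineages[rec_id]))
    return records


def load_contrast(fasta_path, lineage_path, kind: str) -> ContrastDatabase:
    lineages = read_lineage_table(lineage_path) if lineage_path else {}
    return ContrastDatabase(
        kind,
        tuple(
            ContrastRecord(rec_id, seq, lineages.get(rec_id))
            for rec_id, seq in read_sequences(fasta_path)
        ),
    )


def run_pipeline(
    manifest,
    references: Mapping[str, object],
    lineage_path,
    out_dir,
    plant_fasta=None,
    plant_lineages=None,
    nonplant_fasta=None,
    nonplant_lineages=None,
    min_identity: float = 0.95,
    min_coverage: float = 0.80,
    max_accepts: int = 100,
    both_strands: bool = True,
    qc_threshold: float = 0.05,
    min_prop: float = 0.01,
    exclude: AbstractSet[str] = DEFAULT_EXCLUDED_GENERA,
    host_families: AbstractSet[str] = DEFAULT_HOST_FAMILIES,
    renormalize: bool = False,
    relaxed_min_identity: float = 0.0,
) -> dict:
    """Run cleaning (optional), classification and profiling over a manifest.

    ``manifest`` is a path or a :class:`pollenniche.io.Manifest`;
    ``references`` maps locus → barcode FASTA path; ``lineage_path`` points at
    the 8-column lineage TSV covering all barcode ids. If both contrast
    databases are supplied the reference set is decontaminated first.
    Returns the run summary (also written to ``run_summary.json``).
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    if not isinstance(manifest, Manifest):
        manifest = read_manifest(manifest)
    if not manifest.entries:
        raise PipelineError("manifest: no samples")

    lineages = read_lineage_table(lineage_path)
    dbs = {
        locus: load_barcodes(path, lineages, locus)
        for locus, path in references.items()
    }

    cleaning_counts: Optional[dict] = None
    if plant_fasta is not None and nonplant_fasta is not None:
        plant = load_contrast(plant_fasta, plant_lineages, "plant")
        nonplant = load_contrast(nonplant_fasta, nonplant_lineages, "non_plant")
        decisions = []
        for locus in sorted(dbs):
            retained, report = clean_database(
                dbs[locus], nonplant, plant, relaxed_min_identity
            )
            dbs[locus] = retained
            decisions.extend(report.decisions)
            write_fasta(
                ((b.id, b.sequence) for b in retained),
                out_dir / f"cleaned_{locus}.fasta",
            )
            if not retained:
                raise PipelineError(f"clean-db: no {locus} barcodes survived cleaning")
        write_table(
            pd.DataFrame(
                dict(
                    barcode_id=[d.barcode_id for d in decisions],
                    locus=[d.locus for d in decisions],
                    status=[d.status for d in decisions],
                    rule=[d.rule for d in decisions],
                    evidence=[";".join(d.evidence) for d in decisions],
                )
            ),
            out_dir / "cleaning_decisions.tsv",
        )
        cleaning_counts = {
            "per_rule": pd.Series([d.rule for d in decisions]).value_counts().to_dict(),
            "removed": sum(d.status == "mislabeled" for d in decisions),
            "total": len(decisions),
        }

    count_rows = []
    totals_rows = []
    profile_rows = []
    summary_rows = []
    genus_lineages: dict[str, Lineage] = {}
    for lin in lineages.values():
        if lin.genus is not None:
            genus_lineages.setdefault(lin.genus, lin)

    for sample_id in manifest.sample_ids:
        reads: list[MergedRead] = []
        for entry in manifest.entries:
            if entry.sample_id != sample_id:
                continue
            if entry.locus not in dbs:
                raise PipelineError(
                    f"classify: no reference database for locus '{entry.locus}'"
                )
            for read_id, seq in read_sequences(entry.path):
                reads.append(MergedRead(read_id, sample_id, entry.locus, seq))
        counts = classify_sample(
            reads, dbs, lineages,
            min_identity=min_identity, min_coverage=min_coverage,
            max_accepts=max_accepts, both_strands=both_strands,
            sample_id=sample_id,
        )
        for locus in sorted(counts.counts):
            for genus in sorted(counts.counts[locus]):
                count_rows.append(
                    dict(sample_id=sample_id, locus=locus, genus=genus,
                         count=counts.counts[locus][genus])
                )
            totals_rows.append(
                dict(sample_id=sample_id, locus=locus,
                     processed=counts.processed[locus],
                     matched=counts.matched[locus],
                     unmatched=counts.processed[locus] - counts.matched[locus])
            )
        profile = dual_locus_profile(
            counts, exclude=exclude, min_prop=min_prop, qc_threshold=qc_threshold
        )
        reported = profile.retained_proportions(renormalize=renormalize)
        for genus in sorted(profile.proportions):
            profile_rows.append(
                dict(sample_id=sample_id, genus=genus,
                     proportion=profile.proportions[genus],
                     reported_proportion=reported.get(genus),
                     retained=genus in profile.retained)
            )
        summary_rows.append(
            dict(sample_id=sample_id,
                 qc_pass=profile.qc_pass,
                 genus_richness=genus_richness(profile),
                 host_plant_proportion=host_plant_proportion(
                     profile, genus_lineages, host_families,
                     renormalize=renormalize,
                 ))
        )

    if not any(row["qc_pass"] for row in summary_rows):
        raise PipelineError("profile: every sample failed the matched-read QC")

    write_table(pd.DataFrame(count_rows), out_dir / "genus_counts.tsv")
    write_table(pd.DataFrame(totals_rows), out_dir / "locus_totals.tsv")
    write_table(pd.DataFrame(profile_rows), out_dir / "profiles.tsv")
    write_table(pd.DataFrame(summary_rows), out_dir / "sample_summary.tsv")

    summary = {
        "version": __version__,
        "parameters": {
            "min_identity": min_identity,
            "min_coverage": min_coverage,
            "max_accepts": max_accepts,
            "both_strands": both_strands,
            "qc_threshold": qc_threshold,
            "min_prop": min_prop,
            "renormalize": renormalize,
            "excluded_genera": sorted(exclude),
            "host_families": sorted(host_families),
            "relaxed_min_identity": relaxed_min_identity,
        },
        "cleaning": cleaning_counts,
        "samples": summary_rows,
    }
    with open(out_dir / "run_summary.json", "w", encoding="utf-8") as fh:
        json.dump(summary, fh, indent=2, sort_keys=True)
        fh.write("\n")
    logger.info("pipeline complete: %d samples -> %s", len(summary_rows), out_dir)
    return summary
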