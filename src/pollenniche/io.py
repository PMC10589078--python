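"""Readers and writers for the formats the pipeline touches.

Sequences go through Biopython (FASTA/FASTQ); tables are tab-separated UTF-8
with a single header row and stable column order, floats at 6 significant
digits, so fixtures diff cleanly.
"""

from __future__ import annotations

import csv
import os
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from Bio import SeqIO

from .nutrition import ProvisionNutrition, RearingRecord

_FASTA_EXT = {".fasta", ".fa", ".fna"}
_FASTQ_EXT = {".fastq", ".fq"}


def _infer_format(path: Path, fmt: Optional[str]) -> str:
    if fmt is not None:
        fmt = fmt.lower()
        if fmt not in ("fasta", "fastq"):
            raise ValueError(f"unsupported sequence format '{fmt}'")
        return fmt
    suffix = path.suffix.lower()
    if suffix in _FASTA_EXT:
        return "fasta"
    if suffix in _FASTQ_EXT:
        return "fastq"
    raise ValueError(f"cannot infer sequence format from '{path.name}'")


def read_sequences(path, fmt: Optional[str] = None) -> list[tuple[str, str]]:
    """Read FASTA/FASTQ into (id, uppercased sequence) pairs.

    Ids must be unique within the file; FASTQ qualities are parsed but not
    carried (the pipeline consumes already-merged reads as-is).
    """
    path = Path(path)
    fmt = _infer_format(path, fmt)
    records: list[tuple[str, str]] = []
    seen: dict[str, int] = {}
    try:
        for rec in SeqIO.parse(str(path), fmt):
            seen[rec.id] = seen.get(rec.id, 0) + 1
            records.append((rec.id, str(rec.seq).upper()))
    except ValueError as exc:
        raise ValueError(f"{path}: malformed {fmt} record: {exc}") from exc
    duplicates = sorted(i for i, n in seen.items() if n > 1)
    if duplicates:
        raise ValueError(f"{path}: duplicate sequence ids: {', '.join(duplicates)}")
    return records


def write_fasta(records: Iterable[tuple[str, str]], path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        for rec_id, seq in records:
            fh.write(f">{rec_id}\n{seq}\n")


def write_table(frame: pd.DataFrame, path) -> None:
    frame.to_csv(path, sep="\t", index=False, float_format="%.6g")


def read_nutrition_table(path) -> list[ProvisionNutrition]:
    """Nutrition TSV: sample_id, protein_ug_mg, lipid_ug_mg, site, week."""
    frame = pd.read_csv(path, sep="\t")
    required = {"sample_id", "protein_ug_mg", "lipid_ug_mg"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    out = []
    for row in frame.itertuples(index=False):
        week = getattr(row, "week", None)
        out.append(
            ProvisionNutrition(
                sample_id=str(row.sample_id),
                protein=float(row.protein_ug_mg),
                lipid=float(row.lipid_ug_mg),
                site=str(getattr(row, "site", "")),
                week=int(week) if week is not None and not pd.isna(week) else None,
            )
        )
    return out


def write_nutrition_table(samples: Sequence[ProvisionNutrition], path) -> None:
    write_table(
        pd.DataFrame(
            dict(
                sample_id=[s.sample_id for s in samples],
                protein_ug_mg=[s.protein for s in samples],
                lipid_ug_mg=[s.lipid for s in samples],
                site=[s.site for s in samples],
                week=[s.week for s in samples],
            )
        ),
        path,
    )


def read_rearing_table(path) -> list[RearingRecord]:
    frame = pd.read_csv(path, sep="\t")
    required = {"individual_id", "diet", "cocoon_completed", "pupated",
                "adult_survived"}
    missing = required - set(frame.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")

    def opt_float(value):
        return None if pd.isna(value) else float(value)

    out = []
    for row in frame.itertuples(index=False):
        out.append(
            RearingRecord(
                individual_id=str(row.individual_id),
                diet=str(row.diet),
                cocoon_completed=bool(row.cocoon_completed),
                pupated=bool(row.pupated),
                adult_survived=bool(row.adult_survived),
                hatch_to_cocoon_days=opt_float(getattr(row, "hatch_to_cocoon_days", None)),
                cocoon_to_pupation_days=opt_float(getattr(row, "cocoon_to_pupation_days", None)),
                starting_mass_mg=opt_float(getattr(row, "starting_mass_mg", None)),
                day_of_graft=(
                    None if pd.isna(getattr(row, "day_of_graft", None))
                    else int(row.day_of_graft)
                ),
            )
        )
    return out


def write_rearing_table(records: Sequence[RearingRecord], path) -> None:
    write_table(
        pd.DataFrame(
            dict(
                individual_id=[r.individual_id for r in records],
                diet=[r.diet for r in records],
                cocoon_completed=[r.cocoon_completed for r in records],
                pupated=[r.pupated for r in records],
                adult_survived=[r.adult_survived for r in records],
                hatch_to_cocoon_days=[r.hatch_to_cocoon_days for r in records],
                cocoon_to_pupation_days=[r.cocoon_to_pupation_days for r in records],
                starting_mass_mg=[r.starting_mass_mg for r in records],
                day_of_graft=[r.day_of_graft for r in records],
            )
        ),
        path,
    )


@dataclass(frozen=True)
class ManifestEntry:
    sample_id: str
    locus: str
    path: Path


@dataclass(frozen=True)
class Manifest:
    """Rows of (sample-id, locus, reads path) driving a pipeline run."""

    entries: tuple[ManifestEntry, ...]

    def __post_init__(self) -> None:
        seen = set()
        for entry in self.entries:
            key = (entry.sample_id, entry.locus)
            if key in seen:
                raise ValueError(f"duplicate manifest row for {key}")
            seen.add(key)

    @property
    def sample_ids(self) -> list[str]:
        out = []
        for entry in self.entries:
            if entry.sample_id not in out:
                out.append(entry.sample_id)
        return out


def read_manifest(path) -> Manifest:
    path = Path(path)
    entries = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        required = {"sample_id", "locus", "path"}
        if reader.fieldnames is None or not required <= set(reader.fieldnames):
            raise ValueError(f"{path}: manifest needs columns {sorted(required)}")
        for row in reader:
            reads_path = Path(row["path"])
            if not reads_path.is_absolute():
                reads_path = path.parent / reads_path
            entries.append(
                ManifestEntry(row["sample_id"].strip(), row["locus"].strip(), reads_path)
            )
    return Manifest(tuple(entries))


def write_manifest(manifest: Manifest, path) -> None:
    # Reads paths are written relative to the manifest's own directory (the
    # reader resolves them against it), keeping fixture sets relocatable.
    base = Path(path).resolve().parent
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter="\t", lineterminator="\n")
        writer.writerow(("sample_id", "locus", "path"))
        for entry in manifest.entries:
            writer.writerow((
                entry.sample_id, entry.locus,
                os.path.relpath(entry.path.resolve(), base),
            ))
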