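"""Reference barcode database decontamination.

Public reference databases for ITS barcodes carry mislabeled accessions —
fungal sequences deposited under plant names, or plant sequences filed under
the wrong genus. Classifying pollen reads against such records silently
corrupts genus profiles, so every barcode is screened against two contrast
databases before use:

1. any 100%-identity, 100%-query-coverage hit in the **non-plant** contrast
   database flags the barcode as mislabeled;
2. otherwise exact hits in the **plant** contrast database are inspected: a
   hit of the barcode's own labeled genus confirms the label, exact hits to
   other genera only refute it;
3. barcodes with no exact plant hit are resolved by their best relaxed
   (semi-global) plant hit: same genus confirms, anything else refutes;
4. finally, an exact hit whose lineage class is known and is not
   Magnoliopsida forces the mislabeled flag regardless of rules 2–3.

"100% query coverage with 100% identity" is implemented as exact substring
containment of the barcode inside the contrast sequence; ``N`` never matches
any base, so a barcode containing ``N`` cannot have an exact hit.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from typing import Iterable, Optional

from .taxonomy import Lineage, lowest_common_ancestor

logger = logging.getLogger(__name__)

_ALPHABET = frozenset("ACGTN")

MISLABELED = "mislabeled"
CORRECTLY_LABELED = "correctly_labeled"

RULE_NONPLANT_EXACT = "nonplant_exact_hit"
RULE_PLANT_MISMATCH = "plant_genus_mismatch"
RULE_PLANT_MATCH = "plant_genus_match"
RULE_TOPHIT_SAME = "no_plant_hit_tophit_same_genus"
RULE_TOPHIT_OTHER = "no_plant_hit_tophit_other"
RULE_NON_MAGNOLIOPSIDA = "non_magnoliopsida_hit"

ALL_RULES = (
    RULE_NONPLANT_EXACT,
    RULE_PLANT_MISMATCH,
    RULE_PLANT_MATCH,
    RULE_TOPHIT_SAME,
    RULE_TOPHIT_OTHER,
    RULE_NON_MAGNOLIOPSIDA,
)

PLANT_CLASS = "Magnoliopsida"


@dataclass(frozen=True)
class BarcodeRecord:
    """A reference barcode for one locus with its labeled lineage."""

    id: str
    locus: str
    sequence: str
    lineage: Lineage

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"barcode '{self.id}' has an empty sequence")
        bad = set(self.sequence) - _ALPHABET
        if bad:
            raise ValueError(
                f"barcode '{self.id}' contains characters outside ACGTN: {sorted(bad)}"
            )
        if self.lineage.genus is None:
            raise ValueError(f"barcode '{self.id}' has no labeled genus")


@dataclass(frozen=True)
class ContrastRecord:
    id: str
    sequence: str
    lineage: Optional[Lineage] = None


@dataclass(frozen=True)
class ContrastDatabase:
    """A plant or non-plant contrast sequence collection."""

    kind: str  # "plant" or "non_plant"
    records: tuple[ContrastRecord, ...]

    def __post_init__(self) -> None:
        if self.kind not in ("plant", "non_plant"):
            raise ValueError(f"unknown contrast database kind '{self.kind}'")

    @classmethod
    def from_sequences(cls, kind: str, records: Iterable) -> "ContrastDatabase":
        out = []
        for rec in records:
            if isinstance(rec, ContrastRecord):
                out.append(rec)
            else:
                rec_id, seq, *rest = rec
                out.append(ContrastRecord(rec_id, seq, rest[0] if rest else None))
        return cls(kind, tuple(out))


@dataclass(frozen=True)
class FlagDecision:
    barcode_id: str
    locus: str
    status: str  # MISLABELED or CORRECTLY_LABELED
    rule: str
    evidence: tuple[str, ...] = ()


def exact_full_matches(barcode: BarcodeRecord, db: ContrastDatabase) -> list[str]:
    """Ids of contrast records containing the barcode as an exact substring.

    Equal-length exact equality is the special case; an ``N`` anywhere in the
    barcode precludes any hit because ``N`` matches nothing.
    """
    seq = barcode.sequence
    bad = set(seq) - _ALPHABET
    if bad:
        raise ValueError(
            f"barcode '{barcode.id}' contains characters outside ACGTN: {sorted(bad)}"
        )
    if "N" in seq:
        return []
    # Literal substring search is correct here: contrast-side Ns can never
    # equal an ACGT character, so they fail the window exactly as required.
    return sorted(r.id for r in db.records if seq in r.sequence)


def _relaxed_top_hit(
    barcode: BarcodeRecord,
    plant: ContrastDatabase,
    min_identity: float,
    min_coverage: float = 0.80,
) -> tuple[list[ContrastRecord], list[str]]:
    """Best relaxed plant hit(s) for rule 3, via the read-search machinery.

    Uses the same accepted-hit semantics as read classification (identity and
    query-coverage thresholds; hits ordered identity desc, score desc, record
    id asc). The coverage requirement matters: under free end gaps a
    few-column terminal alignment of unrelated sequences trivially reaches
    identity 1.0, so identity alone cannot rank hits. All records tying the
    winner on (identity, score) are returned so genus agreement can be tested
    against their LCA.
    """
    from .classify import MergedRead, search_reference

    query = MergedRead(barcode.id, "", barcode.locus, barcode.sequence)
    hits = search_reference(
        query,
        [(r.id, r.sequence) for r in plant.records],
        min_identity=min_identity,
        min_coverage=min_coverage,
        max_accepts=len(plant.records),
        both_strands=False,
    )
    if not hits:
        return [], []
    top = hits[0]
    tied_ids = [
        h.reference_id for h in hits
        if h.identity == top.identity and h.score == top.score
    ]
    by_id = {r.id: r for r in plant.records}
    return [by_id[i] for i in tied_ids], tied_ids


def flag_barcode(
    barcode: BarcodeRecord,
    nonplant: ContrastDatabase,
    plant: ContrastDatabase,
    relaxed_min_identity: float = 0.0,
) -> FlagDecision:
    """Apply the four-rule decontamination cascade to one barcode."""
    if not nonplant.records or not plant.records:
        raise ValueError("contrast databases must be non-empty")

    nonplant_hits = exact_full_matches(barcode, nonplant)
    if nonplant_hits:
        return FlagDecision(
            barcode.id, barcode.locus, MISLABELED, RULE_NONPLANT_EXACT,
            tuple(nonplant_hits),
        )

    plant_hits = exact_full_matches(barcode, plant)
    plant_by_id = {r.id: r for r in plant.records}
    labeled_genus = barcode.lineage.genus

    if plant_hits:
        same = [
            h for h in plant_hits
            if plant_by_id[h].lineage is not None
            and plant_by_id[h].lineage.genus == labeled_genus
        ]
        other = [h for h in plant_hits if h not in same]
        if same:
            if other:
                logger.warning(
                    "barcode %s: exact plant hits in both its own genus (%s) and "
                    "others (%s); same-genus concordance wins",
                    barcode.id, ",".join(same), ",".join(other),
                )
            decision = FlagDecision(
                barcode.id, barcode.locus, CORRECTLY_LABELED, RULE_PLANT_MATCH,
                tuple(same),
            )
        else:
            decision = FlagDecision(
                barcode.id, barcode.locus, MISLABELED, RULE_PLANT_MISMATCH,
                tuple(other),
            )
    else:
        tied, evidence = _relaxed_top_hit(barcode, plant, relaxed_min_identity)
        if not tied:
            logger.warning(
                "barcode %s: no relaxed plant hit at min identity %.2f; "
                "flagged mislabeled with empty evidence",
                barcode.id, relaxed_min_identity,
            )
            decision = FlagDecision(
                barcode.id, barcode.locus, MISLABELED, RULE_TOPHIT_OTHER, ()
            )
        else:
            with_lineage = [r.lineage for r in tied if r.lineage is not None]
            if len(with_lineage) == len(tied) and with_lineage:
                top_genus = lowest_common_ancestor(with_lineage).genus
            else:
                top_genus = None
            if top_genus is not None and top_genus == labeled_genus:
                decision = FlagDecision(
                    barcode.id, barcode.locus, CORRECTLY_LABELED,
                    RULE_TOPHIT_SAME, tuple(evidence),
                )
            else:
                decision = FlagDecision(
                    barcode.id, barcode.locus, MISLABELED,
                    RULE_TOPHIT_OTHER, tuple(evidence),
                )

    # Rule 4: any exact match whose lineage class is known and not
    # Magnoliopsida overrides whatever rules 2-3 concluded. Non-plant exact
    # matches were already handled by rule 1 above.
    offending = [
        h for h in plant_hits
        if plant_by_id[h].lineage is not None
        and plant_by_id[h].lineage.class_ is not None
        and plant_by_id[h].lineage.class_ != PLANT_CLASS
    ]
    if offending:
        return FlagDecision(
            barcode.id, barcode.locus, MISLABELED, RULE_NON_MAGNOLIOPSIDA,
            tuple(offending),
        )
    return decision


@dataclass
class CleaningReport:
    """Per-rule and per-locus bookkeeping for a cleaning run."""

    decisions: list[FlagDecision] = field(default_factory=list)

    def counts_by_rule(self) -> dict[str, int]:
        return dict(Counter(d.rule for d in self.decisions))

    def counts_by_locus_rule(self) -> dict[tuple[str, str], int]:
        return dict(Counter((d.locus, d.rule) for d in self.decisions))

    def removed_fraction(self) -> dict[str, float]:
        total = Counter(d.locus for d in self.decisions)
        removed = Counter(
            d.locus for d in self.decisions if d.status == MISLABELED
        )
        return {locus: removed[locus] / n for locus, n in total.items()}


def clean_database(
    barcodes: Iterable[BarcodeRecord],
    nonplant: ContrastDatabase,
    plant: ContrastDatabase,
    relaxed_min_identity: float = 0.0,
) -> tuple[list[BarcodeRecord], CleaningReport]:
    """Flag every barcode and drop the mislabeled ones.

    Decisions are per-barcode and independent, so the retained set does not
    depend on input order (output preserves it).
    """
    report = CleaningReport()
    retained: list[BarcodeRecord] = []
    for barcode in barcodes:
        decision = flag_barcode(barcode, nonplant, plant, relaxed_min_identity)
        report.decisions.append(decision)
        if decision.status == CORRECTLY_LABELED:
            retained.append(barcode)
        else:
            logger.info(
                "removed barcode %s (%s): %s", barcode.id, barcode.locus,
                decision.rule,
            )
    return retained, report
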