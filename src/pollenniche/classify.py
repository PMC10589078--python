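"""Genus-level classification of merged amplicon reads.

Each merged read is searched against the per-locus reference barcode set by
semi-global alignment; hits passing the identity (default 0.95) and query
coverage (default 0.80) thresholds are accepted and the top hit(s) decide the
assignment. Ties on (identity, score) are resolved taxonomically: if the tied
references disagree at genus rank, the read falls back to their lowest common
ancestor and — when that sits above genus — is counted as matched but
unassigned.

Only forward-strand reference sequences are stored; by default each read is
additionally tried as its reverse complement and the better orientation kept,
because merged amplicon orientation is not guaranteed.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

from .align import (
    DEFAULT_GAP,
    DEFAULT_MATCH,
    DEFAULT_MISMATCH,
    AlignmentHit,
    encode,
    reverse_complement,
    semiglobal_align,
)
from .taxonomy import Lineage, lowest_common_ancestor

LOCI = ("ITS1", "ITS2")

MATCHED_UNASSIGNED = "matched_unassigned"
UNMATCHED = "unmatched"
GENUS = "genus"


@dataclass(frozen=True)
class MergedRead:
    """A merged (already paired) amplicon read for one sample and locus."""

    id: str
    sample_id: str
    locus: str
    sequence: str

    def __post_init__(self) -> None:
        if len(self.sequence) < 1:
            raise ValueError(f"read '{self.id}' has an empty sequence")


class ReferenceIndex:
    """Per-locus reference set with pre-encoded sequences."""

    def __init__(self, records: Sequence) -> None:
        if not records:
            raise ValueError("reference database is empty")
        self.records = list(records)
        self.ids = [r.id if hasattr(r, "id") else r[0] for r in self.records]
        self.sequences = [
            r.sequence if hasattr(r, "sequence") else r[1] for r in self.records
        ]
        self.loci = [getattr(r, "locus", None) for r in self.records]
        self.encoded = [encode(s) for s in self.sequences]

    def __len__(self) -> int:
        return len(self.ids)


@dataclass(frozen=True)
class ReadAssignment:
    read_id: str
    status: str  # GENUS, MATCHED_UNASSIGNED or UNMATCHED
    genus: Optional[str] = None
    hits: tuple[AlignmentHit, ...] = ()


@dataclass
class LocusCounts:
    """Per-sample, per-locus genus read counts plus search totals."""

    sample_id: str
    counts: dict[str, dict[str, int]] = field(default_factory=dict)
    processed: dict[str, int] = field(default_factory=dict)
    matched: dict[str, int] = field(default_factory=dict)

    def total_processed(self) -> int:
        return sum(self.processed.values())

    def total_matched(self) -> int:
        return sum(self.matched.values())


def search_reference(
    read: MergedRead,
    db,
    min_identity: float = 0.95,
    min_coverage: float = 0.80,
    max_accepts: int = 100,
    both_strands: bool = True,
    match: int = DEFAULT_MATCH,
    mismatch: int = DEFAULT_MISMATCH,
    gap: int = DEFAULT_GAP,
) -> list[AlignmentHit]:
    """Accepted hits of ``read`` in ``db``, best first.

    The whole reference set is searched exhaustively; accepted hits (identity
    ≥ ``min_identity`` and coverage ≥ ``min_coverage``) are ordered by
    identity desc, score desc, reference id asc and truncated to
    ``max_accepts``. Deterministic for fixed inputs.
    """
    if not 0.0 <= min_identity <= 1.0 or not 0.0 <= min_coverage <= 1.0:
        raise ValueError("thresholds must lie in [0, 1]")
    index = db if isinstance(db, ReferenceIndex) else ReferenceIndex(db)
    for ref_id, locus in zip(index.ids, index.loci):
        if locus is not None and locus != read.locus:
            raise ValueError(
                f"read '{read.id}' is {read.locus} but reference '{ref_id}' is {locus}"
            )
    q_fwd = encode(read.sequence)
    q_rev = encode(reverse_complement(read.sequence)) if both_strands else None
    accepted: list[AlignmentHit] = []
    for ref_id, ref_seq, ref_enc in zip(index.ids, index.sequences, index.encoded):
        # Thresholds apply per orientation: an orientation only competes if
        # it is itself an acceptable hit, otherwise a degenerate few-column
        # end alignment (identity 1.0 at negligible coverage) on the wrong
        # strand could mask a genuine hit on the right one.
        candidates = [
            semiglobal_align(
                read.sequence, ref_seq, match, mismatch, gap,
                reference_id=ref_id, _query_enc=q_fwd, _target_enc=ref_enc,
            )
        ]
        if q_rev is not None:
            rev = semiglobal_align(
                read.sequence, ref_seq, match, mismatch, gap,
                reference_id=ref_id, _query_enc=q_rev, _target_enc=ref_enc,
            )
            candidates.append(dataclasses.replace(rev, strand="-"))
        passing = [
            c for c in candidates
            if c.identity >= min_identity and c.query_coverage >= min_coverage
        ]
        if passing:
            # forward listed first wins ties, so plus-strand data never flips
            accepted.append(max(passing, key=lambda c: (c.identity, c.score)))
    accepted.sort(key=lambda h: (-h.identity, -h.score, h.reference_id))
    return accepted[:max_accepts]


def assign_read(
    hits: Sequence[AlignmentHit],
    lineages: Mapping[str, Lineage],
    read_id: str = "",
) -> ReadAssignment:
    """Top-hit lineage assignment with LCA tie-breaking.

    ``hits`` must already be ordered as produced by :func:`search_reference`.
    """
    if not hits:
        return ReadAssignment(read_id=read_id, status=UNMATCHED)
    top = hits[0]
    tied = [
        h for h in hits if h.identity == top.identity and h.score == top.score
    ]
    tied_lineages = []
    for h in tied:
        if h.reference_id not in lineages:
            raise KeyError(f"no lineage for reference '{h.reference_id}'")
        tied_lineages.append(lineages[h.reference_id])
    consensus = lowest_common_ancestor(tied_lineages)
    if consensus.genus is not None:
        return ReadAssignment(
            read_id=read_id, status=GENUS, genus=consensus.genus, hits=tuple(tied)
        )
    return ReadAssignment(
        read_id=read_id, status=MATCHED_UNASSIGNED, hits=tuple(tied)
    )


def classify_sample(
    reads: Iterable[MergedRead],
    dbs: Mapping[str, Sequence],
    lineages: Mapping[str, Lineage],
    min_identity: float = 0.95,
    min_coverage: float = 0.80,
    max_accepts: int = 100,
    both_strands: bool = True,
    sample_id: Optional[str] = None,
) -> LocusCounts:
    """Classify one sample's reads, per locus, into genus count tables.

    Totals track reads processed, matched (genus-assigned plus matched but
    genus-ambiguous) and unmatched per locus; per-locus genus counts plus
    ambiguous plus unmatched always sum to the reads processed.
    """
    reads = list(reads)
    if sample_id is None:
        sample_id = reads[0].sample_id if reads else ""
    indexes = {locus: ReferenceIndex(db) for locus, db in dbs.items()}
    result = LocusCounts(
        sample_id=sample_id,
        counts={locus: {} for locus in indexes},
        processed={locus: 0 for locus in indexes},
        matched={locus: 0 for locus in indexes},
    )
    for read in reads:
        if read.locus not in indexes:
            raise ValueError(f"no reference database for locus '{read.locus}'")
        result.processed[read.locus] += 1
        hits = search_reference(
            read,
            indexes[read.locus],
            min_identity=min_identity,
            min_coverage=min_coverage,
            max_accepts=max_accepts,
            both_strands=both_strands,
        )
        assignment = assign_read(hits, lineages, read_id=read.id)
        if assignment.status == GENUS:
            result.matched[read.locus] += 1
            bucket = result.counts[read.locus]
            bucket[assignment.genus] = bucket.get(assignment.genus, 0) + 1
        elif assignment.status == MATCHED_UNASSIGNED:
            result.matched[read.locus] += 1
    return result
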