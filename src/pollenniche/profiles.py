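"""Per-sample genus profiles from dual-locus read counts.

Both ITS loci are sequenced per sample but amplify genera unevenly; the
profile therefore takes, for each genus, the *maximum* read count over the
two loci and divides by the sum of those maxima. Two filters follow the
counting: a sample-level QC requiring at least 5% of merged reads (both loci
combined) to have matched the reference database, and a 1% minimum proportion
for a genus to be retained in downstream analyses. Genera known to be
geographically implausible (database mismatches) are excluded before any
proportion is computed.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import AbstractSet, Mapping

from .classify import LocusCounts
from .taxonomy import Lineage

logger = logging.getLogger(__name__)

#: Genera reported by the reference database but absent from the study area.
DEFAULT_EXCLUDED_GENERA = frozenset({"Clusia", "Hirtella", "Parinari"})

#: Host plant families of Osmia cornifrons.
DEFAULT_HOST_FAMILIES = frozenset({"Rosaceae", "Fabaceae"})


@dataclass(frozen=True)
class GenusProfile:
    """Genus → proportion table for one sample.

    ``proportions`` are pre-threshold and un-renormalized: over all detected
    (non-excluded) genera they sum to 1. ``retained`` holds the genera at or
    above the inclusion threshold.
    """

    sample_id: str
    proportions: Mapping[str, float]
    retained: frozenset[str]
    excluded: frozenset[str]
    qc_pass: bool
    min_prop: float

    def retained_proportions(self, renormalize: bool = False) -> dict[str, float]:
        kept = {g: self.proportions[g] for g in self.retained}
        if renormalize and kept:
            total = sum(kept.values())
            kept = {g: p / total for g, p in kept.items()}
        return kept


def sample_qc(counts: LocusCounts, threshold: float = 0.05) -> bool:
    """True when matched reads across both loci reach ``threshold`` (inclusive)."""
    processed = counts.total_processed()
    if processed == 0:
        raise ValueError(
            f"sample '{counts.sample_id}' has zero processed reads at every locus"
        )
    return counts.total_matched() / processed >= threshold


def dual_locus_profile(
    counts: LocusCounts,
    exclude: AbstractSet[str] = DEFAULT_EXCLUDED_GENERA,
    min_prop: float = 0.01,
    qc_threshold: float = 0.05,
) -> GenusProfile:
    """Dual-locus maximum aggregation into a genus proportion profile.

    For each genus g, m(g) = max(ITS1 count, ITS2 count) with an absent locus
    counting 0; proportions are m(g) / Σ m(g). Excluded genera are dropped
    from both loci before aggregation; genera below ``min_prop`` stay in the
    proportion table but are not in the retained set.
    """
    maxima: dict[str, int] = {}
    for locus_counts in counts.counts.values():
        for genus, n in locus_counts.items():
            if n < 0:
                raise ValueError(f"negative count for genus '{genus}'")
            if genus in exclude:
                continue
            maxima[genus] = max(maxima.get(genus, 0), n)
    total = sum(maxima.values())
    if total == 0:
        raise ValueError(
            f"sample '{counts.sample_id}': no classified reads after exclusions"
        )
    proportions = {g: m / total for g, m in sorted(maxima.items())}
    retained = frozenset(g for g, p in proportions.items() if p >= min_prop)
    return GenusProfile(
        sample_id=counts.sample_id,
        proportions=proportions,
        retained=retained,
        excluded=frozenset(exclude),
        qc_pass=sample_qc(counts, qc_threshold),
        min_prop=min_prop,
    )


def genus_richness(profile: GenusProfile) -> int:
    """Number of genera retained after the inclusion threshold."""
    return len(profile.retained)


def host_plant_proportion(
    profile: GenusProfile,
    lineages: Mapping[str, Lineage],
    host_families: AbstractSet[str] = DEFAULT_HOST_FAMILIES,
    renormalize: bool = False,
) -> float:
    """Summed proportion of retained genera belonging to the host families.

    ``lineages`` maps genus name → lineage; a retained genus with no lineage
    or unknown family contributes zero and is logged. Computed on
    un-renormalized proportions unless ``renormalize`` is set.
    """
    kept = profile.retained_proportions(renormalize=renormalize)
    total = 0.0
    for genus, prop in kept.items():
        lineage = lineages.get(genus)
        if lineage is None or lineage.family is None:
            logger.warning(
                "sample %s: genus %s has no known family; contributes 0 to "
                "host-plant proportion", profile.sample_id, genus,
            )
            continue
        if lineage.family in host_families:
            total += prop
    return total
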