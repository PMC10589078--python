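"""Protein:lipid nutritional-niche arithmetic and rearing summaries.

The macronutrient niche of a pollen-provisioning bee is summarised here by
the protein-to-lipid mass ratio (P:L, µg protein per µg lipid) of its larval
provisions: the *target* is the mean ratio across provisions and the *niche
breadth* the observed range. Experimental diets probing that breadth are
formulated by adding a protein additive (casein) and/or a lipid additive
(canola oil) to a base pollen of known composition; concentrations are
conventionally expressed per mg of base pollen, so adding one nutrient leaves
the printed concentration of the other unchanged ("dilution-ignored"
convention). A mass-balance mode that divides by the total diet mass is
available behind a flag; it yields the same target ratio (both concentrations
are divided by the same total) but lower absolute concentrations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Iterable, Literal, Optional, Sequence

import pandas as pd


@dataclass(frozen=True)
class ProvisionNutrition:
    """One provision's macronutrient concentrations with collection metadata."""

    sample_id: str
    protein: float  # µg per mg dry mass
    lipid: float  # µg per mg dry mass
    site: str = ""
    week: Optional[int] = None

    def __post_init__(self) -> None:
        if self.protein < 0:
            raise ValueError(f"sample '{self.sample_id}': negative protein")
        if self.lipid < 0:
            raise ValueError(f"sample '{self.sample_id}': negative lipid")


@dataclass(frozen=True)
class MetricSummary:
    n: int
    mean: float
    se: Optional[float]  # sample SD (n-1) / sqrt(n); None when n == 1
    min: float
    max: float


@dataclass(frozen=True)
class NicheSummary:
    protein: MetricSummary
    lipid: MetricSummary
    ratio: MetricSummary


@dataclass(frozen=True)
class DietFormulation:
    """Additive masses (mg per mg base pollen) and resulting composition."""

    protein_additive: float
    lipid_additive: float
    protein: float  # resulting µg/mg
    lipid: float  # resulting µg/mg


@dataclass(frozen=True)
class RearingRecord:
    """Outcome of one in-vitro-reared individual."""

    individual_id: str
    diet: str
    cocoon_completed: bool
    pupated: bool
    adult_survived: bool
    hatch_to_cocoon_days: Optional[float] = None
    cocoon_to_pupation_days: Optional[float] = None
    starting_mass_mg: Optional[float] = None
    day_of_graft: Optional[int] = None

    def __post_init__(self) -> None:
        if self.pupated and not self.cocoon_completed:
            raise ValueError(
                f"individual '{self.individual_id}' pupated without completing a cocoon"
            )
        if self.adult_survived and not self.pupated:
            raise ValueError(
                f"individual '{self.individual_id}' survived to adult without pupating"
            )


#: Experimental diet formulations (name, group, printed ratio label,
#: protein µg/mg, lipid µg/mg, sample size). Control diets of homogenized
#: bee-collected provisions carry a presumed 3:1 label and no measured
#: concentrations.
REFERENCE_DIETS: tuple[tuple[str, str, str, Optional[float], Optional[float], int], ...] = (
    ("control_unaltered", "altered_multifloral_2020", "5.5:1", 191.40, 34.40, 44),
    ("modified_control", "altered_multifloral_2020", "5.5:1", 327.72, 59.54, 42),
    ("high_lipid", "altered_multifloral_2020", "0.4:1", 191.40, 443.18, 42),
    ("mid_range", "altered_multifloral_2020", "6.6:1", 228.30, 34.40, 48),
    ("high_protein", "altered_multifloral_2020", "14.5:1", 498.36, 34.40, 33),
    ("juglans_nigra", "monofloral_2022", "0.6:1", 51.38, 81.63, 35),
    ("plantago_lanceolata", "monofloral_2022", "1.4:1", 125.23, 87.64, 35),
    ("salix_nigra", "monofloral_2022", "2.5:1", 115.90, 46.22, 35),
    ("dactylis_glomerata", "monofloral_2022", "4.2:1", 111.09, 26.33, 35),
    ("acer_rubrum", "monofloral_2022", "6.3:1", 217.76, 34.38, 35),
    ("control_provisions_mono", "monofloral_2022", "3:1", None, None, 35),
    ("natural_high_lipid", "natural_multifloral_2022", "1:1", 83.17, 82.73, 35),
    ("natural_mid_range_1", "natural_multifloral_2022", "2.9:1", 87.95, 29.61, 35),
    ("natural_mid_range_2", "natural_multifloral_2022", "5.2:1", 77.51, 14.90, 35),
    ("natural_high_protein", "natural_multifloral_2022", "10.5:1", 104.62, 9.88, 35),
    ("control_provisions_multi", "natural_multifloral_2022", "3:1", None, None, 35),
)


def pl_ratio(protein: float, lipid: float) -> float:
    """Protein-to-lipid mass ratio (dimensionless).

    Scale-invariant: any common unit for the two concentrations cancels.
    """
    if lipid <= 0:
        raise ValueError(f"lipid must be positive to form a P:L ratio, got {lipid}")
    if protein < 0:
        raise ValueError(f"protein must be non-negative, got {protein}")
    return protein / lipid


def _summarize(values: Sequence[float]) -> MetricSummary:
    n = len(values)
    mean = sum(values) / n
    if n > 1:
        var = sum((v - mean) ** 2 for v in values) / (n - 1)
        se = math.sqrt(var) / math.sqrt(n)
    else:
        se = None
    return MetricSummary(n=n, mean=mean, se=se, min=min(values), max=max(values))


def niche_summary(
    samples: Iterable[ProvisionNutrition],
    group_by: Literal[None, "site", "week"] = None,
) -> dict:
    """Mean ± SE and range of protein, lipid and per-sample P:L ratio.

    The ratio is computed per sample and then summarised (not as a ratio of
    means). Returns a mapping group-label → :class:`NicheSummary`; the
    ungrouped summary lives under the key ``"all"``.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("niche_summary of an empty sample collection")
    if group_by is None:
        groups = {"all": samples}
    elif group_by in ("site", "week"):
        groups = {}
        for s in samples:
            groups.setdefault(getattr(s, group_by), []).append(s)
    else:
        raise ValueError(f"group_by must be None, 'site' or 'week', got {group_by!r}")
    out = {}
    for label, members in sorted(groups.items(), key=lambda kv: str(kv[0])):
        if not members:
            raise ValueError(f"empty group '{label}'")
        out[label] = NicheSummary(
            protein=_summarize([s.protein for s in members]),
            lipid=_summarize([s.lipid for s in members]),
            ratio=_summarize([pl_ratio(s.protein, s.lipid) for s in members]),
        )
    return out


def niche_summary_frame(summaries: dict) -> pd.DataFrame:
    """Tidy DataFrame view of :func:`niche_summary` output."""
    rows = []
    for label, summary in summaries.items():
        for metric in ("protein", "lipid", "ratio"):
            m: MetricSummary = getattr(summary, metric)
            rows.append(
                dict(group=label, metric=metric, n=m.n, mean=m.mean, se=m.se,
                     min=m.min, max=m.max)
            )
    return pd.DataFrame(rows)


def formulate_diet(
    base_protein: float,
    base_lipid: float,
    target_ratio: float,
    protein_purity: float = 1.0,
    lipid_purity: float = 1.0,
    dilution_aware: bool = False,
) -> DietFormulation:
    """Additive masses turning a base pollen into a target-P:L diet.

    Exactly one additive is used: lipid when the target sits below the base
    ratio, protein when above, neither at equality. With purity c (fraction of
    additive mass that is the nutrient), the mg of additive per mg base pollen
    are a_l = (P0/ρ − L0)/(1000·c_l) or a_p = (ρ·L0 − P0)/(1000·c_p). Under
    the default dilution-ignored convention the resulting concentrations are
    per mg of *base pollen*; with ``dilution_aware`` they are per mg of total
    diet (ratio unchanged).
    """
    if target_ratio <= 0:
        raise ValueError(f"target ratio must be positive, got {target_ratio}")
    if not 0 < protein_purity <= 1 or not 0 < lipid_purity <= 1:
        raise ValueError("additive purities must lie in (0, 1]")
    if base_lipid <= 0 or base_protein < 0:
        raise ValueError("base composition must have protein ≥ 0 and lipid > 0")
    base_ratio = base_protein / base_lipid
    a_p = 0.0
    a_l = 0.0
    if target_ratio < base_ratio:
        a_l = (base_protein / target_ratio - base_lipid) / (1000.0 * lipid_purity)
    elif target_ratio > base_ratio:
        a_p = (target_ratio * base_lipid - base_protein) / (1000.0 * protein_purity)
    protein = base_protein + 1000.0 * protein_purity * a_p
    lipid = base_lipid + 1000.0 * lipid_purity * a_l
    if dilution_aware:
        total_mass = 1.0 + a_p + a_l
        protein /= total_mass
        lipid /= total_mass
    return DietFormulation(
        protein_additive=a_p, lipid_additive=a_l, protein=protein, lipid=lipid
    )


def survival_summary(records: Iterable[RearingRecord]) -> pd.DataFrame:
    """Per-diet survival percentages and median development times.

    Denominators follow the rearing design: cocoon completion is a percentage
    of all individuals; pupation and adult survival are percentages of cocoon
    completers (the adult model only includes bees that survived the larval
    stage). Medians ignore unknown timings. Returns one row per diet with
    columns n, pct_cocoon, pct_pupated, pct_adult, median_hatch_to_cocoon,
    median_cocoon_to_pupation.
    """
    by_diet: dict[str, list[RearingRecord]] = {}
    for rec in records:
        if not rec.diet:
            raise ValueError(f"individual '{rec.individual_id}' has no diet group")
        by_diet.setdefault(rec.diet, []).append(rec)
    if not by_diet:
        raise ValueError("survival_summary of an empty record collection")
    rows = []
    for diet in sorted(by_diet):
        group = by_diet[diet]
        n = len(group)
        cocoon = [r for r in group if r.cocoon_completed]
        pupated = [r for r in cocoon if r.pupated]
        adults = [r for r in cocoon if r.adult_survived]
        t_cocoon = [r.hatch_to_cocoon_days for r in group
                    if r.hatch_to_cocoon_days is not None]
        t_pupa = [r.cocoon_to_pupation_days for r in group
                  if r.cocoon_to_pupation_days is not None]
        rows.append(
            dict(
                diet=diet,
                n=n,
                pct_cocoon=100.0 * len(cocoon) / n,
                pct_pupated=100.0 * len(pupated) / len(cocoon) if cocoon else float("nan"),
                pct_adult=100.0 * len(adults) / len(cocoon) if cocoon else float("nan"),
                median_hatch_to_cocoon=float(pd.Series(t_cocoon).median()) if t_cocoon else float("nan"),
                median_cocoon_to_pupation=float(pd.Series(t_pupa).median()) if t_pupa else float("nan"),
            )
        )
    return pd.DataFrame(rows)
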