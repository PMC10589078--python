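"""Synthetic study data: reference databases, reads, nutrition, rearing.

Every pipeline stage is exercised without any download by generating inputs
with the statistical structure the analysis assumes:

* **reference databases** — per-genus barcode founders evolved into species
  sequences for both ITS loci, a plant contrast database holding each true
  sequence embedded in random flanks, a non-plant (fungal) contaminant pool,
  and a configurable fraction of barcodes whose sequence is silently replaced
  by an exact copy from another genus or from the contaminant pool (the
  planted mislabels the cleaner must find);
* **sample reads** — multinomial draws from a known genus composition
  reweighted by per-locus amplification bias, each read copying a uniformly
  chosen conspecific reference and mutating bases at a substitution error
  rate;
* **provision nutrition** — protein and lipid concentrations from zero-
  truncated normals whose default moments emulate field provisions
  (protein 151.42, lipid 53.94 µg/mg on average);
* **rearing outcomes** — stage-conditional Bernoulli survival draws with
  per-diet probabilities and discrete development-time distributions.

All generators are pure functions of (config, seed): one global seed expands
into independent substreams per generator (and per sample), so adding a call
never perturbs other streams and identical inputs give byte-identical output
files. Truth tables record every generated entity exactly once.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .classify import LOCI, MergedRead
from .nutrition import ProvisionNutrition, RearingRecord
from .refdb import BarcodeRecord, ContrastDatabase, ContrastRecord
from .taxonomy import Lineage

_BASES = np.array(list("ACGT"))

# Real genus/family names keep the host-family and Magnoliopsida logic
# meaningful; the first two genera belong to the host families.
PLANT_CATALOG: tuple[tuple[str, str, str], ...] = (
    ("Malus", "Rosaceae", "Rosales"),
    ("Cercis", "Fabaceae", "Fabales"),
    ("Acer", "Sapindaceae", "Sapindales"),
    ("Lonicera", "Caprifoliaceae", "Dipsacales"),
    ("Salix", "Salicaceae", "Malpighiales"),
    ("Prunus", "Rosaceae", "Rosales"),
    ("Trifolium", "Fabaceae", "Fabales"),
    ("Juglans", "Juglandaceae", "Fagales"),
    ("Plantago", "Plantaginaceae", "Lamiales"),
    ("Quercus", "Fagaceae", "Fagales"),
    ("Vicia", "Fabaceae", "Fabales"),
    ("Rubus", "Rosaceae", "Rosales"),
)

FUNGAL_CATALOG: tuple[tuple[str, str, str, str], ...] = (
    ("Cladosporium", "Cladosporiaceae", "Capnodiales", "Dothideomycetes"),
    ("Alternaria", "Pleosporaceae", "Pleosporales", "Dothideomycetes"),
    ("Aspergillus", "Aspergillaceae", "Eurotiales", "Eurotiomycetes"),
)

_STREAMS = {"db": 1, "reads": 2, "nutrition": 3, "rearing": 4}

DEFAULT_DIET_SURVIVAL: dict[str, tuple[float, float, float]] = {
    # (P(cocoon), P(pupate | cocoon), P(adult | pupate))
    "control": (0.80, 0.90, 0.85),
    "acer_rubrum": (0.70, 0.85, 0.80),
    "juglans_nigra": (0.35, 0.50, 0.60),
    "plantago_lanceolata": (0.30, 0.00, 0.00),
    "salix_nigra": (0.15, 0.00, 0.00),
    "dactylis_glomerata": (0.20, 0.00, 0.00),
}


def plant_lineage(genus: str, species: str) -> Lineage:
    for g, family, order in PLANT_CATALOG:
        if g == genus:
            return Lineage(
                ("Viridiplantae", "Streptophyta", "Magnoliopsida", order,
                 family, genus, species)
            )
    raise KeyError(f"genus '{genus}' not in the synthetic plant catalog")


@dataclass
class SimulationConfig:
    """Study conditions for every generator; ``seed`` is mandatory."""

    seed: int
    # reference database
    n_genera: int = 5
    species_per_genus: int = 3
    barcode_length: int = 150
    inter_genus_divergence: float = 0.15  # substitutions evolving genus founders
    species_divergence: float = 0.01  # substitutions evolving species from founders
    mislabel_rate: float = 0.0
    nonplant_contaminant_count: int = 10
    contrast_flank: int = 20  # random bases flanking contrast-db sequences
    # sample reads
    composition: Optional[dict[str, float]] = None  # genus -> proportion, sums to 1
    reads_per_locus: int = 2000
    locus_bias: Optional[dict[str, dict[str, float]]] = None
    substitution_error_rate: float = 0.01
    # nutrition (pre-truncation moments of zero-truncated normals, µg/mg)
    protein_mean: float = 151.42
    protein_sd: float = 47.78
    lipid_mean: float = 53.94
    lipid_sd: float = 20.66
    sites: tuple[str, ...] = ("A", "B", "C", "D")
    n_weeks: int = 6
    # rearing
    diet_survival: dict[str, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_DIET_SURVIVAL)
    )

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("a seed is mandatory")
        for name in ("inter_genus_divergence", "species_divergence",
                     "mislabel_rate", "substitution_error_rate"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {value}")
        if self.n_genera > len(PLANT_CATALOG):
            raise ValueError(
                f"at most {len(PLANT_CATALOG)} genera available, asked for {self.n_genera}"
            )
        if self.composition is not None:
            total = sum(self.composition.values())
            if abs(total - 1.0) > 1e-9:
                raise ValueError(f"composition must sum to 1, got {total}")
        for sd in (self.protein_sd, self.lipid_sd):
            if sd < 0:
                raise ValueError(f"negative SD: {sd}")
        for diet, probs in self.diet_survival.items():
            if len(probs) != 3 or any(not 0.0 <= p <= 1.0 for p in probs):
                raise ValueError(
                    f"diet '{diet}': stage survival probabilities must be three "
                    f"values in [0, 1], got {probs}"
                )

    @property
    def genera(self) -> list[str]:
        return [g for g, _, _ in PLANT_CATALOG[: self.n_genera]]


def paper_like_config(seed: int) -> SimulationConfig:
    """Desk-scale preset emulating the field study's structure.

    Five genera at uneven proportions (the two host-family genera dominate),
    2000 reads per locus at 1% substitution error, and a 2-fold amplification
    bias favouring each genus at exactly one locus so the dual-locus maximum
    rule is consequential.
    """
    genera = [g for g, _, _ in PLANT_CATALOG[:5]]
    composition = dict(zip(genera, (0.40, 0.30, 0.15, 0.10, 0.05)))
    its1 = {g: (2.0 if i % 2 == 0 else 1.0) for i, g in enumerate(genera)}
    its2 = {g: (1.0 if i % 2 == 0 else 2.0) for i, g in enumerate(genera)}
    return SimulationConfig(
        seed=seed,
        n_genera=5,
        species_per_genus=3,
        barcode_length=150,
        mislabel_rate=0.1,
        nonplant_contaminant_count=10,
        composition=composition,
        reads_per_locus=2000,
        locus_bias={"ITS1": its1, "ITS2": its2},
        substitution_error_rate=0.01,
    )


def tiny_config(seed: int) -> SimulationConfig:
    """Very small preset for fast smoke tests."""
    genera = [g for g, _, _ in PLANT_CATALOG[:3]]
    return SimulationConfig(
        seed=seed,
        n_genera=3,
        species_per_genus=2,
        barcode_length=60,
        mislabel_rate=0.0,
        nonplant_contaminant_count=3,
        composition=dict(zip(genera, (0.5, 0.3, 0.2))),
        reads_per_locus=120,
        substitution_error_rate=0.0,
    )


def _rng(seed: int, stream: str, *extra: int) -> np.random.Generator:
    return np.random.default_rng(
        np.random.SeedSequence([int(seed), _STREAMS[stream], *extra])
    )


def _random_seq(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.integers(0, 4, size=length, dtype=np.int8)


def _mutate(seq: np.ndarray, rate: float, rng: np.random.Generator) -> np.ndarray:
    out = seq.copy()
    if rate <= 0.0:
        return out
    hit = rng.random(out.size) < rate
    n_hit = int(hit.sum())
    if n_hit:
        # shift by 1-3 guarantees a different base
        out[hit] = (out[hit] + rng.integers(1, 4, size=n_hit, dtype=np.int8)) % 4
    return out


def _to_str(seq: np.ndarray) -> str:
    return "".join(_BASES[seq])


@dataclass
class ReferenceSet:
    """A synthetic reference database plus the truth behind it."""

    barcodes: dict[str, list[BarcodeRecord]]  # per locus (mislabels planted)
    plant: ContrastDatabase
    nonplant: ContrastDatabase
    lineages: dict[str, Lineage]  # barcode id -> labeled lineage
    true_sequences: dict[str, dict[str, list[tuple[str, str]]]]  # locus -> genus -> [(species, seq)]
    truth: pd.DataFrame  # barcode_id, locus, genus, status, source


def generate_reference_db(config: SimulationConfig, max_retries: int = 5) -> ReferenceSet:
    """Evolve founders into species barcodes and plant the mislabels."""
    rng = _rng(config.seed, "db")
    genera = config.genera
    for attempt in range(max_retries):
        true_seqs: dict[str, dict[str, list[tuple[str, str]]]] = {}
        ok = True
        for locus in LOCI:
            root = _random_seq(rng, config.barcode_length)
            per_genus: dict[str, list[tuple[str, str]]] = {}
            for genus in genera:
                founder = _mutate(root, config.inter_genus_divergence, rng)
                per_genus[genus] = [
                    (f"{genus} sp{k + 1}",
                     _to_str(_mutate(founder, config.species_divergence, rng)))
                    for k in range(config.species_per_genus)
                ]
            # Identical congeneric sequences are fine (real ITS often is);
            # a sequence shared across genera would corrupt the truth table.
            owner: dict[str, str] = {}
            for genus, specs in per_genus.items():
                for _, s in specs:
                    if owner.setdefault(s, genus) != genus:
                        ok = False
            if not ok:
                break
            true_seqs[locus] = per_genus
        if ok:
            break
    else:
        raise RuntimeError(
            "could not generate distinct reference sequences; raise the "
            "divergence or barcode length"
        )

    barcodes: dict[str, list[BarcodeRecord]] = {locus: [] for locus in LOCI}
    lineages: dict[str, Lineage] = {}
    entries = []  # (locus, index) for mislabel planting
    for locus in LOCI:
        for genus in genera:
            for species, seq in true_seqs[locus][genus]:
                tag = species.replace(" ", "_")
                bc_id = f"{tag}_{locus}"
                barcodes[locus].append(
                    BarcodeRecord(bc_id, locus, seq, plant_lineage(genus, species))
                )
                lineages[bc_id] = plant_lineage(genus, species)
                entries.append((locus, len(barcodes[locus]) - 1))

    # Contrast databases: every true plant sequence embedded in random flanks,
    # plus fungal contaminants.
    plant_records = []
    for locus in LOCI:
        for genus in genera:
            for species, seq in true_seqs[locus][genus]:
                flank5 = _to_str(_random_seq(rng, config.contrast_flank))
                flank3 = _to_str(_random_seq(rng, config.contrast_flank))
                plant_records.append(
                    ContrastRecord(
                        f"PL_{species.replace(' ', '_')}_{locus}",
                        flank5 + seq + flank3,
                        plant_lineage(genus, species),
                    )
                )
    nonplant_records = []
    contaminant_cores = []
    for i in range(config.nonplant_contaminant_count):
        genus, family, order, class_ = FUNGAL_CATALOG[i % len(FUNGAL_CATALOG)]
        core = _to_str(_random_seq(rng, config.barcode_length))
        contaminant_cores.append(core)
        flank5 = _to_str(_random_seq(rng, config.contrast_flank))
        flank3 = _to_str(_random_seq(rng, config.contrast_flank))
        nonplant_records.append(
            ContrastRecord(
                f"NP_{genus}_{i + 1}",
                flank5 + core + flank3,
                Lineage(("Fungi", "Ascomycota", class_, order, family, genus,
                         f"{genus} sp{i + 1}")),
            )
        )

    # Plant mislabels: replace the sequence of a random subset of barcodes by
    # an exact copy of another genus's plant record or a contaminant core;
    # the (now wrong) label stays.
    n_total = len(entries)
    n_mislabels = int(round(config.mislabel_rate * n_total))
    status = {key: ("correct", "") for key in entries}
    if n_mislabels:
        chosen = rng.choice(n_total, size=n_mislabels, replace=False)
        for k, entry_idx in enumerate(sorted(chosen)):
            locus, idx = entries[entry_idx]
            victim = barcodes[locus][idx]
            use_nonplant = contaminant_cores and k % 2 == 1
            if use_nonplant:
                source_seq = contaminant_cores[
                    int(rng.integers(0, len(contaminant_cores)))
                ]
                source = "non_plant"
            else:
                other = [
                    g for g in genera if g != victim.lineage.genus
                ]
                donor_genus = other[int(rng.integers(0, len(other)))]
                donors = true_seqs[locus][donor_genus]
                source_seq = donors[int(rng.integers(0, len(donors)))][1]
                source = "cross_genus"
            barcodes[locus][idx] = BarcodeRecord(
                victim.id, victim.locus, source_seq, victim.lineage
            )
            status[(locus, idx)] = ("mislabeled", source)

    truth_rows = []
    for locus, idx in entries:
        record = barcodes[locus][idx]
        st, source = status[(locus, idx)]
        truth_rows.append(
            dict(barcode_id=record.id, locus=locus,
                 genus=record.lineage.genus, status=st, source=source)
        )
    return ReferenceSet(
        barcodes=barcodes,
        plant=ContrastDatabase("plant", tuple(plant_records)),
        nonplant=ContrastDatabase("non_plant", tuple(nonplant_records)),
        lineages=lineages,
        true_sequences=true_seqs,
        truth=pd.DataFrame(truth_rows),
    )


def generate_sample_reads(
    config: SimulationConfig,
    refset: ReferenceSet,
    sample_id: str,
) -> tuple[dict[str, list[MergedRead]], pd.DataFrame]:
    """Dual-locus reads from the configured genus mixture.

    Per locus the composition is reweighted by that locus's amplification
    bias, read counts are multinomial, and each read copies a uniformly
    chosen conspecific true sequence mutated at the substitution error rate.
    Reads always derive from the *true* sequences, not from any planted
    mislabel.
    """
    composition = config.composition
    if composition is None:
        composition = {g: 1.0 / len(config.genera) for g in config.genera}
    missing = set(composition) - set(refset.true_sequences[LOCI[0]])
    if missing:
        raise ValueError(f"composition genera absent from the reference db: {missing}")
    rng = _rng(config.seed, "reads", zlib.crc32(sample_id.encode()))
    genera = sorted(composition)
    reads: dict[str, list[MergedRead]] = {locus: [] for locus in LOCI}
    truth_rows = []
    for locus in LOCI:
        bias = (config.locus_bias or {}).get(locus, {})
        weights = np.array(
            [composition[g] * bias.get(g, 1.0) for g in genera], dtype=float
        )
        if config.reads_per_locus == 0:
            continue
        weights /= weights.sum()
        counts = rng.multinomial(config.reads_per_locus, weights)
        k = 0
        for genus, n_reads in zip(genera, counts):
            templates = refset.true_sequences[locus][genus]
            for _ in range(int(n_reads)):
                species, template = templates[int(rng.integers(0, len(templates)))]
                seq = _to_str(
                    _mutate(
                        np.fromiter(
                            ("ACGT".index(c) for c in template),
                            dtype=np.int8, count=len(template),
                        ),
                        config.substitution_error_rate,
                        rng,
                    )
                )
                read_id = f"{sample_id}_{locus}_r{k:05d}"
                k += 1
                reads[locus].append(MergedRead(read_id, sample_id, locus, seq))
                truth_rows.append(
                    dict(read_id=read_id, sample_id=sample_id, locus=locus,
                         genus=genus, species=species)
                )
    return reads, pd.DataFrame(truth_rows)


def generate_provision_nutrition(
    config: SimulationConfig, n: int
) -> list[ProvisionNutrition]:
    """Zero-truncated normal protein/lipid draws with round-robin metadata."""
    if n < 1:
        raise ValueError(f"need n >= 1 samples, got {n}")
    rng = _rng(config.seed, "nutrition")
    values = {}
    for metric, mean, sd in (
        ("protein", config.protein_mean, config.protein_sd),
        ("lipid", config.lipid_mean, config.lipid_sd),
    ):
        if sd < 0:
            raise ValueError(f"negative {metric} SD")
        if sd == 0:
            values[metric] = np.full(n, mean)
        else:
            a = (0.0 - mean) / sd  # truncate at zero; moments are pre-truncation
            values[metric] = stats.truncnorm.rvs(
                a, np.inf, loc=mean, scale=sd, size=n, random_state=rng
            )
    return [
        ProvisionNutrition(
            sample_id=f"P{i + 1:04d}",
            protein=float(values["protein"][i]),
            lipid=float(values["lipid"][i]),
            site=config.sites[i % len(config.sites)],
            week=(i % config.n_weeks) + 1,
        )
        for i in range(n)
    ]


def generate_rearing_outcomes(
    config: SimulationConfig, n_per_diet: int
) -> list[RearingRecord]:
    """Stage-conditional Bernoulli rearing outcomes per diet group.

    Survival is drawn per stage conditional on reaching the prior stage, so
    the cocoon ⊇ pupated ⊇ adult ordering holds by construction. Development
    times are discrete (shifted Poisson) and unknown for stages not reached.
    """
    rng = _rng(config.seed, "rearing")
    records = []
    for diet in sorted(config.diet_survival):
        p_cocoon, p_pupate, p_adult = config.diet_survival[diet]
        for i in range(n_per_diet):
            cocoon = bool(rng.random() < p_cocoon)
            pupated = bool(cocoon and rng.random() < p_pupate)
            adult = bool(pupated and rng.random() < p_adult)
            records.append(
                RearingRecord(
                    individual_id=f"{diet}_{i + 1:03d}",
                    diet=diet,
                    cocoon_completed=cocoon,
                    pupated=pupated,
                    adult_survived=adult,
                    hatch_to_cocoon_days=float(10 + rng.poisson(4)) if cocoon else None,
                    cocoon_to_pupation_days=float(30 + rng.poisson(10)) if pupated else None,
                    starting_mass_mg=float(max(1.0, rng.normal(15.0, 5.0))),
                    day_of_graft=(i % 7) + 1,
                )
            )
    return records


def write_fixture_set(
    config: SimulationConfig,
    out_dir,
    n_samples: int = 2,
    n_nutrition: int = 59,
    n_per_diet: int = 19,
    sample_prefix: str = "WP",
):
    """Write a complete desk-scale fixture set in the pipeline's own formats.

    Emits per-locus reference FASTA + lineage TSV, plant/non-plant contrast
    FASTA + lineage TSVs, per-sample per-locus read FASTA with a manifest,
    nutrition and rearing TSVs, and truth tables. Returns the manifest path.
    """
    from pathlib import Path

    from .io import (
        Manifest,
        ManifestEntry,
        write_fasta,
        write_manifest,
        write_nutrition_table,
        write_rearing_table,
        write_table,
    )
    from .taxonomy import write_lineage_table

    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    refset = generate_reference_db(config)
    for locus in LOCI:
        write_fasta(
            ((b.id, b.sequence) for b in refset.barcodes[locus]),
            out_dir / f"references_{locus}.fasta",
        )
    write_lineage_table(refset.lineages, out_dir / "lineages.tsv")
    write_fasta(
        ((r.id, r.sequence) for r in refset.plant.records),
        out_dir / "plant_contrast.fasta",
    )
    write_lineage_table(
        {r.id: r.lineage for r in refset.plant.records if r.lineage is not None},
        out_dir / "plant_lineages.tsv",
    )
    write_fasta(
        ((r.id, r.sequence) for r in refset.nonplant.records),
        out_dir / "nonplant_contrast.fasta",
    )
    write_lineage_table(
        {r.id: r.lineage for r in refset.nonplant.records if r.lineage is not None},
        out_dir / "nonplant_lineages.tsv",
    )
    write_table(refset.truth, out_dir / "truth_barcodes.tsv")

    entries = []
    truth_frames = []
    for i in range(n_samples):
        sample_id = f"{sample_prefix}{i + 1:02d}"
        reads, truth = generate_sample_reads(config, refset, sample_id)
        truth_frames.append(truth)
        for locus in LOCI:
            reads_path = out_dir / f"reads_{sample_id}_{locus}.fasta"
            write_fasta(((r.id, r.sequence) for r in reads[locus]), reads_path)
            entries.append(ManifestEntry(sample_id, locus, reads_path))
    manifest = Manifest(tuple(entries))
    manifest_path = out_dir / "manifest.tsv"
    write_manifest(manifest, manifest_path)
    if truth_frames:
        write_table(pd.concat(truth_frames, ignore_index=True),
                    out_dir / "truth_reads.tsv")
    composition = config.composition or {
        g: 1.0 / len(config.genera) for g in config.genera
    }
    write_table(
        pd.DataFrame(
            dict(genus=sorted(composition),
                 proportion=[composition[g] for g in sorted(composition)])
        ),
        out_dir / "truth_composition.tsv",
    )
    write_nutrition_table(
        generate_provision_nutrition(config, n_nutrition), out_dir / "nutrition.tsv"
    )
    write_rearing_table(
        generate_rearing_outcomes(config, n_per_diet), out_dir / "rearing.tsv"
    )
    return manifest_path


def implied_ratio_mean(
    config: SimulationConfig, n: int = 10_000, grid: int = 200_001
) -> float:
    """Predictive mean of the per-sample P:L ratio for a sample of size n.

    Protein and lipid are independent, so E[P/L] = E[P]·E[1/L] — but the
    exact E[1/L] diverges (logarithmically) for a zero-truncated normal whose
    density is positive at zero. The finite-sample prediction therefore cuts
    the lipid integral at the 1/n tail quantile: the region a sample of size
    n explores. Computed by log-spaced quadrature.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    mu_p, sd_p = config.protein_mean, config.protein_sd
    mu_l, sd_l = config.lipid_mean, config.lipid_sd
    if sd_p == 0:
        ep = mu_p
    else:
        ep = float(
            stats.truncnorm.mean((0 - mu_p) / sd_p, np.inf, loc=mu_p, scale=sd_p)
        )
    if sd_l == 0:
        return ep / mu_l
    a = (0.0 - mu_l) / sd_l
    lo = float(stats.truncnorm.ppf(1.0 / n, a, np.inf, loc=mu_l, scale=sd_l))
    lo = max(lo, 1e-9)
    x = np.geomspace(lo, mu_l + 12 * sd_l, grid)
    pdf = stats.truncnorm.pdf(x, a, np.inf, loc=mu_l, scale=sd_l)
    einv_l = float(np.trapezoid(pdf / x, x))
    return ep * einv_l
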