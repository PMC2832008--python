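"""Ground-truthed synthetic inputs for the whole pipeline.

The generator emulates the statistical structure of the study system: a
nodule-cDNA two-channel array of 2366 probes hybridized against a common
reference over a 10-point infection time course (0-29 dpi), a 15-genotype
Fix- mutant panel blocked at four archetypal developmental points, DAPI
flow-cytometry ploidy histograms spanning 2C-64C, bacteroid length samples
(cultured rods vs elongated differentiated bacteroids) and efficiency-
corrected qPCR crossing-point tables.  Every emitted record carries a truth
label so that downstream recovery can be scored.

All generators are pure functions of (config, seed).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from .arrays import SpotTable, SPOT_COLUMNS
from .de import stage_for_dpi
from .profiles import DEFAULT_PROFILE_SHAPES

# ---------------------------------------------------------------------------
# Archetypes
# ---------------------------------------------------------------------------

#: Expression/phenotype archetypes: where a genotype is blocked.
ARCHETYPE_WILD_TYPE = "wild_type"  # functional symbiosis, both waves
ARCHETYPE_FIX_MINUS_DIFFERENTIATED = "fix_minus_differentiated"  # both waves, no fixation
ARCHETYPE_BACTEROID_BLOCKED = "bacteroid_blocked"  # wave 1 only (bacA-like)
ARCHETYPE_INFECTED_UNDIFFERENTIATED = "infected_undifferentiated"  # root-like, IT network
ARCHETYPE_UNINFECTED = "uninfected"  # root-like, empty nodules
ARCHETYPE_ROOT = "root"  # uninoculated root control

ROOT_LIKE_ARCHETYPES = (ARCHETYPE_INFECTED_UNDIFFERENTIATED, ARCHETYPE_UNINFECTED)

#: The fifteen mutant genotypes of the study and their archetypes: ten
#: senescence-prone but fully differentiated Fix- mutants, bacA (bacteroids
#: fail to differentiate), the allelic TR3/TE7 (infection threads only) and
#: the uninfected V1/exoY.
DEFAULT_MUTANT_ARCHETYPES: dict[str, str] = {
    "TR36": ARCHETYPE_FIX_MINUS_DIFFERENTIATED,
    "TR183": ARCHETYPE_FIX_MINUS_DIFFERENTIATED,
    "TRV36": ARCHETYPE_FIX_MINUS_DIFFERENTIATED,
    "TRV43": ARCHETYPE_FIX_MINUS_DIFFERENTIATED,
    "nifH": ARCHETYPE_FIX_MINUS_DIFFERENTIATED,
    "nifA": ARCHETYPE_FIX_MINUS_DIFFERENTIATED,
    "fixG": ARCHETYPE_FIX_MINUS_DIFFERENTIATED,
    "fixJ": ARCHETYPE_FIX_MINUS_DIFFERENTIATED,
    "fixK": ARCHETYPE_FIX_MINUS_DIFFERENTIATED,
    "lpsB": ARCHETYPE_FIX_MINUS_DIFFERENTIATED,
    "bacA": ARCHETYPE_BACTEROID_BLOCKED,
    "TR3": ARCHETYPE_INFECTED_UNDIFFERENTIATED,
    "TE7": ARCHETYPE_INFECTED_UNDIFFERENTIATED,
    "V1": ARCHETYPE_UNINFECTED,
    "exoY": ARCHETYPE_UNINFECTED,
}

#: Ploidy mixtures per archetype.  Roots (and nodules without symbiotic-cell
#: differentiation) only reach 8C; differentiated nodules span 2C-64C with
#: enough high-ploidy mass for an endoreduplication index well above 15.
DEFAULT_PLOIDY_MIXTURES: dict[str, dict[int, float]] = {
    ARCHETYPE_ROOT: {2: 0.60, 4: 0.30, 8: 0.10},
    ARCHETYPE_WILD_TYPE: {2: 0.30, 4: 0.25, 8: 0.15, 16: 0.12, 32: 0.10, 64: 0.08},
    ARCHETYPE_FIX_MINUS_DIFFERENTIATED: {2: 0.30, 4: 0.25, 8: 0.15, 16: 0.12, 32: 0.10, 64: 0.08},
    ARCHETYPE_BACTEROID_BLOCKED: {2: 0.32, 4: 0.26, 8: 0.16, 16: 0.11, 32: 0.09, 64: 0.06},
    ARCHETYPE_INFECTED_UNDIFFERENTIATED: {2: 0.58, 4: 0.31, 8: 0.11},
    ARCHETYPE_UNINFECTED: {2: 0.61, 4: 0.29, 8: 0.10},
}

#: Bacteroid length models (micrometres).  Cultured S. meliloti are 1-2 um
#: rods; terminally differentiated bacteroids are 4-5x longer on average.
DEFAULT_BACTEROID_MODELS: dict[str, tuple[str, float, float]] = {
    "cultured": ("uniform", 1.0, 2.0),
    "undifferentiated": ("uniform", 1.0, 2.0),
    "differentiated": ("normal", 6.75, 0.8),
}

PLOIDY_CLASSES = (2, 4, 8, 16, 32, 64)


class GeneratorConfigError(ValueError):
    """Invalid generator configuration."""


# ---------------------------------------------------------------------------
# Configuration
# ---------------------------------------------------------------------------


@dataclass
class QpcrParams:
    """Planted qPCR conditions: per-transcript fold changes across samples,
    amplification efficiencies (base E, 2.0 = perfect doubling), baseline
    crossing points and CP noise."""

    folds: dict[str, dict[str, float]] = field(
        default_factory=lambda: {
            "wave1_marker": {"root": 1.0, "incipient": 8.0, "nodule": 8.0},
            "wave2_marker": {"root": 1.0, "incipient": 1.0, "nodule": 16.0},
            "flat_marker": {"root": 1.0, "incipient": 1.0, "nodule": 1.0},
        }
    )
    efficiencies: dict[str, float] = field(default_factory=dict)
    reference_transcript: str = "histone_h3"
    default_efficiency: float = 2.0
    baseline_cp: float = 22.0
    reference_cp: float = 18.0
    cp_noise_sd: float = 0.0
    input_shift_sd: float = 0.3
    replicates: int = 3

    def efficiency_of(self, transcript: str) -> float:
        return self.efficiencies.get(transcript, self.default_efficiency)


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic arrays, histograms and qPCR tables.

    Counts mirror the probe set of the study: 2366 genes of which 520 are
    planted as differential (65 per temporal profile) and 1500 as invariant,
    anchored to a constitutive control spotted 12 times per array.
    """

    n_genes: int = 2366
    n_de: int = 520
    n_invariant: int = 1500
    anchor_id: str = "mtc27"
    replicate_spots: int = 12
    timepoints: tuple[float, ...] = (0, 2, 4, 6, 7, 8, 10, 13, 20, 29)
    arrays_per_timepoint: int = 3
    arrays_per_genotype: int = 3
    profile_shapes: dict[int, tuple[float, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_PROFILE_SHAPES)
    )
    de_effect: float = 3.0  # log2 fold step between stage tiers
    noise_sd: float = 0.25  # log2 per-spot channel noise on the ratio
    background_sd: float = 0.6  # per-array biological wobble of background genes
    invariant_baseline_sd: float = 0.5
    background_baseline_sd: float = 1.0
    array_scale_sd: float = 0.4  # log2 sd of the global per-array intensity factor
    reference_intensity: float = 1000.0
    reference_sd: float = 0.4  # log2 spot-to-spot variation of the reference channel
    mutant_archetypes: dict[str, str] = field(
        default_factory=lambda: dict(DEFAULT_MUTANT_ARCHETYPES)
    )
    n_common: int = 20
    # log2 induction of the common set in mutant nodules: 4-fold, clearly
    # below the 8-fold nodule-specific steps yet detectable at p<0.01 with
    # 3 biological replicates (the property that defines these genes)
    common_induction: float = 2.0
    ploidy_mixtures: dict[str, dict[int, float]] = field(
        default_factory=lambda: {k: dict(v) for k, v in DEFAULT_PLOIDY_MIXTURES.items()}
    )
    ploidy_anchor: float = 100.0  # fluorescence position of the 2C peak (a.u.)
    ploidy_cv: float = 0.05  # per-peak coefficient of variation
    ploidy_replicates: int = 3
    ploidy_bin_width: float = 4.0
    ploidy_max_fluorescence: float = 9600.0
    bacteroid_length_models: dict[str, tuple[str, float, float]] = field(
        default_factory=lambda: dict(DEFAULT_BACTEROID_MODELS)
    )
    qpcr: QpcrParams = field(default_factory=QpcrParams)
    seed: int = 0

    # -- validation ---------------------------------------------------------

    def validate(self) -> None:
        if self.n_de + self.n_invariant > self.n_genes:
            raise GeneratorConfigError(
                f"n_de ({self.n_de}) + n_invariant ({self.n_invariant}) exceeds "
                f"n_genes ({self.n_genes})"
            )
        for name in ("noise_sd", "background_sd", "invariant_baseline_sd",
                     "background_baseline_sd", "array_scale_sd", "reference_sd"):
            if getattr(self, name) < 0:
                raise GeneratorConfigError(f"{name} must be >= 0")
        if self.replicate_spots < 1:
            raise GeneratorConfigError("replicate_spots must be >= 1")
        shapes = list(self.profile_shapes.values())
        if len({tuple(s) for s in shapes}) != len(shapes):
            raise GeneratorConfigError("profile shapes must be pairwise distinct")
        for name, mixture in self.ploidy_mixtures.items():
            if not mixture:
                raise GeneratorConfigError(f"ploidy mixture {name!r} is empty")
            total = sum(mixture.values())
            if abs(total - 1.0) > 1e-9:
                raise GeneratorConfigError(
                    f"ploidy mixture {name!r} sums to {total}, not 1"
                )
            unknown = set(mixture) - set(PLOIDY_CLASSES)
            if unknown:
                raise GeneratorConfigError(f"unknown ploidy classes {unknown}")
        for t, e in {**self.qpcr.efficiencies,
                     "default": self.qpcr.default_efficiency}.items():
            if not (1.0 < e <= 2.0):
                raise GeneratorConfigError(
                    f"amplification efficiency for {t!r} is {e}; must be in (1, 2]"
                )

    # -- serialization ------------------------------------------------------

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "GeneratorConfig":
        d = yaml.safe_load(Path(path).read_text())
        if "qpcr" in d and isinstance(d["qpcr"], dict):
            d["qpcr"] = QpcrParams(**d["qpcr"])
        if "timepoints" in d:
            d["timepoints"] = tuple(d["timepoints"])
        for key in ("profile_shapes",):
            if key in d:
                d[key] = {int(k): tuple(v) for k, v in d[key].items()}
        if "ploidy_mixtures" in d:
            d["ploidy_mixtures"] = {
                k: {int(c): f for c, f in v.items()} for k, v in d["ploidy_mixtures"].items()
            }
        if "bacteroid_length_models" in d:
            d["bacteroid_length_models"] = {
                k: tuple(v) for k, v in d["bacteroid_length_models"].items()
            }
        return cls(**d)

    # -- derived quantities -------------------------------------------------

    def profile_templates(self) -> dict[int, np.ndarray]:
        """Stage-mean triples (log2) = tier shape x de_effect."""
        return {
            p: np.asarray(shape, dtype=float) * self.de_effect
            for p, shape in self.profile_shapes.items()
        }

    def gene_ids(self) -> list[str]:
        width = len(str(self.n_genes))
        return [f"g{i:0{width}d}" for i in range(1, self.n_genes + 1)]


@dataclass
class GeneratorTruth:
    """Planted labels for every generated record."""

    gene_labels: dict[str, str] = field(default_factory=dict)  # profile id / invariant / background / common
    sample_stages: dict[str, str] = field(default_factory=dict)
    genotype_archetypes: dict[str, str] = field(default_factory=dict)
    ploidy_mixtures: dict[str, dict[int, float]] = field(default_factory=dict)
    bacteroid_models: dict[str, tuple[str, float, float]] = field(default_factory=dict)
    qpcr_folds: dict[str, dict[str, float]] = field(default_factory=dict)
    common_genes: list[str] = field(default_factory=list)

    def de_genes(self) -> list[str]:
        return [g for g, l in self.gene_labels.items() if l.startswith("profile")]

    def profile_of(self, gene: str) -> int | None:
        label = self.gene_labels.get(gene, "")
        return int(label.removeprefix("profile")) if label.startswith("profile") else None

    def invariant_genes(self) -> list[str]:
        return [g for g, l in self.gene_labels.items() if l == "invariant"]

    def to_json(self, path: str | Path) -> None:
        d = {
            "gene_labels": self.gene_labels,
            "sample_stages": self.sample_stages,
            "genotype_archetypes": self.genotype_archetypes,
            "ploidy_mixtures": {
                k: {str(c): f for c, f in v.items()} for k, v in self.ploidy_mixtures.items()
            },
            "bacteroid_models": {k: list(v) for k, v in self.bacteroid_models.items()},
            "qpcr_folds": self.qpcr_folds,
            "common_genes": self.common_genes,
        }
        Path(path).write_text(json.dumps(d, indent=1))

    @classmethod
    def from_json(cls, path: str | Path) -> "GeneratorTruth":
        d = json.loads(Path(path).read_text())
        return cls(
            gene_labels=d["gene_labels"],
            sample_stages=d["sample_stages"],
            genotype_archetypes=d["genotype_archetypes"],
            ploidy_mixtures={
                k: {int(c): f for c, f in v.items()} for k, v in d["ploidy_mixtures"].items()
            },
            bacteroid_models={k: tuple(v) for k, v in d["bacteroid_models"].items()},
            qpcr_folds=d["qpcr_folds"],
            common_genes=list(d["common_genes"]),
        )


# ---------------------------------------------------------------------------
# Gene-role assignment (shared between the time course and the mutant panel)
# ---------------------------------------------------------------------------


def _assign_gene_roles(config: GeneratorConfig, rng: np.random.Generator):
    """Split genes into DE (with a planted profile), invariant, common and
    background pools, and draw their baselines.

    Invariant baselines are median-centred so that the invariant-set median
    log2 ratio is exactly 0, which pins the normalization scale to the
    per-array global factor.
    """
    genes = config.gene_ids()
    order = rng.permutation(len(genes))
    profile_ids = sorted(config.profile_shapes)
    labels: dict[str, str] = {}
    de_genes = [genes[i] for i in order[: config.n_de]]
    inv_genes = [genes[i] for i in order[config.n_de : config.n_de + config.n_invariant]]
    rest = [genes[i] for i in order[config.n_de + config.n_invariant :]]
    common = rest[: min(config.n_common, len(rest))]
    background = rest
    for j, g in enumerate(de_genes):
        labels[g] = f"profile{profile_ids[j % len(profile_ids)]}"
    for g in inv_genes:
        labels[g] = "invariant"
    for g in background:
        labels[g] = "background"
    for g in common:
        labels[g] = "common"

    inv_base = rng.normal(0.0, config.invariant_baseline_sd, size=len(inv_genes))
    # centre so the *linear*-scale median ratio of the invariant set is 1,
    # which pins the normalization scale to the per-array global factor
    if len(inv_base):
        inv_base -= np.log2(np.median(np.exp2(inv_base)))
    baselines = {g: 0.0 for g in genes}
    baselines.update(dict(zip(inv_genes, inv_base)))
    bg_base = rng.normal(0.0, config.background_baseline_sd, size=len(background))
    baselines.update(dict(zip(background, bg_base)))
    templates = config.profile_templates()
    return labels, baselines, templates, de_genes, inv_genes, background, common


def _emit_array(
    config: GeneratorConfig,
    rng: np.random.Generator,
    array_id: str,
    genotype: str,
    dpi: float | None,
    gene_log2: Mapping[str, float],
) -> SpotTable:
    """Turn per-gene expected log2 ratios into a two-channel spot table."""
    genes = config.gene_ids()
    n_anchor = config.replicate_spots
    ids = genes + [config.anchor_id] * n_anchor
    reps = [0] * len(genes) + list(range(n_anchor))
    log2r = np.array([gene_log2[g] for g in genes] + [0.0] * n_anchor)
    array_scale = rng.normal(0.0, config.array_scale_sd)
    ref = config.reference_intensity * np.exp2(
        rng.normal(0.0, config.reference_sd, size=len(ids))
    )
    noise = rng.normal(0.0, config.noise_sd, size=len(ids)) if config.noise_sd > 0 else 0.0
    sample = ref * np.exp2(log2r + array_scale + noise)
    data = pd.DataFrame(
        {
            "spot_id": [f"{array_id}_s{i:05d}" for i in range(len(ids))],
            "gene_id": ids,
            "replicate_index": reps,
            "sample_intensity": sample,
            "reference_intensity": ref,
        }
    )[list(SPOT_COLUMNS)]
    return SpotTable(array_id=array_id, data=data, genotype=genotype, dpi=dpi)


# ---------------------------------------------------------------------------
# Time course
# ---------------------------------------------------------------------------


def simulate_timecourse(
    config: GeneratorConfig, seed: int | None = None
) -> tuple[dict[str, SpotTable], GeneratorTruth]:
    """Spot tables for the wild-type infection time course.

    DE genes follow their planted profile's stage means, invariant genes keep
    a constant sample/reference ratio, background genes wobble around a
    gene-specific baseline with no stage structure, and the anchor gene is
    emitted with ``replicate_spots`` spots per array.

    Gene roles and baselines are a function of the seed alone, so the time
    course and the mutant panel generated from the same seed share the same
    planted gene structure (as the study's single probe set does); only the
    measurement noise streams differ.
    """
    config.validate()
    base_seed = config.seed if seed is None else seed
    labels, baselines, templates, de_genes, _, background, common = _assign_gene_roles(
        config, np.random.default_rng(base_seed)
    )
    rng = np.random.default_rng([base_seed, 1])
    stage_index = {"roots": 0, "incipient": 1, "nodules": 2}
    truth = GeneratorTruth(gene_labels=labels, common_genes=common)
    # common genes carry no planted structure in the time course
    for g in common:
        truth.gene_labels[g] = "background"
    tables: dict[str, SpotTable] = {}
    for dpi in config.timepoints:
        stage = stage_for_dpi(dpi)
        si = stage_index[stage]
        for rep in range(1, config.arrays_per_timepoint + 1):
            array_id = f"wild_type__{dpi:g}dpi__r{rep}"
            gene_log2 = dict(baselines)
            for g in de_genes:
                gene_log2[g] = templates[truth.profile_of(g)][si]
            if config.background_sd > 0 and background:
                wobble = rng.normal(0.0, config.background_sd, size=len(background))
                for g, w in zip(background, wobble):
                    gene_log2[g] = baselines[g] + w
            tables[array_id] = _emit_array(
                config, rng, array_id, "wild_type", dpi, gene_log2
            )
            truth.sample_stages[array_id] = stage
    return tables, truth


# ---------------------------------------------------------------------------
# Mutant panel
# ---------------------------------------------------------------------------

#: Which stage column of the profile template each archetype expresses, per
#: profile id.  None means "root column for every profile".
def _archetype_stage_index(archetype: str, profile_id: int) -> int:
    nodule, root = 2, 0
    if archetype in (ARCHETYPE_WILD_TYPE, ARCHETYPE_FIX_MINUS_DIFFERENTIATED):
        return nodule
    if archetype == ARCHETYPE_BACTEROID_BLOCKED:
        # first wave (profiles 5-6) at nodule levels, everything else root-like
        return nodule if profile_id in (5, 6) else root
    if archetype in ROOT_LIKE_ARCHETYPES or archetype == ARCHETYPE_ROOT:
        return root
    raise GeneratorConfigError(f"unknown archetype {archetype!r}")


def simulate_mutant_panel(
    config: GeneratorConfig,
    seed: int | None = None,
    include_roots: bool = True,
    include_wild_type: bool = True,
) -> tuple[dict[str, SpotTable], GeneratorTruth]:
    """Spot tables for the Fix- mutant panel (plus root and wild-type controls).

    Wild-type-like genotypes express profile 5-8 genes at nodule levels,
    the bacA-like archetype expresses profiles 5-6 at nodule levels and 7-8
    at root levels, and root-like archetypes keep all DE genes at root levels
    but mildly induce the planted common-gene set.
    """
    config.validate()
    for genotype, archetype in config.mutant_archetypes.items():
        _archetype_stage_index(archetype, 5)  # raises on unknown names
    base_seed = config.seed if seed is None else seed
    labels, baselines, templates, de_genes, _, background, common = _assign_gene_roles(
        config, np.random.default_rng(base_seed)
    )
    rng = np.random.default_rng([base_seed, 2])
    truth = GeneratorTruth(gene_labels=labels, common_genes=common)
    genotypes = dict(config.mutant_archetypes)
    if include_wild_type:
        genotypes.setdefault("wild_type", ARCHETYPE_WILD_TYPE)
    if include_roots:
        genotypes.setdefault("root", ARCHETYPE_ROOT)
    tables: dict[str, SpotTable] = {}
    for genotype, archetype in genotypes.items():
        truth.genotype_archetypes[genotype] = archetype
        dpi = 0.0 if archetype == ARCHETYPE_ROOT else 21.0
        for rep in range(1, config.arrays_per_genotype + 1):
            array_id = f"{genotype}__{dpi:g}dpi__r{rep}"
            gene_log2 = dict(baselines)
            for g in de_genes:
                p = truth.profile_of(g)
                gene_log2[g] = templates[p][_archetype_stage_index(archetype, p)]
            if archetype != ARCHETYPE_ROOT:
                for g in common:
                    gene_log2[g] = baselines[g] + config.common_induction
            if config.background_sd > 0:
                others = [g for g in background if g not in common]
                wobble = rng.normal(0.0, config.background_sd, size=len(others))
                for g, w in zip(others, wobble):
                    gene_log2[g] = baselines[g] + w
            tables[array_id] = _emit_array(config, rng, array_id, genotype, dpi, gene_log2)
            truth.sample_stages[array_id] = (
                "roots" if archetype == ARCHETYPE_ROOT else "nodules"
            )
    return tables, truth


# ---------------------------------------------------------------------------
# Ploidy histograms
# ---------------------------------------------------------------------------


@dataclass
class SimulatedHistogram:
    bin_centers: np.ndarray
    counts: np.ndarray
    sample_id: str
    replicate: int


def simulate_ploidy(
    config: GeneratorConfig,
    archetype: str,
    n_nuclei: int = 10000,
    seed: int | None = None,
) -> tuple[list[SimulatedHistogram], GeneratorTruth]:
    """DAPI fluorescence histograms for one sample, 3 replicates.

    Nuclei are drawn from a mixture of peaks at anchor x 2^j with a
    per-peak coefficient of variation, then binned on a fixed linear grid.
    """
    config.validate()
    if archetype not in config.ploidy_mixtures:
        raise GeneratorConfigError(f"no ploidy mixture for archetype {archetype!r}")
    if n_nuclei < 100:
        raise GeneratorConfigError("n_nuclei must be >= 100")
    mixture = config.ploidy_mixtures[archetype]
    rng = np.random.default_rng(config.seed if seed is None else seed)
    edges = np.arange(0.0, config.ploidy_max_fluorescence + config.ploidy_bin_width,
                      config.ploidy_bin_width)
    centers = 0.5 * (edges[:-1] + edges[1:])
    classes = sorted(mixture)
    probs = np.array([mixture[c] for c in classes])
    hists = []
    for rep in range(1, config.ploidy_replicates + 1):
        draws = rng.choice(len(classes), size=n_nuclei, p=probs)
        peak = config.ploidy_anchor * np.array(
            [c / 2.0 for c in classes], dtype=float
        )[draws] * 1.0
        fluor = rng.normal(peak, np.maximum(config.ploidy_cv * peak, 1e-12))
        fluor = np.clip(fluor, edges[0] + 1e-9, edges[-1] - 1e-9)
        counts, _ = np.histogram(fluor, bins=edges)
        hists.append(
            SimulatedHistogram(
                bin_centers=centers, counts=counts, sample_id=archetype, replicate=rep
            )
        )
    truth = GeneratorTruth(ploidy_mixtures={archetype: dict(mixture)})
    return hists, truth


# ---------------------------------------------------------------------------
# Bacteroid lengths
# ---------------------------------------------------------------------------


def simulate_bacteroid_lengths(
    config: GeneratorConfig, archetype: str, n: int = 1000, seed: int | None = None
) -> np.ndarray:
    """Bacteroid/bacterium length sample in micrometres."""
    config.validate()
    if archetype not in config.bacteroid_length_models:
        raise GeneratorConfigError(f"unknown bacteroid archetype {archetype!r}")
    if n < 10:
        raise GeneratorConfigError("n must be >= 10")
    family, a, b = config.bacteroid_length_models[archetype]
    rng = np.random.default_rng(config.seed if seed is None else seed)
    if family == "uniform":
        return rng.uniform(a, b, size=n)
    if family == "normal":
        lengths = rng.normal(a, b, size=n)
        return np.abs(lengths)  # lengths are positive; reflect the rare negatives
    raise GeneratorConfigError(f"unknown length distribution family {family!r}")


# ---------------------------------------------------------------------------
# qPCR
# ---------------------------------------------------------------------------


def simulate_qpcr(
    config: GeneratorConfig, seed: int | None = None
):
    """Crossing-point tables consistent with planted fold changes under the
    efficiency-corrected (Pfaffl) model, 3 biological replicates.

    Per replicate a random cDNA input shift moves all of that replicate's CP
    values together; the reference transcript tracks input only, so the
    target/reference contrast recovers the planted folds.
    """
    from .qpcr import QpcrDataset  # local import to avoid a cycle

    config.validate()
    q = config.qpcr
    rng = np.random.default_rng(config.seed if seed is None else seed)
    samples = sorted({s for folds in q.folds.values() for s in folds})
    rows = []
    for rep in range(1, q.replicates + 1):
        for sample in samples:
            shift = rng.normal(0.0, q.input_shift_sd) if q.input_shift_sd > 0 else 0.0
            e_ref = q.efficiency_of(q.reference_transcript)
            ref_cp = q.reference_cp + shift
            if q.cp_noise_sd > 0:
                ref_cp += rng.normal(0.0, q.cp_noise_sd)
            rows.append((q.reference_transcript, sample, rep, ref_cp))
            for transcript, folds in q.folds.items():
                e = q.efficiency_of(transcript)
                # fold f relative to the fold-1 calibrator: CP drops by log_E(f)
                cp = q.baseline_cp - np.log(folds[sample]) / np.log(e) + shift
                if q.cp_noise_sd > 0:
                    cp += rng.normal(0.0, q.cp_noise_sd)
                rows.append((transcript, sample, rep, cp))
    cp = pd.DataFrame(rows, columns=["transcript", "sample", "replicate", "cp"])
    efficiencies = {t: q.efficiency_of(t) for t in list(q.folds) + [q.reference_transcript]}
    truth = GeneratorTruth(qpcr_folds={t: dict(f) for t, f in q.folds.items()})
    return QpcrDataset(cp=cp, efficiencies=efficiencies,
                       reference_transcript=q.reference_transcript), truth


# ---------------------------------------------------------------------------
# Annotations
# ---------------------------------------------------------------------------


def simulate_annotations(
    config: GeneratorConfig, truth: GeneratorTruth, seed: int | None = None
) -> pd.DataFrame:
    """Per-gene secretome annotation flags with planted enrichment.

    Genes of the activation-wave profiles (5-8) are secretory-pathway rich
    (about half carry a signal peptide, most of those shorter than 220 aa),
    matching the enrichment the analysis is meant to detect; the rest of the
    probe set gets background rates.
    """
    rng = np.random.default_rng(config.seed + 1 if seed is None else seed)
    rows = []
    wave_profiles = {5, 6, 7, 8}
    for gene in config.gene_ids():
        profile = truth.profile_of(gene)
        in_wave = profile in wave_profiles
        u = rng.random()
        sp, tm, sys = False, 0, False
        if in_wave:
            if u < 0.04:
                sys = True
            elif u < 0.12:
                tm = int(rng.integers(1, 8))
            elif u < 0.62:
                sp = True
        else:
            if u < 0.02:
                sys = True
            elif u < 0.11:
                tm = int(rng.integers(1, 8))
            elif u < 0.28:
                sp = True
        if sp:
            peptide = rng.random() < (0.75 if in_wave else 0.35)
            length = int(rng.integers(60, 220)) if peptide else int(rng.integers(220, 700))
        else:
            length = int(rng.integers(100, 900))
        rows.append((gene, sp, tm, sys, length))
    rows.append((config.anchor_id, False, 0, False, 300))
    return pd.DataFrame(
        rows,
        columns=["gene_id", "signal_peptide", "tm_domain_count",
                 "secretory_system", "length_aa"],
    )


# ---------------------------------------------------------------------------
# File emission
# ---------------------------------------------------------------------------


def write_histograms(hists: Sequence[SimulatedHistogram], outdir: str | Path) -> list[Path]:
    """Two-column comma-separated (bin_center,count) files, one per replicate."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = []
    for h in hists:
        path = outdir / f"{h.sample_id}__rep{h.replicate}.csv"
        pd.DataFrame({"bin_center": h.bin_centers, "count": h.counts}).to_csv(
            path, index=False
        )
        paths.append(path)
    return paths


def read_histogram(path: str | Path):
    from .differentiation import PloidyHistogram

    path = Path(path)
    df = pd.read_csv(path)
    stem = path.stem
    sample_id, _, rep = stem.partition("__rep")
    return PloidyHistogram(
        bin_centers=df["bin_center"].to_numpy(dtype=float),
        counts=df["count"].to_numpy(dtype=float),
        sample_id=sample_id or stem,
        replicate=int(rep) if rep.isdigit() else 0,
    )
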