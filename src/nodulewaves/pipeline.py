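"""End-to-end orchestration: simulate inputs, run every analysis stage in
order and emit a machine-readable run report.

Stage order: normalize -> differential expression -> temporal profiles ->
secretome enrichment -> wave scoring -> ploidy/bacteroid differentiation ->
mutant classification -> (optional) qPCR -> report.  Any stage error aborts
the run with the failing stage named.
"""

from __future__ import annotations

import importlib.resources
import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import arrays as arr
from . import classify as cls
from . import de
from . import differentiation as diff
from . import profiles as prof
from . import qpcr as qp
from . import secretome as sec
from . import synthetic as syn

__version__ = "0.1.0"

log = logging.getLogger("nodulewaves")


class PipelineError(RuntimeError):
    """A stage failed; carries the stage name."""

    def __init__(self, stage: str, message: str):
        self.stage = stage
        super().__init__(f"stage {stage!r}: {message}")


@dataclass
class PipelineConfig:
    """Paths and the analysis constants of the study.

    Thresholds default to the study's printed decision rules: raw p < 0.01
    for differential expression, 8 temporal profiles, 3 sample stages, a
    2-fold (1.0 log2) wave-activation threshold, EI bounds 2 and 15, a 2.5x
    bacteroid length-fold threshold and 1500 invariant genes.
    """

    input_dir: str = "inputs"
    output_dir: str = "results"
    alpha: float = 0.01
    k_profiles: int = 8
    k_sample_clusters: int = 3
    wave_threshold: float = 1.0
    ei_low: float = 2.0
    ei_high: float = 15.0
    bacteroid_fold_threshold: float = 2.5
    n_invariant: int = 1500
    anchor_id: str = "mtc27"
    ploidy_anchor: float = 100.0
    ploidy_occupancy_floor: float = 0.5
    seed: int = 0

    def validate(self) -> None:
        for name in ("alpha", "wave_threshold", "ei_low", "ei_high",
                     "bacteroid_fold_threshold", "ploidy_anchor"):
            if getattr(self, name) <= 0:
                raise PipelineError("config", f"{name} must be positive")

    def to_yaml(self, path: str | Path) -> None:
        Path(path).write_text(yaml.safe_dump(asdict(self), sort_keys=False))

    @classmethod
    def from_yaml(cls_, path: str | Path) -> "PipelineConfig":
        return cls_(**yaml.safe_load(Path(path).read_text()))


# ---------------------------------------------------------------------------
# Input generation
# ---------------------------------------------------------------------------

#: Histology evidence per archetype: (infected, infection-thread network,
#: nitrogen fixing).
_ARCHETYPE_HISTOLOGY = {
    syn.ARCHETYPE_WILD_TYPE: (True, True, True),
    syn.ARCHETYPE_FIX_MINUS_DIFFERENTIATED: (True, True, False),
    syn.ARCHETYPE_BACTEROID_BLOCKED: (True, True, False),
    syn.ARCHETYPE_INFECTED_UNDIFFERENTIATED: (True, True, False),
    syn.ARCHETYPE_UNINFECTED: (False, False, False),
}

#: Bacteroid length model per archetype (None: no bacteria to isolate).
_ARCHETYPE_BACTEROIDS = {
    syn.ARCHETYPE_WILD_TYPE: "differentiated",
    syn.ARCHETYPE_FIX_MINUS_DIFFERENTIATED: "differentiated",
    syn.ARCHETYPE_BACTEROID_BLOCKED: "undifferentiated",
    syn.ARCHETYPE_INFECTED_UNDIFFERENTIATED: "undifferentiated",
    syn.ARCHETYPE_UNINFECTED: None,
}


def simulate_inputs(
    gen_config: syn.GeneratorConfig,
    outdir: str | Path,
    seed: int | None = None,
    n_nuclei: int = 10000,
    n_lengths: int = 1000,
) -> Path:
    """Write the full set of pipeline inputs (arrays, histograms, lengths,
    annotations, histology, qPCR and truth files) under ``outdir``."""
    outdir = Path(outdir)
    seed = gen_config.seed if seed is None else seed
    (outdir / "arrays" / "timecourse").mkdir(parents=True, exist_ok=True)
    (outdir / "arrays" / "mutants").mkdir(parents=True, exist_ok=True)

    tc_tables, tc_truth = syn.simulate_timecourse(gen_config, seed=seed)
    for array_id, table in tc_tables.items():
        arr.write_spot_table(table, outdir / "arrays" / "timecourse" / f"{array_id}.tsv")
    tc_truth.to_json(outdir / "truth_timecourse.json")

    panel_tables, panel_truth = syn.simulate_mutant_panel(gen_config, seed=seed)
    for array_id, table in panel_tables.items():
        arr.write_spot_table(table, outdir / "arrays" / "mutants" / f"{array_id}.tsv")
    panel_truth.to_json(outdir / "truth_mutants.json")

    annotations = syn.simulate_annotations(gen_config, tc_truth, seed=seed + 2)
    annotations.to_csv(outdir / "annotations.tsv", sep="\t", index=False)

    genotypes = dict(panel_truth.genotype_archetypes)
    hist_dir = outdir / "histograms"
    lengths_dir = outdir / "bacteroid_lengths"
    lengths_dir.mkdir(parents=True, exist_ok=True)
    histology_rows = []
    for i, (genotype, archetype) in enumerate(sorted(genotypes.items())):
        hists, _ = syn.simulate_ploidy(
            gen_config, archetype, n_nuclei=n_nuclei, seed=seed + 100 + i
        )
        for h in hists:
            h.sample_id = genotype
        syn.write_histograms(hists, hist_dir)
        if archetype != syn.ARCHETYPE_ROOT:
            infected, it_net, fixing = _ARCHETYPE_HISTOLOGY[archetype]
            histology_rows.append(
                {"genotype": genotype, "infected": infected,
                 "infection_thread_network": it_net, "nitrogen_fixing": fixing}
            )
            model = _ARCHETYPE_BACTEROIDS[archetype]
            if model is not None:
                lengths = syn.simulate_bacteroid_lengths(
                    gen_config, model, n=n_lengths, seed=seed + 200 + i
                )
                np.savetxt(lengths_dir / f"{genotype}.txt", lengths, fmt="%.4f")
    cultured = syn.simulate_bacteroid_lengths(gen_config, "cultured", n=n_lengths,
                                              seed=seed + 299)
    np.savetxt(lengths_dir / "cultured.txt", cultured, fmt="%.4f")
    pd.DataFrame(histology_rows).to_csv(outdir / "histology.tsv", sep="\t", index=False)

    qpcr_ds, qpcr_truth = syn.simulate_qpcr(gen_config, seed=seed + 3)
    qpcr_ds.cp.to_csv(outdir / "qpcr_cp.tsv", sep="\t", index=False)
    pd.DataFrame(
        sorted(qpcr_ds.efficiencies.items()), columns=["transcript", "efficiency"]
    ).to_csv(outdir / "qpcr_efficiencies.tsv", sep="\t", index=False)
    (outdir / "qpcr_reference.txt").write_text(qpcr_ds.reference_transcript + "\n")

    gen_config.to_yaml(outdir / "generator_config.yaml")
    return outdir


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def _load_arrays(indir: Path) -> tuple[list[arr.SpotTable], set[str], set[str]]:
    tc_dir = indir / "arrays" / "timecourse"
    mut_dir = indir / "arrays" / "mutants"
    if not tc_dir.is_dir():
        raise FileNotFoundError(f"missing array directory {tc_dir}")
    tables, tc_ids, mut_ids = [], set(), set()
    for path in sorted(tc_dir.glob("*.tsv")):
        t = arr.read_spot_table(path)
        tables.append(t)
        tc_ids.add(t.array_id)
    if mut_dir.is_dir():
        for path in sorted(mut_dir.glob("*.tsv")):
            t = arr.read_spot_table(path)
            tables.append(t)
            mut_ids.add(t.array_id)
    return tables, tc_ids, mut_ids


def run_pipeline(config: PipelineConfig) -> dict[str, Any]:
    """Execute every stage on the inputs under ``config.input_dir`` and write
    artifacts plus the JSON run report under ``config.output_dir``."""
    config.validate()
    indir = Path(config.input_dir)
    outdir = Path(config.output_dir)
    outdir.mkdir(parents=True, exist_ok=True)
    report: dict[str, Any] = {
        "version": __version__,
        "seed": config.seed,
        "config": asdict(config),
    }

    # -- normalize ----------------------------------------------------------
    stage = "normalize"
    log.info("stage %s", stage)
    try:
        tables, tc_ids, mut_ids = _load_arrays(indir)
        raw = arr.build_ratio_matrix(tables)
        invariant = arr.select_invariant_genes(raw, config.anchor_id, config.n_invariant)
        expr = arr.normalize_arrays(raw, invariant)
        arr.write_expression_matrix(expr, outdir / "expression_matrix.tsv")
        lin = expr.linear()
        dev = float((lin.loc[invariant].median(axis=0) - 1.0).abs().max())
        report["normalization"] = {
            "n_arrays": int(expr.values.shape[1]),
            "n_invariant": len(invariant),
            "median_identity_max_deviation": dev,
        }
    except Exception as e:  # noqa: BLE001 - stage boundary
        raise PipelineError(stage, str(e)) from e

    # -- differential expression --------------------------------------------
    stage = "differential_expression"
    log.info("stage %s", stage)
    try:
        tc_meta = expr.metadata.loc[sorted(tc_ids)]
        groups = de.assign_stages(tc_meta)
        tc_expr = arr.ExpressionMatrix(
            values=expr.values[sorted(tc_ids)],
            scales=expr.scales[sorted(tc_ids)],
            invariant_genes=invariant,
            metadata=tc_meta,
        )
        res = de.pairwise_stage_tests(tc_expr, groups, alpha=config.alpha)
        de_genes = de.select_de_genes(res)
        res.pvalues.rename_axis("gene_id").to_csv(outdir / "de_pvalues.tsv", sep="\t")
        digital = de.digital_transform(res)
        digital.loc[de_genes].rename_axis("gene_id").to_csv(
            outdir / "digital_genes.tsv", sep="\t"
        )
        report["differential_expression"] = {
            "alpha": config.alpha,
            "n_selected": len(de_genes),
        }
    except PipelineError:
        raise
    except Exception as e:
        raise PipelineError(stage, str(e)) from e

    # -- temporal profiles and sample structure ------------------------------
    stage = "profiles"
    log.info("stage %s", stage)
    try:
        assignment = prof.cluster_gene_profiles(
            tc_expr, groups, de_genes, k=config.k_profiles
        )
        assignment.assignments.rename("profile_id").rename_axis("gene_id").to_csv(
            outdir / "profile_assignment.tsv", sep="\t"
        )
        pca = prof.pca_samples(tc_expr)
        pca.coordinates.rename_axis("array_id").to_csv(outdir / "pca_coordinates.tsv", sep="\t")
        sc = prof.cluster_samples(tc_expr, k=config.k_sample_clusters)
        sc.labels.rename_axis("array_id").to_csv(outdir / "sample_clusters.tsv", sep="\t")
        (outdir / "sample_dendrogram.nwk").write_text(sc.newick + "\n")
        sizes = assignment.assignments.value_counts().sort_index()
        report["profiles"] = {
            "k": config.k_profiles,
            "sizes": {str(k): int(v) for k, v in sizes.items()},
        }
        report["sample_clusters"] = {
            "k": config.k_sample_clusters,
            "labels": {a: int(l) for a, l in sc.labels.items()},
            "pca_variance_fractions": [float(v) for v in pca.variance_fractions[:2]],
        }
    except Exception as e:
        raise PipelineError(stage, str(e)) from e

    # -- secretome enrichment ------------------------------------------------
    stage = "enrichment"
    log.info("stage %s", stage)
    try:
        ann_path = indir / "annotations.tsv"
        if not ann_path.is_file():
            raise FileNotFoundError(f"missing annotation file {ann_path}")
        annotations = sec.read_annotation_table(ann_path)
        wave_genes = assignment.genes_in(
            prof.WAVE1_PROFILES + prof.WAVE2_PROFILES
        )
        enr = sec.fisher_enrichment(
            wave_genes, annotations["gene_id"], annotations
        )
        sec.write_enrichment(enr, outdir / "secretome_enrichment.tsv")
        report["enrichment"] = {
            cat: {
                "log10_p": float(row["log10_p"]),
                "odds_ratio": float(row["odds_ratio"]),
                "direction": row["direction"],
            }
            for cat, row in enr.iterrows()
        }
    except Exception as e:
        raise PipelineError(stage, str(e)) from e

    # -- wave scores of the mutant panel -------------------------------------
    stage = "wave_scores"
    log.info("stage %s", stage)
    try:
        root_arrays = [a for a in groups.arrays_in("roots")] + [
            a for a in mut_ids if a.startswith("root__")
        ]
        baseline = prof.root_baseline(expr, root_arrays)
        genotype_of = expr.metadata["genotype"]
        wave_calls: dict[str, tuple[bool, bool]] = {}
        wave_rows = []
        mutant_genotypes = sorted(
            {genotype_of[a] for a in mut_ids if genotype_of[a] != "root"}
        )
        for genotype in mutant_genotypes:
            cols = [a for a in mut_ids if genotype_of[a] == genotype]
            ws = prof.wave_activation(
                expr, assignment, baseline, threshold=config.wave_threshold, samples=cols
            )
            w1 = float(ws.scores["wave1_score"].mean())
            w2 = float(ws.scores["wave2_score"].mean())
            wave_calls[genotype] = (
                w1 >= config.wave_threshold,
                w2 >= config.wave_threshold,
            )
            wave_rows.append({"genotype": genotype, "wave1_score": w1, "wave2_score": w2})
        pd.DataFrame(wave_rows).to_csv(outdir / "wave_scores.tsv", sep="\t", index=False)
    except Exception as e:
        raise PipelineError(stage, str(e)) from e

    # -- ploidy and bacteroid differentiation ---------------------------------
    stage = "differentiation"
    log.info("stage %s", stage)
    try:
        hist_dir = indir / "histograms"
        ploidy_profiles: dict[str, diff.PloidyProfile] = {}
        for genotype in sorted({p.stem.split("__rep")[0] for p in hist_dir.glob("*.csv")}):
            hists = [syn.read_histogram(p) for p in sorted(hist_dir.glob(f"{genotype}__rep*.csv"))]
            ploidy_profiles[genotype] = diff.call_ploidy_fractions(
                hists, anchor_2c=config.ploidy_anchor
            )
        ploidy_report = {}
        cell_diff: dict[str, str] = {}
        for genotype, profile in ploidy_profiles.items():
            ei = diff.endoreduplication_index(profile)
            call = diff.classify_symbiotic_cell_differentiation(
                ei, low=config.ei_low, high=config.ei_high
            )
            cell_diff[genotype] = call
            ploidy_report[genotype] = {
                "ei": ei,
                "cell_diff": call,
                "max_class": diff.max_occupied_class(
                    profile, floor_percent=config.ploidy_occupancy_floor
                ),
            }
        frame = diff.profiles_to_frame(list(ploidy_profiles.values()))
        labels, linkage, newick = diff.cluster_ploidy_profiles(frame, k=2)
        (outdir / "ploidy_dendrogram.nwk").write_text(newick + "\n")
        frame.rename_axis("sample").to_csv(outdir / "ploidy_profiles.tsv", sep="\t")
        report["ploidy"] = ploidy_report

        lengths_dir = indir / "bacteroid_lengths"
        cultured = np.loadtxt(lengths_dir / "cultured.txt")
        bact_report = {}
        bact_calls: dict[str, bool] = {}
        for path in sorted(lengths_dir.glob("*.txt")):
            genotype = path.stem
            if genotype == "cultured":
                continue
            call = diff.classify_bacteroid_differentiation(
                np.loadtxt(path), cultured, threshold=config.bacteroid_fold_threshold
            )
            bact_calls[genotype] = call.differentiated
            bact_report[genotype] = {
                "fold": call.fold,
                "differentiated": call.differentiated,
            }
        report["bacteroids"] = bact_report
    except Exception as e:
        raise PipelineError(stage, str(e)) from e

    # -- mutant classification ------------------------------------------------
    stage = "classification"
    log.info("stage %s", stage)
    try:
        histology = pd.read_csv(indir / "histology.tsv", sep="\t")
        observations = []
        for row in histology.itertuples(index=False):
            genotype = row.genotype
            w1, w2 = wave_calls.get(genotype, (False, False))
            observations.append(
                cls.MutantObservation(
                    genotype=genotype,
                    infected=bool(row.infected),
                    infection_thread_network=bool(row.infection_thread_network),
                    cell_diff=cell_diff.get(genotype, diff.INDETERMINATE),
                    bacteroid_diff=bact_calls.get(genotype) if bool(row.infected) else None,
                    wave1_active=w1,
                    wave2_active=w2,
                    nitrogen_fixing=bool(row.nitrogen_fixing),
                )
            )
        table, counts = cls.classify_panel(observations)
        cls.write_category_table(table, outdir / "mutant_categories.tsv")
        report["classification"] = {
            "categories": table["category"].to_dict(),
            "consistent": {g: bool(v) for g, v in table["consistent"].items()},
            "n_distinct_mutant_categories": counts["n_distinct_mutant_categories"],
        }
    except Exception as e:
        raise PipelineError(stage, str(e)) from e

    # -- qPCR (optional inputs) ----------------------------------------------
    stage = "qpcr"
    cp_path = indir / "qpcr_cp.tsv"
    if cp_path.is_file():
        log.info("stage %s", stage)
        try:
            cp = qp.read_cp_table(cp_path)
            eff = qp.read_efficiencies(indir / "qpcr_efficiencies.tsv")
            reference = (indir / "qpcr_reference.txt").read_text().strip()
            ds = qp.QpcrDataset(cp=cp, efficiencies=eff, reference_transcript=reference)
            qpcr_report = {}
            for target in sorted(set(cp["transcript"]) - {reference}):
                rel = qp.pfaffl_relative_expression(ds, target)
                qp.write_relative_expression(rel, outdir / f"qpcr_{target}.tsv")
                qpcr_report[target] = {s: float(v) for s, v in rel.folds.items()}
            report["qpcr"] = qpcr_report
        except Exception as e:
            raise PipelineError(stage, str(e)) from e

    # -- report ---------------------------------------------------------------
    validate_report(report)
    (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return report


# ---------------------------------------------------------------------------
# Report schema validation
# ---------------------------------------------------------------------------

_TYPES = {
    "object": dict,
    "array": list,
    "string": str,
    "integer": int,
    "number": (int, float),
    "boolean": bool,
}


def _check(instance: Any, schema: dict, path: str) -> None:
    t = schema.get("type")
    if t is not None and not isinstance(instance, _TYPES[t]):
        raise ValueError(f"{path}: expected {t}, got {type(instance).__name__}")
    if t == "integer" and isinstance(instance, bool):
        raise ValueError(f"{path}: expected integer, got boolean")
    if "enum" in schema and instance not in schema["enum"]:
        raise ValueError(f"{path}: {instance!r} not in {schema['enum']}")
    if isinstance(instance, dict):
        for key in schema.get("required", []):
            if key not in instance:
                raise ValueError(f"{path}: missing required key {key!r}")
        for key, sub in schema.get("properties", {}).items():
            if key in instance:
                _check(instance[key], sub, f"{path}.{key}")
    if isinstance(instance, list) and "items" in schema:
        for i, item in enumerate(instance):
            _check(item, schema["items"], f"{path}[{i}]")


def report_schema() -> dict:
    text = importlib.resources.files("nodulewaves").joinpath("report_schema.json").read_text()
    return json.loads(text)


def validate_report(report: dict) -> None:
    """Check the run report against the JSON schema shipped with the package."""
    _check(report, report_schema(), "report")
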