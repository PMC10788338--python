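"""Config-driven end-to-end orchestration.

Runs the discovery pipeline in order — cohort (synthetic or loaded) →
comorbidity matrix → co-occurrence network → class-count selection →
stability meta-clustering → outcome comparison — writing every artifact
plus a run manifest (paths, seeds, stage timings). Deterministic stages
rerun byte-identically for the same configuration.
"""

from __future__ import annotations

import time
from dataclasses import dataclass, field
from pathlib import Path

import networkx as nx
import numpy as np

from . import cooccurrence, io, lca, outcomes, selection, synthetic
from .elixhauser import build_comorbidity_matrix, filter_cohort, load_mapping

__all__ = ["PipelineConfig", "run_pipeline"]

_STAGES = ("cohort", "matrix", "network", "selection", "stability",
           "outcomes")


@dataclass
class PipelineConfig:
    output_dir: str
    seed: int = 0
    # exactly one of the two input modes
    synthetic_n_patients: int | None = 2629
    patient_table_path: str | None = None
    # mapping / cohort rules
    combine_hypertension: bool = True
    # model selection
    k_min: int = 1
    k_max: int = 8
    n_restarts: int = 20
    # stability
    n_replicates: int = 30
    g_max: int = 10
    # outcomes
    alpha: float = 0.05
    reference: str | None = None
    # network
    p_max: float = 0.05
    rr_min: float = 1.5
    rr_cap: float = 5.0
    make_plots: bool = False

    def validate(self) -> None:
        if (self.synthetic_n_patients is None) == \
                (self.patient_table_path is None):
            raise ValueError("exactly one of synthetic_n_patients / "
                             "patient_table_path must be set")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must lie in (0, 1)")
        if self.patient_table_path is not None \
                and not Path(self.patient_table_path).exists():
            raise ValueError(f"input not found: {self.patient_table_path}")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls(**io.read_yaml(path))


def _stage_seed(config: PipelineConfig, stage: str) -> int:
    # per-stage seeds derived from the global seed by stage index offset
    return (config.seed * 1000 + _STAGES.index(stage)) % 2**31


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages; return (and write) the run manifest."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"stages": {}, "seed": config.seed, "outputs": []}

    def _record(stage, t0, **info):
        manifest["stages"][stage] = {
            "seconds": round(time.perf_counter() - t0, 3), **info}

    def _write(path, writer, obj):
        writer(obj, path)
        manifest["outputs"].append(str(path))

    try:
        # --- cohort -------------------------------------------------
        t0 = time.perf_counter()
        mapping = load_mapping(
            combine_hypertension=config.combine_hypertension)
        class_names = None
        if config.patient_table_path is not None:
            patients = io.read_patient_table(config.patient_table_path)
            patients = filter_cohort(patients)
            matrix = build_comorbidity_matrix(patients, mapping)
        else:
            scenario = synthetic.default_endotype_scenario(
                seed=_stage_seed(config, "cohort"),
                n_patients=config.synthetic_n_patients)
            patients, matrix, truth = synthetic.generate_cohort(scenario)
            class_names = scenario.class_names
            _write(out / "truth.json", io.write_json,
                   {"labels": truth.labels.tolist(),
                    "mixing_weights": scenario.to_dict()["mixing_weights"],
                    "item_probs": scenario.to_dict()["item_probs"]})
            _write(out / "scenario.yaml", io.write_yaml, scenario.to_dict())
        _write(out / "patients.csv", io.write_patient_table, patients)
        _record("cohort", t0, n_patients=len(patients))

        # --- matrix -------------------------------------------------
        t0 = time.perf_counter()
        _write(out / "comorbidity_matrix.csv", io.write_matrix, matrix)
        _record("matrix", t0, n_rows=len(matrix),
                n_categories=matrix.shape[1])

        # --- network ------------------------------------------------
        t0 = time.perf_counter()
        pairs = cooccurrence.all_pairs(matrix)
        net = cooccurrence.build_network(pairs, matrix, p_max=config.p_max,
                                         rr_min=config.rr_min,
                                         rr_cap=config.rr_cap)
        frame = cooccurrence.network_to_frame(pairs)
        frame.to_csv(out / "pair_associations.csv", index=False)
        manifest["outputs"].append(str(out / "pair_associations.csv"))
        nx.write_graphml(net, out / "network.graphml")
        manifest["outputs"].append(str(out / "network.graphml"))
        _record("network", t0, n_pairs=len(pairs),
                n_edges=net.number_of_edges())

        # --- selection ----------------------------------------------
        t0 = time.perf_counter()
        curve = selection.fit_k_range(
            matrix, k_min=config.k_min, k_max=config.k_max,
            n_restarts=config.n_restarts,
            seed=_stage_seed(config, "selection"))
        _write(out / "aic_curve.json", io.write_json, curve.to_dict())
        _record("selection", t0, selected_k=curve.selected_k)

        # --- stability ----------------------------------------------
        t0 = time.perf_counter()
        fits = selection.replicate_fits(
            matrix, curve.selected_k, r=config.n_replicates,
            base_seed=_stage_seed(config, "stability"))
        report = selection.meta_cluster(fits, g_max=config.g_max,
                                        seed=_stage_seed(config, "stability"))
        representative = fits[report.representative_index]
        _write(out / "stability.json", io.write_json, report.to_dict())
        _write(out / "representative_fit.json", io.write_json,
               representative.to_dict())
        _record("stability", t0, stability_score=report.stability_score,
                n_meta_clusters=report.n_meta_clusters)

        # --- outcomes -----------------------------------------------
        t0 = time.perf_counter()
        assignments = lca.assign_classes(representative)
        names = (list(class_names) if class_names is not None
                 and len(class_names) == representative.k else None)
        table = outcomes.outcome_table(assignments, patients,
                                       class_names=names)
        table.table.to_csv(out / "outcome_table.csv")
        manifest["outputs"].append(str(out / "outcome_table.csv"))
        surv = outcomes.pairwise_chisq(table, "survival", alpha=config.alpha)
        intv = outcomes.pairwise_chisq(table, "intervention",
                                       alpha=config.alpha)
        los = outcomes.pairwise_los_tests(table.los_values,
                                          alpha=config.alpha)
        for name, res in (("pairwise_survival", surv),
                          ("pairwise_intervention", intv),
                          ("pairwise_los", los)):
            res.results.to_csv(out / f"{name}.csv", index=False)
            manifest["outputs"].append(str(out / f"{name}.csv"))
        ancova = outcomes.ancova_los(patients, assignments, class_names=names)
        ancova.tukey.to_csv(out / "ancova_tukey.csv", index=False)
        manifest["outputs"].append(str(out / "ancova_tukey.csv"))
        _record("outcomes", t0, n_groups=len(table.table))

        if config.make_plots:
            from . import plots
            plots.plot_network(net, out / "network.png")
            plots.plot_aic_curve(curve, out / "aic_curve.png")
            plots.plot_profiles(report, list(matrix.columns),
                                out / "profiles.png")
            manifest["outputs"] += [str(out / p) for p in
                                    ("network.png", "aic_curve.png",
                                     "profiles.png")]
        manifest["completed"] = True
    except Exception as exc:
        manifest["completed"] = False
        manifest["error"] = f"{type(exc).__name__}: {exc}"
        io.write_json(manifest, out / "manifest.json")
        raise
    io.write_json(manifest, out / "manifest.json")
    manifest["outputs"].append(str(out / "manifest.json"))
    return manifest
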