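"""End-to-end orchestration: simulate -> preprocess -> DE -> cluster ->
classify -> qPCR, from one structured config, with a machine-readable run
report.

Every stage can be toggled; parameters default to the study's stated values
(missingness threshold 0.5, FDR 0.10, fold 1.5, selection p <= 1e-4, k = 10).
The report records per-stage counts (spots before/after filtering, number of
differential spots, predictor genes, cross-validation and blinded-validation
performance, qPCR concordance rate) plus the seed registry, and is byte-
identical across runs of the same config and seed.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .data import (
    GROUP_CASE,
    read_expression_matrix,
    read_sample_table,
    write_expression_matrix,
    write_sample_table,
)
from .diffexpr import DifferentialExpression, select_genes
from .classify import (
    CVConfig,
    CompoundCovariatePredictor,
    kfold_cross_validate,
)
from .cluster import centered_pearson_distance, complete_linkage, write_treeview
from .exceptions import ConfigError, StageError
from .preprocess import center_arrays, filter_genes_by_missingness, log2_transform
from .qpcr import concordance_report, delta_delta_ct, group_median_fold
from .simulate import (
    CtTable,
    SimulationConfig,
    TruthTable,
    simulate_ct_table,
    simulate_expression,
    substream_rng,
)

log = logging.getLogger("pbmcsig")

_STAGES = ("simulate", "preprocess", "de", "cluster", "classify", "qpcr")

_DEFAULTS = {
    "simulate": {"enabled": True},
    "input": {"matrix": None, "samples": None, "expect_log2": True},
    "preprocess": {"enabled": True, "max_missing_fraction": 0.5,
                   "lowess_frac": 0.3, "lowess_iterations": 3,
                   "log2_input": False},
    "de": {"enabled": True, "max_fdr": 0.10, "min_fold": 1.5},
    "cluster": {"enabled": True, "axis": "samples", "gene_set": "de_selected"},
    "classify": {"enabled": True, "k": 10, "repeats": 1, "method": "ccp",
                 "p_max": 1.0e-4, "min_fold": 1.5,
                 "validation_subject_fraction": 0.35},
    "qpcr": {"enabled": True, "noise_sd": 0.25, "n_genes": 6,
             "ct": None, "housekeeping": "HKG", "calibrator": "REF",
             "genes": None},
}


@dataclass
class PipelineConfig:
    """Validated pipeline configuration (see module docstring for defaults)."""

    seed: int = 0
    simulation: SimulationConfig | None = None
    sections: dict = field(default_factory=dict)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        raw = dict(raw)
        seed = int(raw.pop("seed", 0))
        sim_raw = raw.pop("simulate", {})
        unknown = set(raw) - set(_DEFAULTS)
        if unknown:
            raise ConfigError(f"unknown config sections: {sorted(unknown)}")
        sections = {}
        for name, defaults in _DEFAULTS.items():
            if name == "simulate":
                continue
            user = raw.get(name, {})
            bad = set(user) - set(defaults)
            if bad:
                raise ConfigError(f"unknown keys in section {name!r}: {sorted(bad)}")
            sections[name] = {**defaults, **user}
        sim_enabled = bool(sim_raw.pop("enabled", True)) if isinstance(sim_raw, dict) else True
        simulation = None
        if sim_enabled:
            sim_raw.setdefault("seed", seed)
            simulation = SimulationConfig.from_dict(sim_raw)
        else:
            needs_data = any(sections[s]["enabled"]
                             for s in ("preprocess", "de", "cluster", "classify"))
            inp = sections["input"]
            if needs_data:
                if not inp["matrix"] or not inp["samples"]:
                    raise ConfigError(
                        "simulation disabled: input.matrix and input.samples required")
                for p in (inp["matrix"], inp["samples"]):
                    if not Path(p).exists():
                        raise ConfigError(f"input file does not exist: {p}")
        cfg = cls(seed=seed, simulation=simulation, sections=sections)
        cfg.validate()
        return cfg

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text(encoding="utf-8")) or {}
        if not isinstance(raw, dict):
            raise ConfigError(f"{path}: config must be a mapping")
        return cls.from_dict(raw)

    def validate(self) -> None:
        s = self.sections
        if not 0.0 <= s["preprocess"]["max_missing_fraction"] <= 1.0:
            raise ConfigError("preprocess.max_missing_fraction must be in [0, 1]")
        if not 0.0 < s["de"]["max_fdr"] <= 1.0:
            raise ConfigError("de.max_fdr must be in (0, 1]")
        if s["cluster"]["axis"] not in ("samples", "genes"):
            raise ConfigError("cluster.axis must be 'samples' or 'genes'")
        if s["cluster"]["gene_set"] not in ("de_selected", "all"):
            raise ConfigError("cluster.gene_set must be 'de_selected' or 'all'")
        if s["classify"]["k"] < 2:
            raise ConfigError("classify.k must be >= 2")
        if not 0.0 < s["classify"]["validation_subject_fraction"] < 1.0:
            raise ConfigError("classify.validation_subject_fraction must be in (0, 1)")

    def stage_enabled(self, name: str) -> bool:
        if name == "simulate":
            return self.simulation is not None
        return bool(self.sections[name]["enabled"])


def _perf_dict(perf) -> dict:
    def _f(x):
        return None if (x != x) else round(float(x), 6)  # NaN -> null
    return {
        "TP": perf.TP, "FP": perf.FP, "TN": perf.TN, "FN": perf.FN,
        "sensitivity": _f(perf.sensitivity),
        "specificity": _f(perf.specificity),
        "accuracy": _f(perf.accuracy),
    }


@dataclass
class RunReport:
    """Per-stage summaries; serializes deterministically to JSON."""

    content: dict = field(default_factory=dict)

    def to_json(self) -> str:
        return json.dumps(self.content, indent=2, sort_keys=True) + "\n"

    def write(self, path) -> None:
        Path(path).write_text(self.to_json(), encoding="utf-8")


def run_pipeline(config: PipelineConfig, out_dir) -> RunReport:
    """Execute the enabled stages in order; artifacts land under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    report = {"version": __version__, "seed": config.seed, "stages_run": []}
    matrix = samples = truth = None
    de_res = None
    selected = None

    def _run(stage, fn):
        if not config.stage_enabled(stage):
            log.info("stage %s: disabled", stage)
            return
        log.info("stage %s: start", stage)
        try:
            fn()
        except Exception as exc:  # noqa: BLE001 - rewrapped with stage name
            raise StageError(stage, exc) from exc
        report["stages_run"].append(stage)
        log.info("stage %s: done", stage)

    # --- simulate / load ----------------------------------------------
    def _simulate():
        nonlocal matrix, samples, truth
        matrix, samples, truth = simulate_expression(config.simulation)
        write_expression_matrix(matrix, out / "matrix.tsv")
        write_sample_table(samples, out / "samples.tsv")
        truth.write(out / "truth.tsv")
        report["simulate"] = {
            "n_spots": matrix.n_spots,
            "n_samples": matrix.n_samples,
            "n_de_spots": int(truth.table["is_de"].sum()),
            "config": config.simulation.to_dict(),
        }

    _run("simulate", _simulate)
    if matrix is None:
        inp = config.sections["input"]
        if config.stage_enabled("preprocess") or config.stage_enabled("de"):
            matrix = read_expression_matrix(inp["matrix"], expect_log2=inp["expect_log2"])
            samples = read_sample_table(inp["samples"])

    # --- preprocess -----------------------------------------------------
    def _preprocess():
        nonlocal matrix
        p = config.sections["preprocess"]
        n0 = matrix.n_spots
        m = matrix
        if p["log2_input"]:
            m = log2_transform(m)
        m = center_arrays(m, frac=p["lowess_frac"], iterations=p["lowess_iterations"])
        m = filter_genes_by_missingness(m, p["max_missing_fraction"])
        matrix = m
        write_expression_matrix(matrix, out / "matrix.centered.tsv")
        report["preprocess"] = {
            "n_spots_before": n0,
            "n_spots_after": matrix.n_spots,
            "max_missing_fraction": p["max_missing_fraction"],
        }

    _run("preprocess", _preprocess)

    # --- differential expression ----------------------------------------
    def _de():
        nonlocal de_res, selected
        p = config.sections["de"]
        de_res = DifferentialExpression(matrix, samples).fit()
        sig = de_res.select(max_fdr=p["max_fdr"], min_fold=None)
        selected = de_res.select(max_fdr=p["max_fdr"], min_fold=p["min_fold"])
        de_res.write_tsv(out / "de_table.tsv")
        (out / "de_selected.txt").write_text(
            "\n".join(map(str, selected)) + "\n", encoding="utf-8")
        report["de"] = {
            "n_spots_tested": de_res.n_fitted,
            "n_significant": int(len(sig)),
            "n_significant_min_fold": int(len(selected)),
            "max_fdr": p["max_fdr"],
            "min_fold": p["min_fold"],
        }

    _run("de", _de)

    # --- clustering -------------------------------------------------------
    def _cluster():
        p = config.sections["cluster"]
        if p["gene_set"] == "de_selected" and selected is not None and len(selected) >= 2:
            sub = matrix.subset_spots(selected)
        else:
            sub = matrix
        dist = centered_pearson_distance(sub, axis=p["axis"])
        tree = complete_linkage(dist)
        if p["axis"] == "samples":
            files = write_treeview(sub, None, tree, out / "cluster")
        else:
            files = write_treeview(sub, tree, None, out / "cluster")
        report["cluster"] = {
            "axis": p["axis"],
            "n_items": len(dist.ids),
            "n_spots_used": sub.n_spots,
            "top_height": round(tree.heights[-1], 6),
            "files": [Path(f).name for f in files],
        }

    _run("cluster", _cluster)

    # --- classification ---------------------------------------------------
    def _classify():
        p = config.sections["classify"]
        # subject-level stratified split into training and blinded validation
        rng = substream_rng(config.seed, "folds")
        subj_group = samples.table.groupby("subject_id")["group"].first()
        val_subjects = []
        for grp in sorted(subj_group.unique()):
            subj = sorted(subj_group.index[subj_group == grp])
            n_val = max(1, int(round(len(subj) * p["validation_subject_fraction"])))
            picked = rng.choice(len(subj), size=n_val, replace=False)
            val_subjects += [subj[i] for i in sorted(picked)]
        is_val = samples.subjects.isin(val_subjects)
        train_ids = samples.sample_ids[~is_val]
        val_ids = samples.sample_ids[is_val]
        train_m = matrix.subset_samples(train_ids)
        val_m = matrix.subset_samples(val_ids)
        labels = samples.groups

        cv = CVConfig(k=p["k"], repeats=p["repeats"], method=p["method"],
                      p_max=p["p_max"], min_fold=p["min_fold"], seed=config.seed)
        _, cv_perf = kfold_cross_validate(train_m, labels.loc[train_ids], cv)

        model = CompoundCovariatePredictor(
            train_m, labels.loc[train_ids], p_max=p["p_max"],
            min_fold=p["min_fold"], impute=True).fit()
        model.save(out / "ccp_model.tsv")
        val_perf = model.evaluate(val_m, labels.loc[val_ids])
        report["classify"] = {
            "n_train_samples": int(len(train_ids)),
            "n_validation_samples": int(len(val_ids)),
            "n_predictor_genes": len(model.model.genes),
            "predictor_genes": list(map(str, model.model.genes)),
            "threshold": round(model.model.threshold, 6),
            "cv": _perf_dict(cv_perf),
            "validation": _perf_dict(val_perf),
        }

    _run("classify", _classify)

    # --- qPCR concordance -------------------------------------------------
    def _qpcr():
        p = config.sections["qpcr"]
        if p["ct"] is not None:
            ct = CtTable.read(p["ct"], housekeeping=p["housekeeping"],
                              calibrator=p["calibrator"])
            genes = p["genes"] or [g for g in ct.ct.columns if g != p["housekeeping"]]
            spot_for_gene = None
        else:
            if truth is None or de_res is None:
                raise ConfigError(
                    "qpcr stage needs either qpcr.ct or the simulate+de stages")
            # most differential selected spots, unique by gene
            pool = selected if selected is not None and len(selected) else de_res.table.index
            tab = de_res.table.loc[pool].dropna(subset=["q"])
            tab = tab.assign(absfc=np.maximum(tab["fold_change"], 1 / tab["fold_change"]))
            tab = tab.sort_values(["absfc", "q"], ascending=[False, True])
            tab = tab.drop_duplicates("gene").head(int(p["n_genes"]))
            genes = tab["gene"].tolist()
            spot_for_gene = {row["gene"]: spot for spot, row in tab.iterrows()}
            ct = simulate_ct_table(truth, samples, noise_sd=p["noise_sd"],
                                   seed=config.seed, genes=genes,
                                   housekeeping=p["housekeeping"],
                                   calibrator=p["calibrator"])
            ct.write(out / "ct.tsv")
        qpcr_ratio = {}
        for g in genes:
            folds = delta_delta_ct(ct, g)
            ratio, _ = group_median_fold(folds, samples)
            qpcr_ratio[g] = ratio
        if spot_for_gene is not None:
            micro_ratio = {g: float(de_res.table.loc[s, "fold_change"])
                           for g, s in spot_for_gene.items()}
        else:
            if de_res is None:
                raise ConfigError("qpcr concordance needs the de stage")
            by_gene = de_res.table.dropna(subset=["q"]).drop_duplicates("gene") \
                .set_index("gene")["fold_change"]
            micro_ratio = {g: float(by_gene[g]) for g in genes}
        rep = concordance_report(micro_ratio, qpcr_ratio)
        rep.to_csv(out / "qpcr_concordance.tsv", sep="\t", lineterminator="\n")
        report["qpcr"] = {
            "genes": list(map(str, rep.index)),
            "n_concordant": int(rep["concordant"].sum()),
            "n_genes": int(len(rep)),
            "validation_rate": round(rep.attrs["validation_rate"], 6),
        }

    _run("qpcr", _qpcr)

    rr = RunReport(report)
    rr.write(out / "report.json")
    return rr
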