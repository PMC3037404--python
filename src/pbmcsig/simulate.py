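"""Synthetic two-channel microarray experiments with known ground truth.

The generator realizes the data model the downstream analysis assumes: for
gene g and sample s,

    x_gs = mu_g + delta_g * 1[group(s) = case] + b_{g,subject(s)}
           + o_{array(s)}(A_g) + eps_gs

with per-gene baseline mu_g, a fixed case/control shift delta_g (nonzero for
the truly differential genes), a per-gene per-subject random intercept
b ~ N(0, subject_sd^2) accounting for repeated samples per subject, a
per-array additive offset plus a smooth intensity-dependent dye bias
o_a(A) = offset_a + amp_a * sin(2*pi*(A-6)/10) evaluated at the spot's mean
log intensity A_g ~ U(6, 16), and residual noise eps ~ N(0, residual_sd^2).

Defaults emulate the study design: 26 case subjects contributing 35 samples,
33 control subjects contributing one sample each, ~21,671 analyzable genes of
which 383 are differential with |log2 FC| between log2(1.5) and log2(4.812),
a fraction of duplicate spots (same gene, independent residuals), and missing
spots. A single seed drives everything through fixed substream labels, so any
stage can be re-derived independently and identical (config, seed) pairs give
bit-identical output.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .data import (
    GROUP_CASE,
    GROUP_CONTROL,
    ExpressionMatrix,
    SampleTable,
)
from .exceptions import ConfigError, DomainError

__all__ = [
    "SimulationConfig",
    "TruthTable",
    "CtTable",
    "simulate_expression",
    "simulate_missing",
    "simulate_ct_table",
    "substream_rng",
]

# fixed substream labels: every random draw hangs off (seed, label)
_STREAMS = {
    "sample_counts": 1,
    "baseline": 2,
    "de_spots": 3,
    "effects": 4,
    "intensity": 5,
    "arrays": 6,
    "subject_effects": 7,
    "residual": 8,
    "duplicates": 9,
    "missing": 10,
    "ct": 11,
    "folds": 12,
}


def substream_rng(seed: int, label: str) -> np.random.Generator:
    """Independent generator for a named substream of the global seed."""
    if label not in _STREAMS:
        raise KeyError(f"unknown substream label {label!r}")
    return np.random.default_rng(np.random.SeedSequence((int(seed), _STREAMS[label])))


def _parse_samples_spec(spec):
    """Normalize a samples-per-subject spec.

    Accepted forms: a positive int (every subject contributes that many
    samples), a (min, max) pair (uniform integer draw per subject), or
    ("total", N) / {"total": N} (N samples spread deterministically, first
    subjects taking the extra one).
    """
    if isinstance(spec, int):
        if spec < 1:
            raise ConfigError("samples per subject must be >= 1")
        return ("fixed", spec)
    if isinstance(spec, dict):
        if set(spec) != {"total"}:
            raise ConfigError(f"bad samples-per-subject spec {spec!r}")
        return ("total", int(spec["total"]))
    if isinstance(spec, (tuple, list)) and len(spec) == 2:
        if spec[0] == "total":
            return ("total", int(spec[1]))
        lo, hi = int(spec[0]), int(spec[1])
        if lo < 1 or hi < lo:
            raise ConfigError(f"bad samples-per-subject range {spec!r}")
        return ("uniform", (lo, hi))
    raise ConfigError(f"bad samples-per-subject spec {spec!r}")


@dataclass
class SimulationConfig:
    """Parameters of a synthetic experiment; defaults mirror the study design."""

    n_case_subjects: int = 26
    n_control_subjects: int = 33
    samples_per_subject_case: object = ("total", 35)
    samples_per_subject_control: object = 1
    n_genes: int = 21671
    n_de_genes: int = 383
    de_log2fc_range: tuple = (math.log2(1.5), math.log2(4.812))
    subject_sd: float = 0.3
    residual_sd: float = 0.3
    baseline_sd: float = 0.5
    array_offset_sd: float = 0.1
    dye_bias_amplitude: float = 0.2
    missing_rate: float = 0.02
    duplicate_spot_fraction: float = 0.1
    seed: int = 0

    def validate(self) -> None:
        if self.n_case_subjects <= 0 or self.n_control_subjects <= 0:
            raise ConfigError("subject counts must be positive")
        if self.n_genes <= 0:
            raise ConfigError("n_genes must be positive")
        if self.n_de_genes < 0 or self.n_de_genes > self.n_genes:
            raise ConfigError("n_de_genes must be in [0, n_genes]")
        lo, hi = self.de_log2fc_range
        if lo < 0 or hi < lo:
            raise ConfigError("de_log2fc_range must satisfy 0 <= lo <= hi")
        for name in ("subject_sd", "baseline_sd", "array_offset_sd", "dye_bias_amplitude"):
            if getattr(self, name) < 0:
                raise ConfigError(f"{name} must be >= 0")
        if self.residual_sd < 0:
            raise ConfigError("residual_sd must be >= 0")
        for name in ("missing_rate", "duplicate_spot_fraction"):
            if not 0.0 <= getattr(self, name) <= 1.0:
                raise ConfigError(f"{name} must be in [0, 1]")
        _parse_samples_spec(self.samples_per_subject_case)
        _parse_samples_spec(self.samples_per_subject_control)

    @classmethod
    def from_dict(cls, d: dict) -> "SimulationConfig":
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(d) - known
        if unknown:
            raise ConfigError(f"unknown simulation config keys: {sorted(unknown)}")
        cfg = cls(**d)
        if isinstance(cfg.de_log2fc_range, list):
            cfg.de_log2fc_range = tuple(cfg.de_log2fc_range)
        cfg.validate()
        return cfg

    def to_dict(self) -> dict:
        d = asdict(self)
        d["de_log2fc_range"] = list(self.de_log2fc_range)
        if isinstance(d["samples_per_subject_case"], tuple):
            d["samples_per_subject_case"] = list(d["samples_per_subject_case"])
        if isinstance(d["samples_per_subject_control"], tuple):
            d["samples_per_subject_control"] = list(d["samples_per_subject_control"])
        return d


@dataclass
class TruthTable:
    """Ground truth per spot: gene symbol, differential flag, true log2 fold change.

    ``duplicate_of`` names the parent spot for duplicated spots (same gene,
    independent residual noise), else NA. true_log2fc is exactly 0 for
    non-differential spots.
    """

    table: pd.DataFrame  # index spot_id; columns gene, is_de, true_log2fc, duplicate_of

    @property
    def de_spots(self) -> pd.Index:
        return self.table.index[self.table["is_de"]]

    @property
    def null_spots(self) -> pd.Index:
        return self.table.index[~self.table["is_de"]]

    def write(self, path) -> None:
        out = self.table.copy()
        out.index.name = "spot_id"
        out["is_de"] = out["is_de"].astype(int)
        out.to_csv(path, sep="\t", na_rep="NA", lineterminator="\n")

    @classmethod
    def read(cls, path) -> "TruthTable":
        t = pd.read_csv(path, sep="\t", index_col="spot_id",
                        na_values=["NA"], keep_default_na=False)
        t["is_de"] = t["is_de"].astype(int).astype(bool)
        t["true_log2fc"] = t["true_log2fc"].astype(float)
        return cls(t)


@dataclass
class CtTable:
    """qPCR cycle-threshold values: samples x genes, with designated
    housekeeping gene and calibrator sample."""

    ct: pd.DataFrame  # index sample_id, columns gene
    housekeeping: str
    calibrator: str

    def __post_init__(self) -> None:
        if self.housekeeping not in self.ct.columns:
            raise DomainError(f"housekeeping gene {self.housekeeping!r} not in Ct table")
        if self.calibrator not in self.ct.index:
            raise DomainError(f"calibrator sample {self.calibrator!r} not in Ct table")
        with np.errstate(invalid="ignore"):
            if np.isinf(self.ct.to_numpy(dtype=float)).any():
                raise DomainError("non-finite Ct value")

    def write(self, path) -> None:
        out = self.ct.copy()
        out.index.name = "sample_id"
        out.to_csv(path, sep="\t", na_rep="NA", lineterminator="\n")

    @classmethod
    def read(cls, path, housekeeping: str, calibrator: str) -> "CtTable":
        ct = pd.read_csv(path, sep="\t", index_col="sample_id",
                         na_values=["NA", ""], keep_default_na=False).astype(float)
        return cls(ct, housekeeping=housekeeping, calibrator=calibrator)


def _draw_sample_counts(spec, n_subjects: int, rng: np.random.Generator) -> np.ndarray:
    kind, val = _parse_samples_spec(spec)
    if kind == "fixed":
        return np.full(n_subjects, val, dtype=int)
    if kind == "uniform":
        lo, hi = val
        return rng.integers(lo, hi + 1, size=n_subjects)
    # total: deterministic round-robin, first subjects carry the remainder
    base, extra = divmod(int(val), n_subjects)
    if base < 1 and extra < n_subjects:
        raise ConfigError(f"total {val} samples cannot cover {n_subjects} subjects")
    counts = np.full(n_subjects, base, dtype=int)
    counts[:extra] += 1
    return counts


def simulate_expression(config: SimulationConfig):
    """Generate one experiment.

    Returns
    -------
    (ExpressionMatrix, SampleTable, TruthTable)
        Matrix of log2 ratios ((n_genes + duplicates) spots x samples) with
        per-spot mean log intensity, the sample->subject->group map, and the
        spot-level ground truth.
    """
    config.validate()
    seed = config.seed

    # --- design: subjects and samples ---------------------------------
    rng_counts = substream_rng(seed, "sample_counts")
    case_counts = _draw_sample_counts(
        config.samples_per_subject_case, config.n_case_subjects, rng_counts)
    ctrl_counts = _draw_sample_counts(
        config.samples_per_subject_control, config.n_control_subjects, rng_counts)

    subjects, groups, sample_ids = [], [], []
    for i, c in enumerate(case_counts, start=1):
        sid = f"case{i:03d}"
        for r in range(1, c + 1):
            subjects.append(sid)
            groups.append(GROUP_CASE)
            sample_ids.append(f"{sid}_r{r}")
    for i, c in enumerate(ctrl_counts, start=1):
        sid = f"ctrl{i:03d}"
        for r in range(1, c + 1):
            subjects.append(sid)
            groups.append(GROUP_CONTROL)
            sample_ids.append(f"{sid}_r{r}")
    samples = SampleTable(pd.DataFrame(
        {"subject_id": subjects, "group": groups}, index=pd.Index(sample_ids, name="sample_id")))
    n_samples = len(sample_ids)
    subj_codes, subj_uniques = pd.factorize(pd.Index(subjects))
    n_subjects = len(subj_uniques)
    is_case = np.asarray([g == GROUP_CASE for g in groups])

    # --- gene-level truth ----------------------------------------------
    g = config.n_genes
    gene_names = np.array([f"G{i:05d}" for i in range(1, g + 1)])
    rng_de = substream_rng(seed, "de_spots")
    de_idx = np.sort(rng_de.choice(g, size=config.n_de_genes, replace=False))
    rng_eff = substream_rng(seed, "effects")
    lo, hi = config.de_log2fc_range
    magnitudes = rng_eff.uniform(lo, hi, size=config.n_de_genes)
    signs = rng_eff.choice([-1.0, 1.0], size=config.n_de_genes)
    delta = np.zeros(g)
    delta[de_idx] = signs * magnitudes

    rng_base = substream_rng(seed, "baseline")
    mu = rng_base.normal(0.0, config.baseline_sd, size=g)
    rng_int = substream_rng(seed, "intensity")
    intensity_g = rng_int.uniform(6.0, 16.0, size=g)

    # --- array effects ---------------------------------------------------
    rng_arr = substream_rng(seed, "arrays")
    offsets = rng_arr.normal(0.0, config.array_offset_sd, size=n_samples)
    amps = rng_arr.uniform(-1.0, 1.0, size=n_samples) * config.dye_bias_amplitude
    # smooth intensity-dependent dye bias, one full period over A in (6, 16)
    bias_shape = np.sin(2.0 * np.pi * (intensity_g - 6.0) / 10.0)

    # --- per-gene subject intercepts and residuals ----------------------
    rng_subj = substream_rng(seed, "subject_effects")
    b = rng_subj.normal(0.0, config.subject_sd, size=(g, n_subjects))
    rng_res = substream_rng(seed, "residual")
    eps = rng_res.normal(0.0, config.residual_sd, size=(g, n_samples))

    signal = (
        mu[:, None]
        + delta[:, None] * is_case[None, :]
        + b[:, subj_codes]
    )
    array_term = offsets[None, :] + bias_shape[:, None] * amps[None, :]
    values = signal + array_term + eps

    # --- duplicate spots -------------------------------------------------
    n_dup = int(round(config.duplicate_spot_fraction * g))
    rng_dup = substream_rng(seed, "duplicates")
    if n_dup > 0:
        parents = np.sort(rng_dup.choice(g, size=n_dup, replace=False))
        dup_eps = rng_dup.normal(0.0, config.residual_sd, size=(n_dup, n_samples))
        dup_values = signal[parents] + array_term[parents] + dup_eps
        values = np.vstack([values, dup_values])
        intensity_all = np.concatenate([intensity_g, intensity_g[parents]])
        gene_all = np.concatenate([gene_names, gene_names[parents]])
        delta_all = np.concatenate([delta, delta[parents]])
    else:
        parents = np.array([], dtype=int)
        intensity_all = intensity_g
        gene_all = gene_names
        delta_all = delta

    n_spots = values.shape[0]
    spot_ids = pd.Index([f"S{i:06d}" for i in range(1, n_spots + 1)], name="spot_id")
    dup_of = np.array([None] * n_spots, dtype=object)
    for k, p in enumerate(parents):
        dup_of[g + k] = spot_ids[p]

    matrix = ExpressionMatrix(
        values=pd.DataFrame(values, index=spot_ids, columns=samples.sample_ids),
        gene_symbols=pd.Series(gene_all, index=spot_ids, name="gene_symbol"),
        intensity=pd.DataFrame(
            np.repeat(intensity_all[:, None], n_samples, axis=1),
            index=spot_ids, columns=samples.sample_ids),
    )
    truth = TruthTable(pd.DataFrame({
        "gene": gene_all,
        "is_de": delta_all != 0.0,
        "true_log2fc": delta_all,
        "duplicate_of": dup_of,
    }, index=spot_ids))

    if config.missing_rate > 0:
        matrix = simulate_missing(matrix, config.missing_rate, seed)
    return matrix, samples, truth


def simulate_missing(matrix: ExpressionMatrix, rate: float, seed: int) -> ExpressionMatrix:
    """Mask each present cell independently with probability ``rate``.

    Mask-only change: present values are replaced by NaN; nothing else moves.
    """
    if not 0.0 <= rate <= 1.0:
        raise DomainError(f"missing rate must be in [0, 1], got {rate}")
    out = matrix.copy()
    if rate == 0.0:
        return out
    rng = substream_rng(seed, "missing")
    hit = rng.random(out.values.shape) < rate
    vals = out.values.to_numpy()
    vals[hit] = np.nan
    out.values.iloc[:, :] = vals
    return out


def simulate_ct_table(
    truth: TruthTable,
    samples: SampleTable,
    noise_sd: float,
    seed: int,
    genes=None,
    housekeeping: str = "HKG",
    calibrator: str = "REF",
    base_ct: float = 30.0,
    housekeeping_ct: float = 20.0,
) -> CtTable:
    """Simulate qPCR cycle thresholds consistent with the ground truth.

    Ct decreases by one cycle per doubling of expression, so for a target
    gene in a case sample Ct = base_ct - true_log2fc (+ noise), while control
    samples and the universal-reference calibrator sample sit at base_ct. The
    housekeeping gene has zero group effect by construction. With
    ``noise_sd=0``, 2^-ddCt applied to the output recovers 2^(true_log2fc)
    exactly for every case sample.
    """
    if genes is None:
        genes = truth.table.loc[truth.table["is_de"], "gene"].unique().tolist()
    genes = list(genes)
    if not genes:
        raise DomainError("empty gene set for Ct simulation")
    if housekeeping in genes:
        raise DomainError("housekeeping gene must not be a target gene")

    gene_fc = (
        truth.table.drop_duplicates("gene").set_index("gene")["true_log2fc"]
    )
    unknown = [gn for gn in genes if gn not in gene_fc.index]
    if unknown:
        raise DomainError(f"genes not in truth table: {unknown[:5]}")

    rng = substream_rng(seed, "ct")
    sample_ids = list(samples.sample_ids) + [calibrator]
    is_case = np.array(
        [samples.groups.get(s) == GROUP_CASE if s != calibrator else False
         for s in sample_ids])
    cols = {}
    for gn in genes:
        log2_expr = gene_fc[gn] * is_case.astype(float)
        cols[gn] = base_ct - log2_expr + rng.normal(0.0, noise_sd, size=len(sample_ids))
    cols[housekeeping] = housekeeping_ct + rng.normal(0.0, noise_sd, size=len(sample_ids))
    ct = pd.DataFrame(cols, index=pd.Index(sample_ids, name="sample_id"))
    return CtTable(ct, housekeeping=housekeeping, calibrator=calibrator)
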