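"""Negative binomial Wald differential expression.

The model is a per-gene NB GLM with log link, a two-group condition
indicator and log size-factor offsets, fitted by iteratively reweighted
least squares at a fixed per-gene dispersion ``alpha`` (variance
``mu + alpha * mu**2``).  The Wald statistic is the coefficient over its
expected-information standard error; p-values are two-sided tails (Student
t with residual degrees of freedom by default, asymptotic normal on
request) with no multiple-testing adjustment.  Dispersion is a simple per-gene
method-of-moments estimate with a floor — deliberately simpler than
shrinkage-based estimators.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .io import read_tsv, write_tsv

ALPHA_MIN = 1e-8
_LN2 = np.log(2.0)


@dataclass
class CountMatrix:
    """Gene x sample integer counts with a condition label per sample."""

    counts: pd.DataFrame  # genes x samples
    conditions: pd.Series  # index = sample ids

    def __post_init__(self) -> None:
        if not self.counts.columns.equals(self.conditions.index):
            self.conditions = self.conditions.reindex(self.counts.columns)
        if self.conditions.isna().any():
            missing = self.conditions.index[self.conditions.isna()].tolist()
            raise ValueError(f"samples without a condition label: {missing}")
        vals = self.counts.to_numpy()
        if (vals < 0).any():
            raise ValueError("counts must be non-negative")

    @property
    def gene_ids(self) -> pd.Index:
        return self.counts.index

    @property
    def sample_ids(self) -> pd.Index:
        return self.counts.columns

    def samples_for(self, condition: str) -> list[str]:
        sel = self.conditions[self.conditions == condition].index.tolist()
        if not sel:
            raise ValueError(f"no samples with condition {condition!r}")
        return sel

    def subset_conditions(self, conditions: list[str]) -> "CountMatrix":
        samples = [s for s in self.sample_ids if self.conditions[s] in conditions]
        return CountMatrix(self.counts[samples], self.conditions[samples])

    # -- I/O ---------------------------------------------------------------
    @classmethod
    def from_tsv(cls, counts_path: str | Path, samples_path: str | Path) -> "CountMatrix":
        counts = read_tsv(counts_path, index_col=0)
        sheet = read_tsv(samples_path)
        cond = pd.Series(sheet["condition"].values, index=sheet["sample_id"].values)
        return cls(counts[list(cond.index)], cond)

    def to_tsv(self, counts_path: str | Path, samples_path: str | Path) -> None:
        write_tsv(self.counts.rename_axis("gene_id").reset_index(), counts_path)
        sheet = pd.DataFrame({"sample_id": self.sample_ids, "condition": self.conditions.values})
        write_tsv(sheet, samples_path)


@dataclass(frozen=True)
class FilterRule:
    """Low-count gene filter.

    ``literal-exclusion`` drops a gene when at least ``min_samples`` samples
    have a count below ``min_count``; ``detection-keep`` drops it when fewer
    than ``min_samples`` samples reach ``min_count``.
    """

    min_count: int = 5
    min_samples: int = 3
    mode: str = "literal-exclusion"

    def __post_init__(self) -> None:
        if self.min_count < 0 or self.min_samples < 1:
            raise ValueError("min_count >= 0 and min_samples >= 1 required")
        if self.mode not in ("literal-exclusion", "detection-keep"):
            raise ValueError(f"unknown filter mode {self.mode!r}")


@dataclass(frozen=True)
class DEGThresholds:
    lfc_threshold: float = 0.5
    p_threshold: float = 0.05

    def __post_init__(self) -> None:
        if self.lfc_threshold < 0 or not 0 < self.p_threshold < 1:
            raise ValueError("invalid DEG thresholds")


def filter_low_counts(matrix: CountMatrix, rule: FilterRule = FilterRule()) -> CountMatrix:
    """Remove low-count genes; gene order of the survivors is preserved."""
    if rule.min_samples > matrix.counts.shape[1]:
        raise ValueError("min_samples exceeds the number of samples")
    vals = matrix.counts.to_numpy()
    if rule.mode == "literal-exclusion":
        drop = (vals < rule.min_count).sum(axis=1) >= rule.min_samples
    else:
        drop = (vals >= rule.min_count).sum(axis=1) < rule.min_samples
    kept = matrix.counts.loc[~drop]
    if kept.empty:
        warnings.warn("low-count filter removed every gene", stacklevel=2)
    return CountMatrix(kept, matrix.conditions)


def estimate_size_factors(matrix: CountMatrix) -> pd.Series:
    """Median-of-ratios size factors.

    For genes positive in every sample, each sample's factor is the median
    ratio of its count to the gene's geometric mean across samples.
    """
    vals = matrix.counts.to_numpy(dtype=float)
    allpos = (vals > 0).all(axis=1)
    if not allpos.any():
        raise ValueError(
            "no gene has positive counts in every sample; "
            "median-of-ratios is undefined (consider a pseudocount)"
        )
    logs = np.log(vals[allpos])
    log_geo = logs.mean(axis=1, keepdims=True)
    factors = np.exp(np.median(logs - log_geo, axis=0))
    return pd.Series(factors, index=matrix.sample_ids, name="size_factor")


def estimate_dispersions(
    matrix: CountMatrix,
    factors: pd.Series,
    conditions: tuple[str, str] | list[str],
    alpha_min: float = ALPHA_MIN,
) -> pd.Series:
    """Per-gene method-of-moments dispersion on normalised counts.

    Within each condition of the contrast,
    ``alpha_c = max((s^2 - m) / m^2, alpha_min)``; the per-gene estimate is
    the mean of the per-condition values.
    """
    per_cond = []
    for cond in conditions:
        samples = matrix.samples_for(cond)
        if len(samples) < 2:
            raise ValueError(f"condition {cond!r} needs >= 2 replicates")
        norm = matrix.counts[samples].to_numpy(dtype=float) / factors[samples].to_numpy()
        m = norm.mean(axis=1)
        v = norm.var(axis=1, ddof=1)
        with np.errstate(divide="ignore", invalid="ignore"):
            a = (v - m) / np.square(m)
        a = np.where(np.isfinite(a), a, 0.0)
        per_cond.append(np.maximum(a, alpha_min))  # floor per condition, then average
    alpha = np.maximum(np.mean(per_cond, axis=0), alpha_min)
    return pd.Series(alpha, index=matrix.gene_ids, name="alpha")


def wald_de(
    matrix: CountMatrix,
    factors: pd.Series,
    dispersions: pd.Series,
    contrast: tuple[str, str],
    max_iter: int = 100,
    tol: float = 1e-10,
    tail: str = "t",
) -> pd.DataFrame:
    """Two-group NB Wald test for ``contrast = (A, B)`` (log2FC of A over B).

    Returns one row per gene with columns gene_id, base_mean, log2FC, SE,
    stat, p, status.  ``status`` is ``ok``, ``all-zero`` (no counts in the
    contrast; statistics undefined), ``low-count`` (a group is all zero;
    the fold change is unbounded) or ``no-converge``.

    ``tail`` selects the reference distribution for the two-sided p-value:
    ``"t"`` (default) uses Student's t with ``n_samples - 2`` degrees of
    freedom, which stays calibrated at half-dozen replicates where the
    plug-in dispersion makes the plain normal tail anticonservative;
    ``"normal"`` gives the asymptotic Wald tail.
    """
    cond_a, cond_b = contrast
    samples_a = matrix.samples_for(cond_a)
    samples_b = matrix.samples_for(cond_b)
    if len(samples_a) < 2 or len(samples_b) < 2:
        raise ValueError("both contrast conditions need >= 2 replicates")
    samples = samples_a + samples_b
    y = matrix.counts[samples].to_numpy(dtype=float)
    sf = factors[samples].to_numpy(dtype=float)
    offset = np.log(sf)
    x = np.array([1.0] * len(samples_a) + [0.0] * len(samples_b))
    alpha = dispersions.reindex(matrix.gene_ids).to_numpy(dtype=float)[:, None]

    n_genes = y.shape[0]
    norm = y / sf
    mean_a = norm[:, x == 1].mean(axis=1)
    mean_b = norm[:, x == 0].mean(axis=1)
    base_mean = norm.mean(axis=1)

    all_zero = (y.sum(axis=1) == 0)
    one_sided_zero = ((mean_a == 0) | (mean_b == 0)) & ~all_zero

    # working-response IRLS with weights mu / (1 + alpha mu)
    b0 = np.log(np.maximum(mean_b, 1e-8))
    b1 = np.log(np.maximum(mean_a, 1e-8)) - b0
    converged = np.zeros(n_genes, dtype=bool)
    active = ~(all_zero | one_sided_zero)
    for _ in range(max_iter):
        eta = b0[:, None] + b1[:, None] * x[None, :] + offset[None, :]
        mu = np.exp(np.clip(eta, -50, 50))
        w = mu / (1.0 + alpha * mu)
        z = (eta - offset[None, :]) + (y - mu) / mu
        sw = w.sum(axis=1)
        swx = (w * x).sum(axis=1)  # x binary: sum of w over group A
        swz = (w * z).sum(axis=1)
        swxz = (w * x * z).sum(axis=1)
        det = swx * (sw - swx)
        with np.errstate(divide="ignore", invalid="ignore"):
            new_b1 = (sw * swxz - swx * swz) / det
            new_b0 = (swz - swx * new_b1) / sw
        step = np.abs(new_b0 - b0) + np.abs(new_b1 - b1)
        upd = active & ~converged & np.isfinite(new_b0) & np.isfinite(new_b1)
        b0 = np.where(upd, new_b0, b0)
        b1 = np.where(upd, new_b1, b1)
        converged |= active & (step < tol)
        if (converged | ~active).all():
            break

    eta = b0[:, None] + b1[:, None] * x[None, :] + offset[None, :]
    mu = np.exp(np.clip(eta, -50, 50))
    w = mu / (1.0 + alpha * mu)
    sw_a = (w * x).sum(axis=1)
    sw_b = (w * (1 - x)).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_b1 = 1.0 / sw_a + 1.0 / sw_b

    log2fc = b1 / _LN2
    se = np.sqrt(var_b1) / _LN2
    stat = log2fc / se
    if tail == "t":
        p = 2.0 * stats.t.sf(np.abs(stat), df=len(samples) - 2)
    elif tail == "normal":
        p = 2.0 * stats.norm.sf(np.abs(stat))
    else:
        raise ValueError(f"unknown tail {tail!r}")

    status = np.full(n_genes, "ok", dtype=object)
    status[~converged & active] = "no-converge"
    status[one_sided_zero] = "low-count"
    status[all_zero] = "all-zero"
    bad = status != "ok"
    p[bad] = np.nan
    stat[bad] = np.nan
    se[bad] = np.nan
    with np.errstate(divide="ignore"):
        log2fc[one_sided_zero] = np.log2(
            np.maximum(mean_a[one_sided_zero], 1e-12) / np.maximum(mean_b[one_sided_zero], 1e-12)
        )
    log2fc[all_zero] = np.nan

    return pd.DataFrame(
        {
            "gene_id": matrix.gene_ids,
            "base_mean": base_mean,
            "log2FC": log2fc,
            "SE": se,
            "stat": stat,
            "p": p,
            "status": status,
        }
    ).reset_index(drop=True)


def call_degs(results: pd.DataFrame, thresholds: DEGThresholds = DEGThresholds()) -> pd.DataFrame:
    """Differentially expressed genes at strict |log2FC| and p cut-offs."""
    if results.empty:
        raise ValueError("empty DE result table")
    ok = results["status"] == "ok"
    hit = ok & (results["log2FC"].abs() > thresholds.lfc_threshold) & (
        results["p"] < thresholds.p_threshold
    )
    degs = results.loc[hit, ["gene_id", "log2FC", "p"]].copy()
    degs["direction"] = np.where(degs["log2FC"] > 0, "up", "down")
    return degs.reset_index(drop=True)


def run_contrast(
    matrix: CountMatrix,
    contrast: tuple[str, str],
    factors: pd.Series | None = None,
) -> pd.DataFrame:
    """Convenience wrapper: size factors (if not given) -> dispersions -> Wald."""
    if factors is None:
        factors = estimate_size_factors(matrix)
    disp = estimate_dispersions(matrix, factors, list(contrast))
    return wald_de(matrix, factors, disp, contrast)
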