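"""Negative binomial count matrices with planted disease and rescue effects.

The variance convention is ``var = mu + alpha * mu**2`` throughout, matching
the differential expression core.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from ..de import CountMatrix

_ALPHA_MIN = 1e-8


@dataclass(frozen=True)
class SimCountsConfig:
    """Layout and effect sizes for a simulated bulk RNA-seq experiment.

    ``condition_layout`` lists (condition label, n replicates) in order; the
    first entry is the healthy reference.  Genes drawn as differentially
    expressed carry their planted log2 fold change in ``disease_condition``
    and in every ``suppressor_conditions`` entry, except that a
    ``rescue_fraction`` subset of them is reverted to baseline (lfc 0) in
    the suppressor conditions.
    """

    n_genes: int = 2000
    condition_layout: tuple[tuple[str, int], ...] = (("Q15", 6), ("Q128", 7), ("Q128_Mtf1", 6))
    baseline_log_mean: tuple[float, float] = (4.0, 1.5)
    dispersion_dist: tuple[float, float] = (2.0, 0.05)  # gamma (shape, scale)
    de_fraction: float = 0.1
    lfc_dist: tuple[float, float, float] = (1.0, 0.25, 0.5)  # (mean, sd, P(sign +))
    rescue_fraction: float = 0.4
    libsize_factors: tuple[float, ...] | None = None
    disease_condition: str | None = None  # default: second condition
    suppressor_conditions: tuple[str, ...] | None = None  # default: the rest
    seed: int = 0

    def __post_init__(self) -> None:
        labels = [c for c, _ in self.condition_layout]
        if len(set(labels)) != len(labels) or len(labels) < 1:
            raise ValueError("condition labels must be unique and non-empty")
        for cond, n in self.condition_layout:
            if n < 2:
                raise ValueError(f"condition {cond}: need >= 2 replicates, got {n}")
        for frac, what in [(self.de_fraction, "de_fraction"), (self.rescue_fraction, "rescue_fraction")]:
            if not 0 <= frac <= 1:
                raise ValueError(f"{what} must be in [0, 1]")
        if self.dispersion_dist[0] <= 0 or self.dispersion_dist[1] <= 0:
            raise ValueError("dispersion gamma parameters must be positive")
        if self.libsize_factors is not None:
            if len(self.libsize_factors) != self.n_samples:
                raise ValueError("libsize_factors length must equal total sample count")
            if any(f <= 0 for f in self.libsize_factors):
                raise ValueError("libsize_factors must be positive")
        for cond in list(self.suppressor_conditions or []) + (
            [self.disease_condition] if self.disease_condition else []
        ):
            if cond not in labels:
                raise ValueError(f"unknown condition {cond!r}")

    @property
    def n_samples(self) -> int:
        return sum(n for _, n in self.condition_layout)

    @property
    def reference(self) -> str:
        return self.condition_layout[0][0]

    @property
    def disease(self) -> str | None:
        if self.disease_condition is not None:
            return self.disease_condition
        return self.condition_layout[1][0] if len(self.condition_layout) > 1 else None

    @property
    def suppressors(self) -> tuple[str, ...]:
        if self.suppressor_conditions is not None:
            return self.suppressor_conditions
        skip = {self.reference, self.disease}
        return tuple(c for c, _ in self.condition_layout if c not in skip)


@dataclass(frozen=True)
class SimCountsTruth:
    true_lfc: pd.DataFrame  # genes x conditions, log2 fold change vs reference
    true_de: frozenset[str]
    true_rescued: frozenset[str]
    baseline: pd.Series
    dispersion: pd.Series


def simulate_counts(config: SimCountsConfig) -> tuple[CountMatrix, SimCountsTruth]:
    """Draw an NB count matrix with planted effects; returns matrix + truth."""
    rng = np.random.default_rng([config.seed, 0xC])
    genes = [f"gene{i:05d}" for i in range(config.n_genes)]
    conditions = [c for c, _ in config.condition_layout]

    mu0, sigma0 = config.baseline_log_mean
    baseline = rng.lognormal(mu0, sigma0, config.n_genes)
    shape, scale = config.dispersion_dist
    alpha = np.maximum(rng.gamma(shape, scale, config.n_genes), _ALPHA_MIN)

    n_de = int(round(config.de_fraction * config.n_genes))
    de_idx = rng.choice(config.n_genes, size=n_de, replace=False)
    mean_l, sd_l, p_up = config.lfc_dist
    signs = np.where(rng.random(n_de) < p_up, 1.0, -1.0)
    planted = signs * rng.normal(mean_l, sd_l, n_de)
    n_resc = int(round(config.rescue_fraction * n_de))
    rescued_idx = rng.choice(de_idx, size=n_resc, replace=False) if n_resc else np.array([], dtype=int)

    lfc = pd.DataFrame(0.0, index=genes, columns=conditions)
    if config.disease is not None:
        lfc.loc[np.array(genes)[de_idx], config.disease] = planted
        for cond in config.suppressors:
            lfc[cond] = lfc[config.disease]
            lfc.loc[np.array(genes)[rescued_idx], cond] = 0.0

    sample_ids: list[str] = []
    sample_cond: list[str] = []
    for cond, n in config.condition_layout:
        for r in range(n):
            sample_ids.append(f"{cond}_r{r + 1}")
            sample_cond.append(cond)
    libsize = (
        np.asarray(config.libsize_factors, dtype=float)
        if config.libsize_factors is not None
        else np.ones(len(sample_ids))
    )

    mu = (
        baseline[:, None]
        * np.power(2.0, lfc[sample_cond].to_numpy())
        * libsize[None, :]
    )
    counts = _nb_draw(rng, mu, alpha[:, None])

    matrix = CountMatrix(
        counts=pd.DataFrame(counts, index=genes, columns=sample_ids),
        conditions=pd.Series(sample_cond, index=sample_ids, name="condition"),
    )
    truth = SimCountsTruth(
        true_lfc=lfc,
        true_de=frozenset(np.array(genes)[de_idx]),
        true_rescued=frozenset(np.array(genes)[rescued_idx]),
        baseline=pd.Series(baseline, index=genes, name="baseline"),
        dispersion=pd.Series(alpha, index=genes, name="alpha"),
    )
    return matrix, truth


def _nb_draw(rng: np.random.Generator, mu: np.ndarray, alpha: np.ndarray) -> np.ndarray:
    """NB(mu, var = mu + alpha mu^2) draws; Poisson in the alpha -> 0 limit."""
    alpha = np.broadcast_to(alpha, mu.shape)
    out = np.empty(mu.shape, dtype=np.int64)
    tiny = alpha <= 1e-7
    if tiny.any():
        out[tiny] = rng.poisson(mu[tiny])
    if (~tiny).any():
        size = 1.0 / alpha[~tiny]
        p = size / (size + mu[~tiny])
        out[~tiny] = rng.negative_binomial(size, p)
    return out
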