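"""Rescue classification and gene-set overlap statistics.

A disease DEG counts as "rescued" by a suppressor when its expression under
the suppressor is statistically indistinguishable from the healthy control
(p >= p_ns_threshold in the suppressor-vs-healthy contrast) while being
shifted away from the disease state (|log2FC| > lfc_threshold in the
suppressor-vs-disease contrast).  Genes lacking either statistic are
conservatively called not rescued.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.proportion import proportions_ztest


@dataclass(frozen=True)
class RescueRule:
    p_ns_threshold: float = 0.05  # suppressor vs healthy: "no longer different"
    lfc_threshold: float = 0.5  # suppressor vs disease: "moved away"

    def __post_init__(self) -> None:
        if self.p_ns_threshold <= 0 or self.lfc_threshold <= 0:
            raise ValueError("rescue thresholds must be positive")


def classify_rescue(
    deg_set: pd.DataFrame,
    de_suppr_vs_healthy: pd.DataFrame,
    de_suppr_vs_disease: pd.DataFrame,
    rule: RescueRule = RescueRule(),
) -> tuple[pd.DataFrame, float]:
    """Classify each disease DEG as rescued or not.

    ``deg_set`` is the disease-vs-healthy DEG table (gene_id, direction);
    the two DE tables are indexed by gene_id with columns p and log2FC.
    Returns the per-gene call table and the rescue fraction in percent.
    """
    if deg_set.empty:
        raise ValueError("empty DEG set: rescue fraction undefined")
    vh = de_suppr_vs_healthy.set_index("gene_id") if "gene_id" in de_suppr_vs_healthy else de_suppr_vs_healthy
    vd = de_suppr_vs_disease.set_index("gene_id") if "gene_id" in de_suppr_vs_disease else de_suppr_vs_disease

    rows = []
    for r in deg_set.itertuples(index=False):
        gene = r.gene_id
        p_vs_healthy = float(vh.at[gene, "p"]) if gene in vh.index else np.nan
        lfc_vs_disease = float(vd.at[gene, "log2FC"]) if gene in vd.index else np.nan
        rescued = (
            np.isfinite(p_vs_healthy)
            and np.isfinite(lfc_vs_disease)
            and p_vs_healthy >= rule.p_ns_threshold
            and abs(lfc_vs_disease) > rule.lfc_threshold
        )
        rows.append((gene, getattr(r, "direction", "na"), bool(rescued), p_vs_healthy, lfc_vs_disease))

    calls = pd.DataFrame(
        rows,
        columns=["gene_id", "mHTT_direction", "rescued", "p_vs_healthy", "log2FC_vs_disease"],
    )
    fraction = 100.0 * calls["rescued"].sum() / len(calls)
    return calls, float(fraction)


def overlap_binomial_test(universe_size: int, set_a: set, set_b: set) -> dict[str, float]:
    """One-sided binomial test for under-representation of the overlap.

    Conditioning on the smaller set (size n1), the overlap under
    independence is Binomial(n1, n2/N); p = P(X <= k_observed).
    """
    if universe_size <= 0:
        raise ValueError("universe size must be positive")
    n1, n2 = sorted((len(set_a), len(set_b)))
    if max(len(set_a), len(set_b)) > universe_size:
        raise ValueError("set larger than the universe")
    k = len(set_a & set_b)
    expected = n1 * n2 / universe_size
    p = float(stats.binom.cdf(k, n1, n2 / universe_size)) if n1 > 0 else 1.0
    return {
        "universe": universe_size,
        "n1": n1,
        "n2": n2,
        "union": len(set_a | set_b),
        "intersection": k,
        "expected": expected,
        "p": p,
        "direction": "under" if k < expected else "over-or-equal",
    }


def geneset_overrepresentation(query: set, gene_set: set, universe: set) -> dict[str, float]:
    """Hypergeometric over-representation of ``gene_set`` members in ``query``."""
    if not query:
        raise ValueError("empty query set")
    if not (query <= universe and gene_set <= universe):
        raise ValueError("query and gene_set must be subsets of the universe")
    n_universe = len(universe)
    overlap = len(query & gene_set)
    p = float(stats.hypergeom.sf(overlap - 1, n_universe, len(gene_set), len(query)))
    return {
        "query_size": len(query),
        "gene_set_size": len(gene_set),
        "universe_size": n_universe,
        "overlap": overlap,
        "p": p,
    }


def compare_rescue_profiles(
    deg_set: pd.DataFrame,
    condition_tables: dict[str, tuple[pd.DataFrame, pd.DataFrame]],
    rule: RescueRule = RescueRule(),
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Rescue fraction per suppressor condition plus pairwise two-proportion
    z-tests on the rescued counts over the common DEG denominator.

    ``condition_tables`` maps condition label to
    (DE table vs healthy, DE table vs disease).
    """
    if len(condition_tables) < 2:
        raise ValueError("need at least two conditions to compare")
    n = len(deg_set)
    fractions = []
    rescued_counts = {}
    for cond, (vs_healthy, vs_disease) in condition_tables.items():
        calls, frac = classify_rescue(deg_set, vs_healthy, vs_disease, rule)
        rescued_counts[cond] = int(calls["rescued"].sum())
        fractions.append((cond, rescued_counts[cond], n, frac))
    frac_table = pd.DataFrame(
        fractions, columns=["condition", "n_rescued", "n_degs", "fraction_pct"]
    )

    pair_rows = []
    conds = list(condition_tables)
    for i in range(len(conds)):
        for j in range(i + 1, len(conds)):
            a, b = conds[i], conds[j]
            if rescued_counts[a] == rescued_counts[b]:
                z, p = 0.0, 1.0  # identical proportions: no evidence by construction
            else:
                z, p = proportions_ztest(
                    [rescued_counts[a], rescued_counts[b]], [n, n], alternative="two-sided"
                )
            pair_rows.append((a, b, float(z), float(p)))
    pairs = pd.DataFrame(pair_rows, columns=["condition_a", "condition_b", "z", "p"])
    return frac_table, pairs
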