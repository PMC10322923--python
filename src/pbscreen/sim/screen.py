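"""Planted integration screens: multinomial event sampling over TTAA sites
with optional enrichment near suppressor genes, expanded to clonal
read-level records."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from ..io import GeneAnnotation
from .annotation import SimScreenConfig


@dataclass(frozen=True)
class SimScreenTruth:
    """Ground truth for one simulated screen."""

    true_suppressors: frozenset[str]
    # one row per event: chrom, pos, orientation, experiment
    true_sites: pd.DataFrame


def simulate_screen(
    config: SimScreenConfig,
    genes: list[GeneAnnotation],
    ttaa_index: dict[str, np.ndarray],
) -> tuple[pd.DataFrame, SimScreenTruth]:
    """Draw integration events and expand them to read records.

    Each experiment draws ``events_per_experiment`` sites from the TTAA
    index with probability proportional to 1 for background sites and
    ``enrichment_multiplier`` for sites within ``window_bp`` of a
    suppressor gene body.  Draws of the same site within one experiment
    collapse to a single event.  Every event is expanded to >=1 records
    sharing (experiment, site) to mimic clonal amplification.

    Returns the record table (columns experiment_id, sample_id, chrom, pos,
    orientation, read_count) and the planted truth.
    """
    unknown = config.suppressor_genes - {g.gene_id for g in genes}
    if unknown:
        raise ValueError(f"suppressor genes not in annotation: {sorted(unknown)}")

    chroms, positions = _flatten(ttaa_index)
    if len(positions) == 0:
        raise ValueError("TTAA index is empty: cannot place integrations")

    weights = np.ones(len(positions))
    if config.enrichment_multiplier > 1:
        for g in genes:
            if g.gene_id not in config.suppressor_genes:
                continue
            on_chrom = chroms == g.chrom
            near = (
                (positions >= g.start - config.window_bp)
                & (positions < g.end + config.window_bp)
                & on_chrom
            )
            weights[near] = config.enrichment_multiplier
    prob = weights / weights.sum()

    rng = np.random.default_rng([config.seed, 0xB])
    dist_name, dist_param = config.clonal_read_dist
    if dist_name != "poisson":
        raise ValueError(f"unsupported clonal_read_dist {dist_name!r}")

    rows = []
    events = []
    for e in range(config.n_experiments):
        exp = f"exp{e + 1}"
        drawn = rng.choice(len(positions), size=config.events_per_experiment, p=prob)
        for site_idx in np.unique(drawn):
            chrom = chroms[site_idx]
            pos = int(positions[site_idx])
            orient = "+" if rng.random() < 0.5 else "-"
            events.append((chrom, pos, orient, exp))
            n_records = int(rng.integers(1, 4))
            for r in range(n_records):
                read_count = 1 + int(rng.poisson(dist_param))
                rows.append((exp, f"{exp}_s{r + 1}", chrom, pos, orient, read_count))

    records = pd.DataFrame(
        rows,
        columns=["experiment_id", "sample_id", "chrom", "pos", "orientation", "read_count"],
    )
    truth = SimScreenTruth(
        true_suppressors=frozenset(config.suppressor_genes),
        true_sites=pd.DataFrame(events, columns=["chrom", "pos", "orientation", "experiment"]),
    )
    return records, truth


def _flatten(ttaa_index: dict[str, np.ndarray]) -> tuple[np.ndarray, np.ndarray]:
    chroms = []
    positions = []
    for chrom in sorted(ttaa_index):
        pos = ttaa_index[chrom]
        chroms.append(np.repeat(chrom, len(pos)))
        positions.append(pos)
    if not chroms:
        return np.array([], dtype=object), np.array([], dtype=np.int64)
    return np.concatenate(chroms), np.concatenate(positions).astype(np.int64)
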