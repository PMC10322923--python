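"""Integration-site hit-calling.

Read-level records are collapsed to events (experiment x site) and unique
sites, sites are assigned to genes within a distance window, per-gene event
tallies are tested against a TTAA-density binomial null with
Benjamini-Hochberg correction, and candidates must additionally recur in a
minimum number of independent experiments.  Unique sites (not reads or
events) enter the test so clonal expansion cannot inflate significance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .io import GeneAnnotation, find_ttaa

Event = tuple[str, str, int, str]  # (experiment_id, chrom, pos, orientation)
Site = tuple[str, int, str]  # (chrom, pos, orientation)

RECORD_COLUMNS = ["experiment_id", "sample_id", "chrom", "pos", "orientation", "read_count"]


@dataclass(frozen=True)
class ScreenCallConfig:
    window_bp: int = 20_000
    min_experiments: int = 2
    fdr_q: float = 0.05
    assignment_mode: str = "nearest"  # or "all-within-window"

    def __post_init__(self) -> None:
        if self.window_bp <= 0:
            raise ValueError("window_bp must be > 0")
        if not 0 < self.fdr_q < 1:
            raise ValueError("fdr_q must be in (0, 1)")
        if self.assignment_mode not in ("nearest", "all-within-window"):
            raise ValueError(f"unknown assignment_mode {self.assignment_mode!r}")


@dataclass
class CollapseResult:
    events: set[Event]
    sites: set[Site]
    provenance: pd.DataFrame  # per site: reads, samples seen

    @property
    def n_events(self) -> int:
        return len(self.events)

    @property
    def n_sites(self) -> int:
        return len(self.sites)


@dataclass
class TTAAIndex:
    """Per-gene-window TTAA counts and the genome-wide total."""

    per_gene: pd.Series  # T_g, indexed by gene_id
    total: int  # T

    def __post_init__(self) -> None:
        if ((self.per_gene < 0) | (self.per_gene > self.total)).any():
            raise ValueError("require 0 <= T_g <= T")


def collapse_records(records: pd.DataFrame) -> CollapseResult:
    """Distinct events and unique sites from read-level records.

    Read multiplicities and sample ids are discarded from the event/site
    sets but summarised in the provenance table (reads and distinct samples
    per unique site).
    """
    if records.empty:
        raise ValueError("no integration records")
    for i, row in enumerate(records.itertuples(index=False), 1):
        if int(row.pos) < 0:
            raise ValueError(f"record {i}: negative position {row.pos}")
        if int(row.read_count) < 1:
            raise ValueError(f"record {i}: read_count must be >= 1")
        if not str(row.experiment_id) or not str(row.chrom) or str(row.orientation) not in "+-":
            raise ValueError(f"record {i}: malformed labels")

    events = {
        (str(r.experiment_id), str(r.chrom), int(r.pos), str(r.orientation))
        for r in records.itertuples(index=False)
    }
    sites = {(c, p, o) for _, c, p, o in events}
    prov = (
        records.groupby(["chrom", "pos", "orientation"], sort=True)
        .agg(
            total_reads=("read_count", "sum"),
            n_records=("read_count", "size"),
            n_samples=("sample_id", "nunique"),
            n_experiments=("experiment_id", "nunique"),
        )
        .reset_index()
    )
    return CollapseResult(events=events, sites=sites, provenance=prov)


def validate_ttaa(
    sites: set[Site], genome: dict[str, str], keep_invalid: bool = False
) -> pd.DataFrame:
    """Flag every site by exact TTAA comparison against the genome."""
    rows = []
    for chrom, pos, orient in sorted(sites):
        if chrom not in genome:
            raise ValueError(f"site {chrom}:{pos}: unknown chromosome")
        if pos + 4 > len(genome[chrom]):
            raise ValueError(f"site {chrom}:{pos}: beyond chromosome end")
        rows.append((chrom, pos, orient, genome[chrom][pos : pos + 4] == "TTAA"))
    report = pd.DataFrame(rows, columns=["chrom", "pos", "orientation", "ttaa_ok"])
    if not keep_invalid:
        report = report  # caller filters via the flag; kept for symmetry
    return report


def assign_genes(
    sites: set[Site],
    genes: list[GeneAnnotation],
    config: ScreenCallConfig = ScreenCallConfig(),
) -> pd.DataFrame:
    """Associate sites to genes within ``window_bp`` of the gene body.

    ``nearest`` mode keeps the single closest gene (ties broken by
    gene_id); ``all-within-window`` emits one row per qualifying gene.
    Unassignable sites are simply absent from the output.
    """
    by_chrom: dict[str, list[GeneAnnotation]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    chrom_arrays = {
        c: (
            np.array([g.start for g in gs]),
            np.array([g.end for g in gs]),
            np.array([g.gene_id for g in gs]),
            np.array([g.strand for g in gs]),
        )
        for c, gs in by_chrom.items()
    }

    rows = []
    for chrom, pos, orient in sorted(sites):
        if chrom not in chrom_arrays:
            continue
        starts, ends, ids, strands = chrom_arrays[chrom]
        dist = np.where(
            pos < starts,
            starts - pos,
            np.where(pos >= ends, pos - (ends - 1), 0),
        )
        within = dist <= config.window_bp
        if not within.any():
            continue
        if config.assignment_mode == "nearest":
            dmin = dist[within].min()
            cands = np.nonzero(within & (dist == dmin))[0]
            chosen = [cands[np.argsort(ids[cands])[0]]]
        else:
            chosen = np.nonzero(within)[0]
        for j in chosen:
            if dist[j] == 0:
                location = "inside"
            else:
                before = pos < starts[j]
                if strands[j] == "+":
                    location = "upstream" if before else "downstream"
                else:
                    location = "downstream" if before else "upstream"
            rows.append(
                (
                    chrom,
                    pos,
                    orient,
                    ids[j],
                    int(dist[j]),
                    "sense" if orient == strands[j] else "antisense",
                    location,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "chrom",
            "pos",
            "orientation",
            "gene_id",
            "distance_bp",
            "relative_orientation",
            "location",
        ],
    )


def tally_gene_events(assignments: pd.DataFrame, events: set[Event]) -> pd.DataFrame:
    """Per-gene unique sites, events and contributing experiments."""
    exps_by_site: dict[Site, set[str]] = {}
    for exp, chrom, pos, orient in events:
        exps_by_site.setdefault((chrom, pos, orient), set()).add(exp)

    rows = []
    for gene_id, grp in assignments.groupby("gene_id", sort=True):
        gene_sites = {
            (r.chrom, int(r.pos), r.orientation) for r in grp.itertuples(index=False)
        }
        missing = [s for s in gene_sites if s not in exps_by_site]
        if missing:
            raise ValueError(f"assigned sites absent from event set: {missing[:3]}")
        gene_events = {(exp, *s) for s in gene_sites for exp in exps_by_site[s]}
        rows.append(
            (
                gene_id,
                len(gene_sites),
                len(gene_events),
                len({e[0] for e in gene_events}),
            )
        )
    return pd.DataFrame(rows, columns=["gene_id", "n_unique_sites", "n_events", "n_experiments"])


def build_ttaa_index(
    genome: dict[str, str],
    genes: list[GeneAnnotation],
    config: ScreenCallConfig = ScreenCallConfig(),
    ttaa_positions: dict[str, np.ndarray] | None = None,
) -> TTAAIndex:
    """Count TTAA starts in [start - window, end + window) per gene and
    genome-wide.  A precomputed per-chromosome TTAA position map may be
    supplied to skip the scan."""
    if ttaa_positions is None:
        ttaa_positions = {c: find_ttaa(seq) for c, seq in genome.items()}
    total = int(sum(len(v) for v in ttaa_positions.values()))
    tg = {}
    for g in genes:
        pos = ttaa_positions.get(g.chrom, np.empty(0, dtype=np.int64))
        lo = np.searchsorted(pos, g.start - config.window_bp, side="left")
        hi = np.searchsorted(pos, g.end + config.window_bp, side="left")
        tg[g.gene_id] = int(hi - lo)
    return TTAAIndex(per_gene=pd.Series(tg, name="T_g", dtype=int), total=total)


def benjamini_hochberg(p: np.ndarray) -> np.ndarray:
    """BH step-up q-values (monotone, q >= p)."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    q_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    q = np.empty(m)
    q[order] = np.minimum(q_sorted, 1.0)
    return q


def call_candidates(
    tallies: pd.DataFrame,
    index: TTAAIndex,
    config: ScreenCallConfig = ScreenCallConfig(),
    n_total_sites: int | None = None,
) -> pd.DataFrame:
    """Binomial test of per-gene unique-site counts against TTAA density.

    Every annotated gene with ``T_g > 0`` enters the test (observed count 0
    where no site was assigned); ``p = P(X >= k)`` with
    ``X ~ Binomial(K, T_g / T)`` where ``K`` is the total number of unique
    sites.  Genes with observed sites but ``T_g = 0`` violate the null
    support: they are flagged, given a 0-surrogate p and excluded from the
    BH correction.  A candidate needs ``q < fdr_q`` and recurrence in at
    least ``min_experiments`` experiments.
    """
    if index.total <= 0:
        raise ValueError("TTAA index is empty")
    if n_total_sites is None:
        n_total_sites = int(tallies["n_unique_sites"].sum())
    if n_total_sites <= 0:
        raise ValueError("need at least one unique site")

    table = (
        index.per_gene.rename("T_g")
        .rename_axis("gene_id")
        .reset_index()
        .merge(tallies, on="gene_id", how="outer")
    )
    for col in ("n_unique_sites", "n_events", "n_experiments", "T_g"):
        table[col] = pd.to_numeric(table[col], errors="coerce").fillna(0).astype(int)
    table["expected_fraction"] = table["T_g"] / index.total

    violation = (table["T_g"] == 0) & (table["n_unique_sites"] > 0)
    testable = table["T_g"] > 0
    p = np.full(len(table), np.nan)
    k = table["n_unique_sites"].to_numpy()
    p[testable.to_numpy()] = stats.binom.sf(
        k[testable.to_numpy()] - 1,
        n_total_sites,
        table.loc[testable, "expected_fraction"].to_numpy(),
    )
    p[violation.to_numpy()] = 0.0
    table["p"] = p
    q = np.full(len(table), np.nan)
    q[testable.to_numpy()] = benjamini_hochberg(p[testable.to_numpy()])
    table["q"] = q
    table["null_violation"] = violation
    table["is_candidate"] = (
        testable
        & (table["q"] < config.fdr_q)
        & (table["n_experiments"] >= config.min_experiments)
    )
    table = table.sort_values(["q", "gene_id"], na_position="last", kind="stable")
    return table.reset_index(drop=True)


def summarize_bubble(tallies: pd.DataFrame) -> pd.DataFrame:
    """(gene, n_events, n_experiments) table, alphabetical by gene."""
    if tallies.empty:
        raise ValueError("no tallies to summarise")
    out = tallies[["gene_id", "n_events", "n_experiments"]].copy()
    return out.sort_values("gene_id", kind="stable").reset_index(drop=True)
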