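import math

import numpy as np
import pandas as pd
import pytest

from pbscreen.io import GeneAnnotation
from pbscreen.screen import (
    ScreenCallConfig,
    TTAAIndex,
    assign_genes,
    benjamini_hochberg,
    build_ttaa_index,
    call_candidates,
    collapse_records,
    summarize_bubble,
    tally_gene_events,
    validate_ttaa,
)

from conftest import naive_ttaa_scan, random_records


def make_records(rows):
    return pd.DataFrame(
        rows, columns=["experiment_id", "sample_id", "chrom", "pos", "orientation", "read_count"]
    )


# ---------------------------------------------------------------------------
# collapse_records
# ---------------------------------------------------------------------------

class TestCollapse:
    def test_clonal_duplicates_one_event(self):
        recs = make_records([
            ("e1", "s1", "chr1", 100, "+", 5),
            ("e1", "s2", "chr1", 100, "+", 2),
            ("e1", "s1", "chr1", 100, "+", 9),
        ])
        res = collapse_records(recs)
        assert res.n_events == 1 and res.n_sites == 1
        assert res.provenance.total_reads.iloc[0] == 16

    def test_same_site_two_experiments(self):
        # events vs unique sites: recurrence across experiments counts twice
        recs = make_records([
            ("e1", "s1", "chr1", 100, "+", 1),
            ("e2", "s1", "chr1", 100, "+", 1),
        ])
        res = collapse_records(recs)
        assert res.n_events == 2 and res.n_sites == 1

    def test_random_records_match_set_oracle(self, rng):
        recs = random_records(rng, 1000)
        res = collapse_records(recs)
        events = {
            (r.experiment_id, r.chrom, int(r.pos), r.orientation)
            for r in recs.itertuples(index=False)
        }
        sites = {(c, p, o) for _, c, p, o in events}
        assert res.n_events == len(events)
        assert res.n_sites == len(sites)
        assert res.events == events and res.sites == sites

    def test_collapse_idempotent(self, rng):
        recs = random_records(rng, 300)
        first = collapse_records(recs)
        dedup = recs.drop_duplicates(["experiment_id", "chrom", "pos", "orientation"])
        second = collapse_records(dedup)
        assert first.events == second.events and first.sites == second.sites

    def test_malformed_record_names_row(self):
        recs = make_records([("e1", "s1", "chr1", -5, "+", 1)])
        with pytest.raises(ValueError, match="record 1"):
            collapse_records(recs)
        recs = make_records([("e1", "s1", "chr1", 5, "+", 1),
                             ("e1", "s1", "chr1", 5, "+", 0)])
        with pytest.raises(ValueError, match="record 2"):
            collapse_records(recs)

    def test_empty_input_raises(self):
        with pytest.raises(ValueError):
            collapse_records(make_records([]))


# ---------------------------------------------------------------------------
# validate_ttaa
# ---------------------------------------------------------------------------

class TestValidate:
    genome = {"chr1": "CCCCTTAAGGGGACGTCCCC"}

    def test_planted_ttaa_passes(self):
        rep = validate_ttaa({("chr1", 4, "+")}, self.genome)
        assert rep.ttaa_ok.all()

    def test_non_ttaa_fails(self):
        rep = validate_ttaa({("chr1", 12, "+")}, self.genome)  # ACGT
        assert not rep.ttaa_ok.any()

    def test_simulated_sites_all_pass(self, small_screen):
        _, genome, _, _, records, _ = small_screen
        res = collapse_records(records)
        rep = validate_ttaa(res.sites, genome)
        assert rep.ttaa_ok.all()

    def test_beyond_chromosome_end_raises(self):
        with pytest.raises(ValueError, match="beyond"):
            validate_ttaa({("chr1", 18, "+")}, self.genome)


# ---------------------------------------------------------------------------
# assign_genes
# ---------------------------------------------------------------------------

def brute_force_nearest(sites, genes, window):
    """All-pairs oracle for nearest-gene assignment with lexicographic ties."""
    out = {}
    for chrom, pos, orient in sites:
        best = None
        for g in genes:
            if g.chrom != chrom:
                continue
            if g.start <= pos < g.end:
                d = 0
            elif pos < g.start:
                d = g.start - pos
            else:
                d = pos - (g.end - 1)
            if d > window:
                continue
            if best is None or (d, g.gene_id) < best:
                best = (d, g.gene_id)
        if best is not None:
            out[(chrom, pos, orient)] = best
    return out


class TestAssign:
    def test_upstream_assignment(self):
        gene = GeneAnnotation("gA", "chr1", "+", 30_000, 35_000)
        asn = assign_genes({("chr1", 25_000, "+")}, [gene], ScreenCallConfig())
        row = asn.iloc[0]
        assert row.gene_id == "gA" and row.distance_bp == 5000
        assert row.location == "upstream" and row.relative_orientation == "sense"

    def test_inside_gene_body(self):
        gene = GeneAnnotation("gA", "chr1", "-", 10_000, 20_000)
        asn = assign_genes({("chr1", 15_000, "+")}, [gene], ScreenCallConfig())
        row = asn.iloc[0]
        assert row.distance_bp == 0 and row.location == "inside"
        assert row.relative_orientation == "antisense"

    def test_minus_strand_locations(self):
        gene = GeneAnnotation("gA", "chr1", "-", 10_000, 20_000)
        before = assign_genes({("chr1", 9_000, "-")}, [gene], ScreenCallConfig()).iloc[0]
        after = assign_genes({("chr1", 21_000, "-")}, [gene], ScreenCallConfig()).iloc[0]
        assert before.location == "downstream" and after.location == "upstream"

    def test_outside_window_dropped(self):
        gene = GeneAnnotation("gA", "chr1", "+", 100_000, 105_000)
        asn = assign_genes({("chr1", 50_000, "+")}, [gene],
                           ScreenCallConfig(window_bp=20_000))
        assert asn.empty

    def test_random_sites_match_brute_force(self, rng):
        genes = []
        for i in range(20):
            start = int(rng.integers(0, 480_000))
            genes.append(GeneAnnotation(f"g{i:02d}", f"chr{1 + i % 2}",
                                        "+" if rng.random() < 0.5 else "-",
                                        start, start + int(rng.integers(500, 8000))))
        sites = {
            (f"chr{1 + int(rng.integers(1, 3)) - 1}", int(rng.integers(0, 500_000)), "+")
            for _ in range(200)
        }
        cfg = ScreenCallConfig(window_bp=20_000)
        asn = assign_genes(sites, genes, cfg)
        oracle = brute_force_nearest(sites, genes, cfg.window_bp)
        got = {
            (r.chrom, int(r.pos), r.orientation): (int(r.distance_bp), r.gene_id)
            for r in asn.itertuples(index=False)
        }
        assert got == oracle

    def test_all_within_window_mode(self):
        genes = [GeneAnnotation("gA", "chr1", "+", 10_000, 12_000),
                 GeneAnnotation("gB", "chr1", "+", 15_000, 17_000)]
        cfg = ScreenCallConfig(window_bp=5_000, assignment_mode="all-within-window")
        asn = assign_genes({("chr1", 13_000, "+")}, genes, cfg)
        assert sorted(asn.gene_id) == ["gA", "gB"]

    def test_translation_symmetry(self, rng):
        genes = [GeneAnnotation("gA", "chr1", "+", 10_000, 12_000),
                 GeneAnnotation("gB", "chr1", "-", 40_000, 45_000)]
        sites = {("chr1", int(p), "+") for p in rng.integers(0, 60_000, 50)}
        shift = 1_000_000
        shifted_genes = [GeneAnnotation(g.gene_id, g.chrom, g.strand,
                                        g.start + shift, g.end + shift) for g in genes]
        shifted_sites = {(c, p + shift, o) for c, p, o in sites}
        a = assign_genes(sites, genes).assign(pos=lambda d: d.pos + shift)
        b = assign_genes(shifted_sites, shifted_genes)
        pd.testing.assert_frame_equal(
            a.sort_values(["pos", "gene_id"]).reset_index(drop=True),
            b.sort_values(["pos", "gene_id"]).reset_index(drop=True),
        )


# ---------------------------------------------------------------------------
# tally_gene_events
# ---------------------------------------------------------------------------

class TestTally:
    def test_one_site_three_experiments(self):
        events = {("e1", "chr1", 100, "+"), ("e2", "chr1", 100, "+"), ("e3", "chr1", 100, "+")}
        asn = pd.DataFrame([("chr1", 100, "+", "gA", 0, "sense", "inside")],
                           columns=["chrom", "pos", "orientation", "gene_id",
                                    "distance_bp", "relative_orientation", "location"])
        tal = tally_gene_events(asn, events)
        row = tal.iloc[0]
        assert (row.n_events, row.n_unique_sites, row.n_experiments) == (3, 1, 3)

    def test_gene_without_sites_absent(self):
        events = {("e1", "chr1", 100, "+")}
        asn = pd.DataFrame([], columns=["chrom", "pos", "orientation", "gene_id",
                                        "distance_bp", "relative_orientation", "location"])
        assert tally_gene_events(asn, events).empty

    def test_simulated_tallies_match_groupby_oracle(self, small_screen):
        cfg, genome, genes, ttaa, records, _ = small_screen
        res = collapse_records(records)
        ccfg = ScreenCallConfig(window_bp=cfg.window_bp)
        asn = assign_genes(res.sites, genes, ccfg)
        tal = tally_gene_events(asn, res.events).set_index("gene_id")

        # oracle: brute-force dict accumulation over (gene, site, experiment)
        site_gene = {(r.chrom, int(r.pos), r.orientation): r.gene_id
                     for r in asn.itertuples(index=False)}
        per_gene: dict[str, dict[str, set]] = {}
        for exp, chrom, pos, orient in res.events:
            gid = site_gene.get((chrom, pos, orient))
            if gid is None:
                continue
            d = per_gene.setdefault(gid, {"sites": set(), "events": set(), "exps": set()})
            d["sites"].add((chrom, pos, orient))
            d["events"].add((exp, chrom, pos, orient))
            d["exps"].add(exp)
        assert set(tal.index) == set(per_gene)
        for gid, d in per_gene.items():
            assert tal.at[gid, "n_unique_sites"] == len(d["sites"])
            assert tal.at[gid, "n_events"] == len(d["events"])
            assert tal.at[gid, "n_experiments"] == len(d["exps"])
            assert tal.at[gid, "n_experiments"] <= tal.at[gid, "n_events"]
            assert tal.at[gid, "n_unique_sites"] <= tal.at[gid, "n_events"]


# ---------------------------------------------------------------------------
# build_ttaa_index
# ---------------------------------------------------------------------------

class TestTTAAIndex:
    def test_window_counts_match_string_scan(self, small_screen):
        cfg, genome, genes, _, _, _ = small_screen
        ccfg = ScreenCallConfig(window_bp=cfg.window_bp)
        index = build_ttaa_index(genome, genes, ccfg)
        for g in genes:
            positions = naive_ttaa_scan(genome[g.chrom])
            expected = sum(g.start - ccfg.window_bp <= p < g.end + ccfg.window_bp
                           for p in positions)
            assert index.per_gene[g.gene_id] == expected
        assert index.total == sum(len(naive_ttaa_scan(s)) for s in genome.values())

    def test_ttaa_free_chromosome_gives_zero(self):
        genome = {"chr1": "ACGTC" * 1000}
        genes = [GeneAnnotation("gA", "chr1", "+", 1000, 2000)]
        index = build_ttaa_index(genome, genes, ScreenCallConfig(window_bp=500))
        assert index.per_gene["gA"] == 0

    def test_disjoint_whole_chromosome_windows_sum_to_total(self):
        genome = {"chr1": "TTAA" * 50 + "C" * 100, "chr2": "G" * 40 + "TTAA" * 10}
        genes = [GeneAnnotation("g1", "chr1", "+", 1, len(genome["chr1"]) - 1),
                 GeneAnnotation("g2", "chr2", "+", 1, len(genome["chr2"]) - 1)]
        cfg = ScreenCallConfig(window_bp=10)
        index = build_ttaa_index(genome, genes, cfg)
        assert index.per_gene.sum() == index.total


# ---------------------------------------------------------------------------
# call_candidates
# ---------------------------------------------------------------------------

def binom_tail_oracle(k, n, p):
    return sum(math.comb(n, j) * p**j * (1 - p) ** (n - j) for j in range(k, n + 1))


class TestCallCandidates:
    def test_single_gene_binomial_tail(self):
        tallies = pd.DataFrame([("gA", 20, 20, 3)],
                               columns=["gene_id", "n_unique_sites", "n_events", "n_experiments"])
        index = TTAAIndex(per_gene=pd.Series({"gA": 1}), total=1000)
        hits = call_candidates(tallies, index, n_total_sites=20)
        expected = binom_tail_oracle(20, 20, 0.001)
        assert hits.p.iloc[0] == pytest.approx(expected, rel=1e-12)

    def test_zero_sites_p_one(self):
        tallies = pd.DataFrame([], columns=["gene_id", "n_unique_sites", "n_events", "n_experiments"])
        index = TTAAIndex(per_gene=pd.Series({"gA": 10}), total=100)
        hits = call_candidates(tallies, index, n_total_sites=5)
        assert hits.p.iloc[0] == 1.0
        assert not hits.is_candidate.any()

    def test_null_violation_flagged(self):
        tallies = pd.DataFrame([("gA", 2, 2, 2)],
                               columns=["gene_id", "n_unique_sites", "n_events", "n_experiments"])
        index = TTAAIndex(per_gene=pd.Series({"gA": 0, "gB": 10}), total=10)
        hits = call_candidates(tallies, index, n_total_sites=2).set_index("gene_id")
        assert hits.at["gA", "null_violation"]
        assert hits.at["gA", "p"] == 0.0
        assert np.isnan(hits.at["gA", "q"])
        assert not hits.at["gA", "is_candidate"]

    def test_q_geq_p_and_candidate_rule(self):
        tallies = pd.DataFrame(
            [("gA", 15, 20, 4), ("gB", 1, 1, 1)],
            columns=["gene_id", "n_unique_sites", "n_events", "n_experiments"])
        index = TTAAIndex(per_gene=pd.Series({"gA": 5, "gB": 500}), total=10_000)
        hits = call_candidates(tallies, index, n_total_sites=16).set_index("gene_id")
        assert (hits.q >= hits.p - 1e-15).all()
        assert hits.at["gA", "is_candidate"]
        assert not hits.at["gB", "is_candidate"]

    def test_recurrence_filter_blocks_single_experiment(self):
        tallies = pd.DataFrame([("gA", 15, 15, 1)],
                               columns=["gene_id", "n_unique_sites", "n_events", "n_experiments"])
        index = TTAAIndex(per_gene=pd.Series({"gA": 5}), total=10_000)
        hits = call_candidates(tallies, index, n_total_sites=16)
        assert hits.p.iloc[0] < 1e-10 and not hits.is_candidate.iloc[0]

    def test_empty_index_raises(self):
        tallies = pd.DataFrame([("gA", 1, 1, 1)],
                               columns=["gene_id", "n_unique_sites", "n_events", "n_experiments"])
        with pytest.raises(ValueError):
            call_candidates(tallies, TTAAIndex(per_gene=pd.Series({"gA": 0}), total=0))


def test_benjamini_hochberg_matches_statsmodels(rng):
    from statsmodels.stats.multitest import multipletests

    p = rng.random(200)
    q = benjamini_hochberg(p)
    _, q_sm, _, _ = multipletests(p, method="fdr_bh")
    assert np.allclose(q, q_sm, atol=1e-12)
    assert (q >= p - 1e-15).all()


# ---------------------------------------------------------------------------
# summarize_bubble
# ---------------------------------------------------------------------------

class TestBubble:
    def test_single_gene(self):
        tal = pd.DataFrame([("gA", 1, 2, 2)],
                           columns=["gene_id", "n_unique_sites", "n_events", "n_experiments"])
        out = summarize_bubble(tal)
        assert len(out) == 1 and list(out.columns) == ["gene_id", "n_events", "n_experiments"]

    def test_alphabetical_order_on_shuffled_input(self, rng):
        names = [f"g{c}" for c in "zebra"]
        tal = pd.DataFrame({"gene_id": names,
                            "n_unique_sites": 1, "n_events": 1, "n_experiments": 1})
        out = summarize_bubble(tal.sample(frac=1, random_state=1))
        assert out.gene_id.tolist() == sorted(set(names)) or out.gene_id.is_monotonic_increasing

    def test_empty_raises(self):
        with pytest.raises(ValueError):
            summarize_bubble(pd.DataFrame(columns=["gene_id", "n_events", "n_experiments"]))
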