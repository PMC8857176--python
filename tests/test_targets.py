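import numpy as np
import pandas as pd
import pytest

import scisomir as sc
from scisomir.errors import ProcessingError
from scisomir.targets import ecdf_frame, ks_target_test

from _oracles import oracle_ks_statistic


# -- target aggregation -----------------------------------------------------

def _table(rows):
    return pd.DataFrame(rows, columns=["mirna", "gene", "source", "rank"])


def test_single_source_genes_are_excluded():
    table = _table([("m1", "g1", "diana", 3)])
    assert len(sc.aggregate_targets(table)["m1"]) == 0


def test_minimum_rank_aggregation():
    table = _table([("m1", "g1", "diana", 5), ("m1", "g1", "mirdb", 17)])
    agg = sc.aggregate_targets(table)["m1"]
    assert agg.to_dict() == {"g1": 5}


def test_aggregation_matches_bruteforce_filter():
    rng = np.random.default_rng(4)
    sources = ["diana", "miranda", "pictar", "targetscan", "mirdb"]
    rows = {
        ("m1", f"g{int(rng.integers(0, 60))}", sources[int(rng.integers(0, 5))])
        for _ in range(300)
    }
    table = _table([(m, g, s, int(rng.integers(1, 100))) for m, g, s in rows])
    agg = sc.aggregate_targets(table, min_sources=2)["m1"]
    by_gene = {}
    for row in table.itertuples():
        by_gene.setdefault(row.gene, []).append((row.source, row.rank))
    expected = {
        g: min(r for _, r in v)
        for g, v in by_gene.items()
        if len({s for s, _ in v}) >= 2
    }
    assert agg.to_dict() == expected


def test_empty_target_table_warns():
    with pytest.warns(UserWarning):
        assert sc.aggregate_targets(_table([])) == {}


# -- category expression ----------------------------------------------------

def test_total_category_equals_normalized_mirna_count(mixed_ann):
    mirna = mixed_ann.groupby("mature").size().idxmax()
    vec = sc.category_expression(mixed_ann, mirna, "TOTAL")
    counts = mixed_ann[mixed_ann.mature == mirna].groupby("cell").size()
    totals = mixed_ann.groupby("cell").size()
    expected = (counts.reindex(totals.index, fill_value=0) / totals * 1e6)
    pd.testing.assert_series_equal(vec, expected, check_names=False)


def test_nta_a_raw_counts_use_at_least_one_a_rule(mixed_ann):
    mirna = mixed_ann.groupby("mature").size().idxmax()
    vec = sc.category_expression(mixed_ann, mirna, "NTA_A", normalization="raw")
    mine = mixed_ann[mixed_ann.mature == mirna]
    expected = mine.groupby("cell")["has_nta_a"].sum()
    assert vec.loc[expected.index].astype(int).to_dict() == expected.to_dict()


def test_unknown_mirna_raises(mixed_ann):
    with pytest.raises(KeyError):
        sc.category_expression(mixed_ann, "mir-nope-5p", "TOTAL")


def test_category_vectors_match_truth_aggregation(mixed_sim, mixed_ann):
    truth_frame = mixed_sim.truth.to_annotation_frame("reads")
    mirna = mixed_ann.groupby("mature").size().idxmax()
    for category in ("TOTAL", "CANONICAL", "FP_VARIANT", "NTA_U"):
        got = sc.category_expression(mixed_ann, mirna, category, normalization="raw")
        want = sc.category_expression(truth_frame, mirna, category, normalization="raw")
        assert got.to_dict() == want.to_dict()


# -- correlation ------------------------------------------------------------

def test_exact_negative_linear_gene_has_r_minus_one():
    cells = [f"c{i}" for i in range(10)]
    vec = pd.Series(np.arange(10, dtype=float), index=cells)
    mrna = pd.DataFrame([100.0 - 3 * np.arange(10)], index=["g1"], columns=cells)
    r = sc.correlate(vec, mrna, normalization="none")
    assert r["g1"] == pytest.approx(-1.0)


def test_constant_gene_is_undefined_and_excluded():
    cells = [f"c{i}" for i in range(6)]
    vec = pd.Series(np.arange(6, dtype=float), index=cells)
    mrna = pd.DataFrame([[7.0] * 6], index=["flat"], columns=cells)
    r = sc.correlate(vec, mrna, normalization="none")
    assert np.isnan(r["flat"])


def test_fewer_than_three_shared_cells_is_an_error():
    vec = pd.Series([1.0, 2.0], index=["c1", "c2"])
    mrna = pd.DataFrame([[1.0, 2.0]], index=["g1"], columns=["c1", "c2"])
    with pytest.raises(ProcessingError):
        sc.correlate(vec, mrna)


# -- KS test ----------------------------------------------------------------

def test_identical_samples_give_zero_statistic_no_direction():
    x = np.linspace(-1, 1, 50)
    res = ks_target_test(x, x)
    assert res.ks_statistic == 0.0
    assert res.direction == "none"


def test_shifted_sample_detected_as_negative():
    rng = np.random.default_rng(5)
    nt = rng.normal(0, 0.3, size=200)
    res = ks_target_test(nt - 0.5, nt)
    assert res.p_value < 0.05
    assert res.direction == "negative"


def test_ks_statistic_equals_bruteforce_ecdf_sup():
    rng = np.random.default_rng(6)
    for _ in range(20):
        a = rng.normal(size=rng.integers(5, 40))
        b = rng.normal(0.3, 1.2, size=rng.integers(5, 40))
        res = ks_target_test(a, b)
        assert res.ks_statistic == pytest.approx(oracle_ks_statistic(a, b))


def test_undersized_vectors_flagged_untestable():
    res = ks_target_test([0.1, 0.2], np.zeros(100))
    assert not res.testable
    assert res.direction == "none"


def test_ecdf_frames_are_valid_cdfs():
    rng = np.random.default_rng(7)
    res = ks_target_test(rng.normal(size=30), rng.normal(size=50), mirna="m", category="TOTAL")
    ecdf = ecdf_frame([res])
    for _, g in ecdf.groupby("group"):
        vals = g.sort_values("r")["ecdf"].to_numpy()
        assert (np.diff(vals) >= 0).all()
        assert vals[-1] == pytest.approx(1.0)


# -- full screen ------------------------------------------------------------

@pytest.fixture(scope="module")
def planted_screen():
    """40 cells; one miRNA with planted repression, one decoy with a target
    list but no planted effect (decoy genes disjoint from the planted block)."""
    ref = sc.make_reference(8, seed=2)
    cfg = sc.SimulationConfig(
        n_cells=40, reads_per_cell=2000, seed=21,
        pcr_duplication_mean=1.0, umi_length=0, adapter="",
    )
    truth = sc.simulate_cells(ref, cfg).truth
    by_abundance = truth.molecules.groupby("mature").size().sort_values(ascending=False)
    planted, decoy = by_abundance.index[0], by_abundance.index[1]
    mrna, table = sc.simulate_mrna_coupled(
        truth, n_genes=3000, n_targets_per_mirna=150, effect_r=-0.5,
        seed=22, mirnas=[planted],
    )
    rng = np.random.default_rng(23)
    decoy_rows = [
        (decoy, f"gene_{i:05d}", src, int(rng.integers(1, 500)))
        for i in range(2000, 2150)
        for src in ("diana", "miranda")
    ]
    table = pd.concat(
        [table, pd.DataFrame(decoy_rows, columns=table.columns)], ignore_index=True
    )
    ann = truth.to_annotation_frame("reads")
    results, ecdf = sc.run_target_analysis(ann, mrna, table, top_k_mirnas=2)
    return planted, decoy, mrna, results, ecdf


def test_planted_mirna_total_is_significant_negative(planted_screen):
    planted, _, _, results, _ = planted_screen
    total = next(r for r in results if r.mirna == planted and r.category == "TOTAL")
    assert total.p_value < 0.05
    assert total.direction == "negative"


def test_decoy_mirna_total_has_no_direction(planted_screen):
    _, decoy, _, results, _ = planted_screen
    total = next(r for r in results if r.mirna == decoy and r.category == "TOTAL")
    assert total.direction == "none"


def test_targets_and_nontargets_partition_gene_universe(planted_screen):
    _, _, mrna, results, _ = planted_screen
    for r in results:
        assert len(r.target_correlations) + len(r.nontarget_correlations) == len(mrna)


def test_alpha_one_assigns_direction_to_every_testable_result(planted_screen):
    planted, decoy, mrna, _, _ = planted_screen
    rng = np.random.default_rng(8)
    res = ks_target_test(rng.normal(size=60), rng.normal(size=400), alpha=1.0)
    assert res.direction in ("negative", "positive")
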