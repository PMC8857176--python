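import numpy as np
import pandas as pd
import pytest

import scisomir as sc
from scisomir.annotate import add_category_columns
from scisomir.errors import ConfigError, ProcessingError
from scisomir.profiles import CellCountMatrix, isomir_parent_fractions


def _ann(rows):
    """rows: (cell, mature, fp, tp, tail, n_sub) -> annotation frame."""
    df = pd.DataFrame(rows, columns=["cell", "mature", "fp_offset", "tp_offset",
                                     "nta_tail", "n_sub"])
    df["read_id"] = [f"r{i}" for i in range(len(df))]
    df["seq"] = "ACGTACGTACGTACGTACGTAC"
    df["umi"] = ""
    df["precursor"] = "pre-" + df["mature"]
    df["align_start"] = 10 - df["fp_offset"]
    df["sub_pos"] = np.where(df["n_sub"] > 0, 5, -1)
    df["sub_ref"] = np.where(df["n_sub"] > 0, "A", "")
    df["sub_alt"] = np.where(df["n_sub"] > 0, "G", "")
    df["ambiguous"] = False
    df["read_len"] = 22 + df["fp_offset"] + df["tp_offset"] + df["nta_tail"].str.len()
    return add_category_columns(df)


# -- counting ---------------------------------------------------------------

def test_mirna_level_counts_reads(ref6):
    ann = _ann([("c1", "mir-x", 0, 0, "", 0)] * 3)
    m = sc.count_features(ann, "reads", "mirna")
    assert m.df.loc["c1", "mir-x"] == 3
    assert m.totals().loc["c1"] == 3


def test_category_level_multimembership_counts_once_per_category():
    ann = _ann([("c1", "mir-x", -1, 2, "", 0)])
    m = sc.count_features(ann, "reads", "category")
    assert m.df.loc["c1", "mir-x|FP_VARIANT"] == 1
    assert m.df.loc["c1", "mir-x|TP_TEMPLATED"] == 1
    assert m.df.loc["c1", "mir-x|TOTAL"] == 1
    assert m.totals().loc["c1"] == 1


def test_mirna_matrix_equals_ground_truth_aggregation(mixed_sim, mixed_ann):
    m = sc.count_features(mixed_ann, "reads", "mirna")
    truth = (
        mixed_sim.truth.molecules.groupby(["cell", "mature"]).size().unstack(fill_value=0)
    )
    pd.testing.assert_frame_equal(
        m.df, truth.sort_index(axis=1), check_names=False, check_dtype=False
    )


def test_per_cell_counts_sum_to_mapped_total(mixed_ann):
    m = sc.count_features(mixed_ann, "reads", "mirna")
    expected = mixed_ann.groupby("cell").size()
    pd.testing.assert_series_equal(m.totals(), expected, check_names=False)
    # per-cell normalization sums to one at miRNA level
    assert np.allclose(m.normalized("fraction").sum(axis=1), 1.0)


def test_count_matrix_exports_to_anndata(mixed_ann):
    m = sc.count_features(mixed_ann, "reads", "mirna")
    adata = m.to_anndata()
    assert adata.shape == m.df.shape
    assert list(adata.obs_names) == list(m.df.index)
    assert adata.uns["level"] == "mirna"


def test_umis_mode_requires_umi_data(mixed_ann):
    with pytest.raises(ConfigError):
        sc.count_features(mixed_ann, "umis", "mirna")


def test_isomir_parent_fractions_sum_to_one_per_parent(mixed_ann):
    m = sc.count_features(mixed_ann, "reads", "isomir")
    frac = isomir_parent_fractions(m)
    parents = pd.Series([f.split("|", 1)[0] for f in frac.columns], index=frac.columns)
    sums = frac.T.groupby(parents).sum().T
    present = sc.count_features(mixed_ann, "reads", "mirna").df > 0
    assert np.allclose(sums.to_numpy()[present.to_numpy()], 1.0)


# -- cell filtering ---------------------------------------------------------

def _matrix_with_totals(totals):
    df = pd.DataFrame({"mir-x": totals}, index=[f"c{i}" for i in range(len(totals))])
    return CellCountMatrix(df=df, mode="reads", level="mirna")


def test_cell_filter_boundary_at_1000():
    m = _matrix_with_totals([999, 1000, 1001])
    kept = sc.filter_cells(m)
    assert list(kept.df.index) == ["c1", "c2"]


def test_cell_filter_all_below_threshold_warns():
    with pytest.warns(UserWarning):
        kept = sc.filter_cells(_matrix_with_totals([5, 10]))
    assert len(kept.df) == 0


def test_cell_filter_matches_direct_count():
    rng = np.random.default_rng(2)
    totals = rng.integers(0, 3000, size=200)
    kept = sc.filter_cells(_matrix_with_totals(list(totals)))
    assert len(kept.df) == int((totals >= 1000).sum())


# -- length distribution ----------------------------------------------------

def test_length_distribution_all_canonical_single_mass():
    ann = _ann([("c1", "mir-x", 0, 0, "", 0)] * 4)
    for scope in ("all", "canonical_only"):
        dist = sc.length_distribution(ann, scope=scope)
        assert dist.to_dict() == {22: 1.0}


def test_canonical_scope_keeps_total_denominator():
    ann = _ann([("c1", "mir-x", 0, 0, "", 0), ("c1", "mir-x", 0, 1, "", 0)])
    assert sc.length_distribution(ann).to_dict() == {22: 0.5, 23: 0.5}
    assert sc.length_distribution(ann, "canonical_only").to_dict() == {22: 0.5}


def test_length_distribution_matches_truth_within_3sd(mixed_sim, mixed_ann):
    got = sc.length_distribution(mixed_ann)
    want = sc.length_distribution(mixed_sim.truth.to_annotation_frame())
    n = len(mixed_ann)
    for length in want.index:
        p = want[length]
        assert abs(got.get(length, 0.0) - p) <= 3 * np.sqrt(p * (1 - p) / n) + 1e-12


# -- positional profiles ----------------------------------------------------

def test_cell_averaging_differs_from_pooling():
    rows = (
        [("c1", "mir-x", -1, 0, "", 0)] * 2 + [("c1", "mir-x", 0, 0, "", 0)] * 8
        + [("c2", "mir-x", -1, 0, "", 0)] * 8 + [("c2", "mir-x", 0, 0, "", 0)] * 12
    )
    ann = _ann(rows)
    averaged = sc.positional_profile(ann)
    assert averaged.loc["all", "fp_-1"] == pytest.approx(0.3)  # mean(0.2, 0.4)
    pooled = sc.positional_profile(ann, cell_average=False)
    assert pooled.loc["all", "fp_-1"] == pytest.approx(10 / 30)


def test_profile_recovers_mixture_offsets_within_3sd(mixed_sim, mixed_ann):
    got = sc.positional_profile(mixed_ann)
    want = sc.positional_profile(mixed_sim.truth.to_annotation_frame())
    n = len(mixed_ann)
    for col in got.columns:
        p = want.loc["all", col]
        assert abs(got.loc["all", col] - p) <= 3 * np.sqrt(p * (1 - p) / n) + 1e-12


def test_per_mirna_profile_filters_low_expression(mixed_ann):
    prof = sc.positional_profile(mixed_ann, group_by="mature", min_group_reads=50)
    pooled = mixed_ann.groupby("mature").size()
    assert set(prof.index) == set(pooled[pooled >= 50].index)


# -- category proportions ---------------------------------------------------

def test_category_proportions_hand_case():
    ann = _ann([("c1", "mir-x", 0, 0, "", 0)] * 4 + [("c1", "mir-x", 0, 1, "", 0)] * 6)
    prop = sc.category_proportions(ann)
    assert prop.loc["c1", "CANONICAL"] == pytest.approx(0.4)
    assert prop.loc["c1", "TP_TEMPLATED"] == pytest.approx(0.6)


def test_multimembership_proportions_need_not_sum_to_one():
    ann = _ann([("c1", "mir-x", -1, 0, "A", 0), ("c1", "mir-x", 0, 0, "", 0)])
    prop = sc.category_proportions(ann)
    assert prop.loc["c1", "FP_VARIANT"] == pytest.approx(0.5)
    assert prop.loc["c1", "TP_NONTEMPLATED"] == pytest.approx(0.5)
    assert prop.loc["c1"].sum() > 1.0


def test_pipeline_proportions_equal_truth_exactly_on_clean_data(mixed_sim, mixed_ann):
    got = sc.category_proportions(mixed_ann)
    want = mixed_sim.truth.category_proportions(level="reads")
    pd.testing.assert_frame_equal(got, want)


# -- dedup shift report -----------------------------------------------------

def test_dedup_shift_zero_when_unchanged(mixed_ann):
    prop = sc.category_proportions(mixed_ann)
    delta, summary = sc.dedup_shift_report(prop, prop)
    assert (delta.to_numpy() == 0).all() and (summary == 0).all()


def test_dedup_shift_requires_matching_cells(mixed_ann):
    prop = sc.category_proportions(mixed_ann)
    with pytest.raises(ProcessingError):
        sc.dedup_shift_report(prop, prop.iloc[1:])


def test_canonical_biased_pcr_gives_negative_canonical_shift(ref6):
    cfg = sc.SimulationConfig(
        n_cells=4, reads_per_cell=1500, seed=17,
        pcr_duplication_mean=4.0, pcr_canonical_bias=2.0,
        umi_length=12, adapter="",
    )
    sim = sc.simulate_cells(ref6, cfg)
    pre = sc.category_proportions(sim.truth.to_annotation_frame("reads"))
    post = sc.category_proportions(sim.truth.to_annotation_frame("molecules"))
    post.index = pre.index
    delta, summary = sc.dedup_shift_report(pre, post)
    assert summary["CANONICAL"] < 0
    assert ((delta >= -1) & (delta <= 1)).all().all()


# -- clustering -------------------------------------------------------------

def test_identical_cells_have_unit_correlation():
    df = pd.DataFrame([[10, 5, 1], [10, 5, 1], [1, 5, 10]],
                      index=["c1", "c2", "c3"], columns=["a", "b", "c"])
    res = sc.cell_similarity_clustering(CellCountMatrix(df=df))
    assert res.correlation.loc["c1", "c2"] == pytest.approx(1.0)
    assert res.correlation.loc["c1", "c3"] == pytest.approx(-1.0)


def test_correlation_matrix_symmetric_unit_diagonal(mixed_ann):
    m = sc.count_features(mixed_ann, "reads", "mirna")
    res = sc.cell_similarity_clustering(m)
    corr = res.correlation.to_numpy()
    assert np.allclose(corr, corr.T)
    assert np.allclose(np.diag(corr), 1.0)
    assert sorted(res.leaf_order) == sorted(m.df.index)


def test_constant_cell_gets_zero_correlation_with_warning():
    df = pd.DataFrame([[5, 5, 5], [1, 2, 3], [3, 2, 1]],
                      index=["flat", "up", "down"], columns=["a", "b", "c"])
    with pytest.warns(UserWarning, match="constant-expression"):
        res = sc.cell_similarity_clustering(CellCountMatrix(df=df))
    assert res.correlation.loc["flat", "up"] == 0.0
    assert res.correlation.loc["flat", "flat"] == 1.0


def test_two_abundance_profiles_separate_into_two_clusters(ref6):
    names = sorted(ref6.mature_index)
    half = len(names) // 2

    def abundance(active):
        raw = {n: (1.0 if n in active else 1e-6) for n in names}
        total = sum(raw.values())
        return {n: v / total for n, v in raw.items()}

    frames = []
    for label, seed, active in (("A", 31, names[:half]), ("B", 32, names[half:])):
        cfg = sc.SimulationConfig(
            n_cells=6, reads_per_cell=800, seed=seed,
            mirna_abundance=abundance(active),
            pcr_duplication_mean=1.0, umi_length=0, adapter="",
        )
        f = sc.simulate_cells(ref6, cfg).truth.to_annotation_frame()
        f["cell"] = f"grp{label}_" + f["cell"]
        frames.append(f)
    ann = pd.concat(frames, ignore_index=True)
    res = sc.cell_similarity_clustering(sc.count_features(ann, "reads", "mirna"))
    labels = res.cut(2)
    groups = labels.groupby(labels.index.str.slice(0, 4)).nunique()
    assert (groups == 1).all()  # each true group maps to a single cluster
    assert labels.nunique() == 2
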