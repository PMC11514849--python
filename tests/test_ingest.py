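"""Cleaning pipeline: reading, filters, scaling, IS bridging, z-scores,
and the rank-sum differential test (with an enumeration oracle)."""

from itertools import combinations

import numpy as np
import pandas as pd
import pytest

import mgomics as mg
from mgomics.ingest import (
    IS_CHANNEL,
    QuantTable,
    _ranksum_p,
    differential_abundance,
    flag_differential,
)
from mgomics.matrix import StageError

from conftest import make_matrix


def build_table(intensities, unique_peptides=None, kind="protein", loc_prob=None,
                channels=None, stage="raw"):
    vals = np.asarray(intensities, dtype=float)
    n, k = vals.shape
    channels = channels or [f"s{j}" for j in range(k - 1)] + [IS_CHANNEL]
    meta = pd.DataFrame(index=[f"f{i}" for i in range(n)])
    if kind == "protein":
        meta["unique_peptides"] = unique_peptides if unique_peptides is not None else 3
    else:
        meta["parent_protein"] = "p"
        meta["localization_prob"] = loc_prob if loc_prob is not None else 0.9
    df = pd.DataFrame(vals, index=meta.index, columns=channels)
    return QuantTable(intensities=df, meta=meta, kind=kind, batch="b1", stage=stage)


class TestReadQuantTable:
    def test_flagged_rows_removed(self, tmp_path):
        rows = []
        for i in range(10):
            rows.append({
                "feature_id": f"f{i}", "unique_peptides": 3,
                "contaminant": "+" if i < 2 else "", "reverse": "",
                "intensity_s1": 100.0, "intensity_s2": 200.0, "intensity_IS": 150.0,
            })
        p = tmp_path / "batch.tsv"
        pd.DataFrame(rows).to_csv(p, sep="\t", index=False)
        t = mg.read_quant_table(p, "protein")
        assert len(t.intensities) == 8

    def test_missing_is_channel_errors(self, tmp_path):
        p = tmp_path / "batch.tsv"
        pd.DataFrame([{"feature_id": "f0", "unique_peptides": 2, "contaminant": "",
                       "reverse": "", "intensity_s1": 1.0}]).to_csv(p, sep="\t", index=False)
        with pytest.raises(ValueError, match="internal-standard"):
            mg.read_quant_table(p, "protein")

    def test_malformed_numeric_names_row_and_column(self, tmp_path):
        p = tmp_path / "batch.tsv"
        pd.DataFrame([{"feature_id": "f0", "unique_peptides": 2, "contaminant": "",
                       "reverse": "", "intensity_s1": "oops", "intensity_IS": 1.0}]).to_csv(
            p, sep="\t", index=False)
        with pytest.raises(ValueError, match="f0.*s1"):
            mg.read_quant_table(p, "protein")

    def test_unknown_column_warns_and_is_ignored(self, tmp_path):
        p = tmp_path / "batch.tsv"
        pd.DataFrame([{"feature_id": "f0", "unique_peptides": 2, "contaminant": "",
                       "reverse": "", "mystery": 5, "intensity_s1": 1.0,
                       "intensity_IS": 1.0}]).to_csv(p, sep="\t", index=False)
        with pytest.warns(UserWarning, match="mystery"):
            t = mg.read_quant_table(p, "protein")
        assert list(t.intensities.columns) == ["s1", "IS"]

    def test_synthetic_batch_row_count_matches_config(self, cohort_dir, small_config):
        path = sorted(cohort_dir.glob("proteome_batch*.tsv"))[0]
        t = mg.read_quant_table(path, "protein")
        # decoy rows are flag-filtered at read time
        assert len(t.intensities) == small_config.n_proteins


class TestFilterFeatures:
    @pytest.mark.parametrize(
        "peptides, kept",
        [([1, 2, 3], ["f1", "f2"]), ([2, 2], ["f0", "f1"])],
    )
    def test_unique_peptide_floor(self, peptides, kept):
        t = build_table(np.ones((len(peptides), 2)), unique_peptides=peptides)
        out = mg.filter_features(t)
        assert list(out.intensities.index) == kept

    def test_localization_probability_strictly_above_threshold(self):
        t = build_table(np.ones((3, 2)), kind="phospho", loc_prob=[0.74, 0.75, 0.76])
        out = mg.filter_features(t)
        assert list(out.intensities.index) == ["f2"]


class TestScaleTotalIntensity:
    def test_sums_equalized_to_mean(self):
        t = build_table([[100.0, 200.0]], channels=["s1", IS_CHANNEL])
        out = mg.scale_total_intensity(t)
        assert np.allclose(out.intensities.to_numpy(), [[150.0, 150.0]])

    def test_random_table_sums_equal(self):
        rng = np.random.default_rng(0)
        vals = rng.uniform(10, 1000, (50, 5))
        vals[rng.random((50, 5)) < 0.2] = 0.0
        t = build_table(vals, channels=[f"s{j}" for j in range(4)] + [IS_CHANNEL])
        out = mg.scale_total_intensity(t)
        sums = out.intensities.to_numpy().sum(axis=0)
        assert np.allclose(sums, sums[0], rtol=1e-9)
        # zeros stay zero
        assert ((vals == 0) == (out.intensities.to_numpy() == 0)).all()

    def test_all_zero_channel_errors(self):
        t = build_table([[0.0, 1.0], [0.0, 2.0]])
        with pytest.raises(ValueError, match="all-zero"):
            mg.scale_total_intensity(t)


class TestBridgeToIS:
    def test_self_ratio_is_one(self):
        t = build_table([[5.0, 5.0], [7.0, 7.0]], stage="scaled")
        m = mg.bridge_to_is(t)
        assert np.allclose(m.values.to_numpy(), 1.0)
        assert m.stage == "s_over_s"
        assert IS_CHANNEL not in m.values.columns

    def test_zero_is_makes_row_missing(self):
        t = build_table([[5.0, 3.0, 0.0], [7.0, 1.0, 2.0]],
                        channels=["s1", "s2", IS_CHANNEL], stage="scaled")
        m = mg.bridge_to_is(t)
        assert m.values.loc["f0"].isna().all()
        assert not m.values.loc["f1"].isna().any()

    def test_ratio_invariant_to_batch_rescale(self):
        rng = np.random.default_rng(1)
        vals = rng.uniform(1, 100, (20, 4))
        t1 = build_table(vals, channels=["a", "b", "c", IS_CHANNEL], stage="scaled")
        t2 = build_table(vals * 7.3, channels=["a", "b", "c", IS_CHANNEL], stage="scaled")
        pd.testing.assert_frame_equal(mg.bridge_to_is(t1).values, mg.bridge_to_is(t2).values)

    def test_requires_scaled_stage(self):
        t = build_table([[1.0, 1.0]])
        with pytest.raises(StageError):
            mg.bridge_to_is(t)


class TestCombineBatches:
    def test_outer_join_and_log2(self):
        a = make_matrix([[4.0], [2.0]], stage="s_over_s", features=["f0", "f1"], samples=["s1"])
        b = make_matrix([[8.0]], stage="s_over_s", features=["f0"], samples=["s2"])
        m = mg.combine_batches([a, b])
        assert m.stage == "log2"
        assert m.values.loc["f0", "s1"] == 2.0
        assert np.isnan(m.values.loc["f1", "s2"])

    def test_duplicate_sample_ids_error(self):
        a = make_matrix([[1.0]], stage="s_over_s", samples=["s1"])
        with pytest.raises(ValueError, match="duplicate"):
            mg.combine_batches([a, a])

    def test_sample_count(self, cohort_dir, small_bundle):
        from conftest import clean_batches
        m = clean_batches(cohort_dir.glob("proteome_batch*.tsv"))
        assert m.n_samples == 2 * len(small_bundle.clinical)


class TestZscore:
    def test_row_closed_form(self):
        m = make_matrix([[1.0, 2.0, 3.0]])
        z = mg.zscore(m, "rows")
        assert np.allclose(z.values.to_numpy(), [[-1.0, 0.0, 1.0]])

    def test_constant_row_becomes_missing(self):
        m = make_matrix([[2.0, 2.0, 2.0], [1.0, 2.0, 3.0]])
        z = mg.zscore(m, "rows")
        assert z.values.iloc[0].isna().all()
        assert not z.values.iloc[1].isna().any()

    def test_random_matrix_standardized(self):
        rng = np.random.default_rng(2)
        vals = rng.normal(5, 3, (30, 12))
        vals[rng.random((30, 12)) < 0.1] = np.nan
        z = mg.zscore(make_matrix(vals), "rows")
        arr = z.values.to_numpy()
        assert np.nanmax(np.abs(np.nanmean(arr, axis=1))) < 1e-9
        assert np.nanmax(np.abs(np.nanstd(arr, axis=1, ddof=1) - 1)) < 1e-9

    def test_stage_rejection(self):
        m = make_matrix([[1.0, 2.0]], stage="raw")
        with pytest.raises(StageError):
            mg.zscore(m, "rows")


class TestFilterMissing:
    @pytest.mark.parametrize("n_missing, kept", [(51, 0), (50, 1), (0, 1)])
    def test_strict_half_boundary(self, n_missing, kept):
        vals = np.ones((1, 100))
        vals[0, :n_missing] = np.nan
        m = mg.filter_missing(make_matrix(vals))
        assert m.n_features == kept

    def test_idempotent(self):
        rng = np.random.default_rng(3)
        vals = rng.normal(size=(40, 10))
        vals[rng.random((40, 10)) < 0.4] = np.nan
        once = mg.filter_missing(make_matrix(vals))
        twice = mg.filter_missing(once)
        pd.testing.assert_frame_equal(once.values, twice.values)


def exhaustive_ranksum_p(a, b):
    """Permutation oracle: two-sided p of the rank-sum statistic as the
    fraction of group assignments at least as far from its null center."""
    from scipy.stats import rankdata

    pooled = np.concatenate([a, b])
    ranks = rankdata(pooled)
    n_a = len(a)
    center = n_a * (len(pooled) + 1) / 2
    obs = abs(ranks[:n_a].sum() - center)
    count = total = 0
    for idx in combinations(range(len(pooled)), n_a):
        total += 1
        if abs(ranks[list(idx)].sum() - center) >= obs - 1e-12:
            count += 1
    return count / total


class TestDifferentialAbundance:
    def test_identical_groups_null(self):
        vals = np.array([[1.0, 2.0, 3.0, 1.0, 2.0, 3.0]])
        m = make_matrix(vals, samples=["a1", "a2", "a3", "b1", "b2", "b3"])
        res = differential_abundance(m, ["a1", "a2", "a3"], ["b1", "b2", "b3"])
        assert res[0].p > 0.9
        assert res[0].effect == 0.0

    def test_exact_small_sample_tail(self):
        m = make_matrix([[1.0, 2.0, 3.0, 4.0, 5.0, 6.0]],
                        samples=["a1", "a2", "a3", "b1", "b2", "b3"])
        res = differential_abundance(m, ["a1", "a2", "a3"], ["b1", "b2", "b3"])
        # most extreme separation of 3 vs 3: exact two-sided p = 2/20
        assert res[0].p == pytest.approx(0.1)

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_enumeration_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n_a, n_b = rng.integers(3, 8), rng.integers(3, 8)
        a = rng.normal(0, 1, n_a)
        b = rng.normal(0.8, 1, n_b)
        assert _ranksum_p(a, b) == pytest.approx(exhaustive_ranksum_p(a, b), abs=1e-12)

    def test_paired_effect_is_median_pair_difference(self):
        vals = np.array([[1.0, 2.0, 4.0, 0.0, 0.0, 1.0]])
        m = make_matrix(vals, samples=["t1", "t2", "t3", "n1", "n2", "n3"])
        res = differential_abundance(m, ["t1", "t2", "t3"], ["n1", "n2", "n3"], paired=True)
        assert res[0].effect == pytest.approx(2.0)  # median of (1, 2, 3)

    def test_empty_group_errors(self):
        m = make_matrix([[1.0, 2.0]])
        with pytest.raises(ValueError):
            differential_abundance(m, [], ["s0"])


@pytest.mark.parametrize(
    "ratio, p, flagged",
    [(1.3, 0.01, True), (0.8, 0.01, True), (1.1, 0.01, False),
     (1.3, 0.2, False), (0.83, 0.01, False), (1.2, 0.01, False)],
)
def test_cell_ratio_rule_boundaries(ratio, p, flagged):
    assert flag_differential(ratio, p) is flagged


def test_batch_scale_invariance_of_final_matrix(cohort_dir):
    """Multiplying every intensity of one batch by a constant must leave
    the IS-bridged (and hence z-scored) matrix unchanged."""
    paths = sorted(cohort_dir.glob("proteome_batch*.tsv"))
    mats_ref, mats_scaled = [], []
    for i, p in enumerate(paths):
        t = mg.filter_features(mg.read_quant_table(p, "protein"))
        mats_ref.append(mg.bridge_to_is(mg.scale_total_intensity(t)))
        if i == 0:
            t = QuantTable(intensities=t.intensities * 37.5, meta=t.meta,
                           kind=t.kind, batch=t.batch, is_channel=t.is_channel)
        mats_scaled.append(mg.bridge_to_is(mg.scale_total_intensity(t)))
    ref = mg.dual_zscore(mg.filter_missing(mg.combine_batches(mats_ref)))
    scaled = mg.dual_zscore(mg.filter_missing(mg.combine_batches(mats_scaled)))
    pd.testing.assert_frame_equal(ref.values, scaled.values)
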