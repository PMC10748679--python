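"""Clinical validation: subgroups, FF test, Jenks, Cramér's V, associations."""

import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import chi2_contingency

from speechassay.clinical import (
    assign_subgroups,
    association_matrix,
    bonferroni_threshold,
    cluster_association_matrix,
    cramers_v,
    ff_test,
    jenks_discretize,
)
from speechassay.clinical.association import AssociationMatrix
from speechassay.clinical.subgroups import LESS, MORE


def _clinical_row(**kw):
    base = dict(sex_code=1, onset_site="spinal", age=60.0, frs_total=40.0,
                frs_bulb=12.0, frs_resp=12.0, sit_rate=180.0, sit_intell=99.0,
                fvc_pct=90.0)
    base.update(kw)
    return pd.DataFrame([base])


class TestSubgroups:
    @pytest.mark.parametrize(
        "measure,value,expected",
        [
            ("sit_rate", 150.0, MORE),   # < 160 WPM
            ("sit_rate", 160.0, LESS),   # strict threshold
            ("frs_bulb", 11.0, LESS),    # < 11 is more severe, 11 is not
            ("frs_bulb", 10.0, MORE),
            ("fvc_pct", 80.0, LESS),     # < 80% strict
            ("fvc_pct", 79.9, MORE),
            ("frs_total", 34.0, MORE),
            ("frs_resp", 9.0, MORE),
            ("sit_intell", 95.0, MORE),
        ],
    )
    def test_threshold_directions(self, measure, value, expected):
        groups = assign_subgroups(_clinical_row(**{measure: value}))
        assert groups[measure].iloc[0] == expected

    def test_sex_and_onset_kept_as_categories(self):
        groups = assign_subgroups(_clinical_row(sex_code=2, onset_site="bulbar"))
        assert groups["sex_code"].iloc[0] == "female"
        assert groups["onset_site"].iloc[0] == "bulbar"

    def test_missing_value_propagates(self):
        groups = assign_subgroups(_clinical_row(fvc_pct=np.nan))
        assert pd.isna(groups["fvc_pct"].iloc[0])

    def test_missing_measure_column_rejected(self):
        with pytest.raises(KeyError):
            assign_subgroups(_clinical_row().drop(columns=["fvc_pct"]))

    def test_bad_sex_encoding_rejected(self):
        with pytest.raises(ValueError, match="male=1/female=2"):
            assign_subgroups(_clinical_row(sex_code=0))


class TestFFTest:
    def test_identical_sets_null(self):
        pts = np.random.default_rng(0).normal(size=(30, 2))
        res = ff_test(pts, pts.copy(), n_perm=200, seed=1)
        assert res.distance == 0.0
        assert res.p_value > 0.5

    def test_complete_separation_minimal_p(self):
        rng = np.random.default_rng(1)
        a = rng.normal(size=(30, 2))
        res = ff_test(a, a + 10.0, n_perm=999, seed=2)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_swap_symmetry(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=(20, 2)), rng.normal(0.5, 1, size=(25, 2))
        r1 = ff_test(a, b, n_perm=300, seed=3)
        r2 = ff_test(b, a, n_perm=300, seed=3)
        assert r1.distance == pytest.approx(r2.distance)

    def test_monotone_axiswise_transform_invariance(self):
        """Strictly monotone per-axis maps applied to both samples leave the
        quadrant statistic unchanged."""
        rng = np.random.default_rng(3)
        a, b = rng.normal(size=(25, 2)), rng.normal(0.3, 1.2, size=(25, 2))
        f = lambda p: np.column_stack([np.exp(p[:, 0]), p[:, 1] ** 3 + 2 * p[:, 1]])
        r1 = ff_test(a, b, n_perm=200, seed=4)
        r2 = ff_test(f(a), f(b), n_perm=200, seed=4)
        assert r1.distance == pytest.approx(r2.distance)
        assert r1.p_value == pytest.approx(r2.p_value)

    def test_small_sample_rejected(self):
        with pytest.raises(ValueError):
            ff_test(np.zeros((2, 2)), np.ones((10, 2)))

    def test_p_floor_respected(self):
        rng = np.random.default_rng(4)
        res = ff_test(rng.normal(size=(10, 2)), rng.normal(size=(12, 2)),
                      n_perm=150, seed=5)
        assert res.p_value >= 1 / 151


class TestBonferroni:
    def test_study_family(self):
        assert bonferroni_threshold(0.05, 24) == 0.0021

    def test_single_test(self):
        assert bonferroni_threshold(0.05, 1) == 0.05

    def test_other_family(self):
        assert bonferroni_threshold(0.01, 10) == 0.001

    def test_invalid_alpha(self):
        with pytest.raises(ValueError):
            bonferroni_threshold(1.5, 10)


class TestJenks:
    def test_perfectly_separable(self):
        res = jenks_discretize(np.array([1, 1, 1, 10, 10, 10.0]), (2, 2))
        assert res.k == 2 and res.gof == pytest.approx(1.0)
        assert list(res.labels) == [0, 0, 0, 1, 1, 1]

    @pytest.mark.parametrize("seed", [3, 11])
    def test_matches_exhaustive_search(self, seed):
        vals = np.sort(np.random.default_rng(seed).uniform(size=20))
        res = jenks_discretize(vals, (3, 3))
        best = np.inf
        for c1, c2 in itertools.combinations(range(1, 20), 2):
            groups = [vals[:c1], vals[c1:c2], vals[c2:]]
            w = sum(float(((g - g.mean()) ** 2).sum()) for g in groups)
            best = min(best, w)
        total = float(((vals - vals.mean()) ** 2).sum())
        assert res.gof == pytest.approx(1 - best / total, abs=1e-9)

    def test_bimodal_selects_two_groups(self):
        rng = np.random.default_rng(5)
        vals = np.concatenate([rng.normal(0, 0.2, 40), rng.normal(5, 0.2, 40)])
        res = jenks_discretize(vals)
        assert res.k == 2 and res.gof > 0.95

    def test_gof_nondecreasing_in_k(self):
        vals = np.random.default_rng(6).normal(size=30)
        gofs = [jenks_discretize(vals, (k, k)).gof for k in (2, 3, 4)]
        assert gofs == sorted(gofs)

    def test_k_equals_distinct_values_perfect_fit(self):
        vals = np.array([1.0, 2.0, 7.0, 1.0, 2.0, 7.0])
        res = jenks_discretize(vals, (3, 3))
        assert res.gof == pytest.approx(1.0)

    def test_identical_values_rejected(self):
        with pytest.raises(ValueError):
            jenks_discretize(np.full(10, 3.0))


class TestCramersV:
    def test_perfect_association(self):
        labels = [0] * 10 + [1] * 10
        assert cramers_v(labels, labels) == pytest.approx(1.0)

    def test_independent_labels_small(self):
        rng = np.random.default_rng(7)
        a, b = rng.integers(0, 2, 5000), rng.integers(0, 2, 5000)
        assert cramers_v(a, b) < 0.05

    def test_matches_chi2_formula(self):
        rng = np.random.default_rng(8)
        a, b = rng.integers(0, 2, 100), rng.integers(0, 3, 100)
        table = pd.crosstab(pd.Series(a), pd.Series(b)).to_numpy()
        chi2 = chi2_contingency(table, correction=False).statistic
        oracle = np.sqrt(chi2 / (100 * (min(table.shape) - 1)))
        assert cramers_v(a, b) == pytest.approx(oracle, abs=1e-12)

    def test_degenerate_table_nan(self):
        assert np.isnan(cramers_v([0] * 10, list(range(10))))

    @settings(deadline=None, max_examples=20)
    @given(st.lists(st.integers(0, 2), min_size=20, max_size=60))
    def test_swap_and_relabel_invariance(self, a):
        rng = np.random.default_rng(9)
        b = rng.integers(0, 2, len(a))
        v1 = cramers_v(a, b)
        v2 = cramers_v(b, a)
        relabeled = [{0: 2, 1: 0, 2: 1}[x] for x in a]
        v3 = cramers_v(relabeled, b)
        if np.isnan(v1):
            assert np.isnan(v2) and np.isnan(v3)
        else:
            assert v1 == pytest.approx(v2) and v1 == pytest.approx(v3)

    def test_missing_pairs_dropped(self):
        a = pd.Series([0, 0, 1, 1, np.nan] * 4)
        b = pd.Series([0, 0, 1, 1, 1] * 4)
        assert cramers_v(a, b) == pytest.approx(1.0)


class TestAssociationMatrix:
    def _subgroups(self, n, rng):
        return pd.DataFrame(
            {m: rng.choice([MORE, LESS], n) for m in
             ("sex_code", "onset_site", "frs_total", "frs_bulb", "frs_resp",
              "sit_rate", "sit_intell", "fvc_pct")},
            index=range(n),
        )

    def test_eight_by_fiftythree_cells(self):
        rng = np.random.default_rng(10)
        preds = pd.DataFrame(rng.normal(size=(60, 53)), index=range(60))
        assoc = association_matrix(preds, self._subgroups(60, rng))
        assert assoc.values.shape == (8, 53)
        assert assoc.values.size == 424

    def test_prediction_matching_group_gives_v_one(self):
        rng = np.random.default_rng(11)
        groups = self._subgroups(60, rng)
        preds = pd.DataFrame(
            {"feat": np.where(groups["sit_rate"] == MORE, 5.0, 0.0)
             + 0.01 * rng.normal(size=60)},
            index=groups.index,
        )
        assoc = association_matrix(preds, groups)
        assert assoc.values.loc["sit_rate", "feat"] > 0.95

    def test_shuffled_labels_mostly_below_large_effect(self):
        rng = np.random.default_rng(12)
        preds = pd.DataFrame(rng.normal(size=(100, 53)), index=range(100))
        assoc = association_matrix(preds, self._subgroups(100, rng))
        frac_small = float((assoc.values.to_numpy() < 0.35).mean())
        assert frac_small >= 0.95


class TestClusterAssociation:
    def _block_matrix(self):
        vals = np.zeros((6, 10))
        vals[:3, :5] = 0.8
        vals[3:, 5:] = 0.8
        return AssociationMatrix(
            values=pd.DataFrame(vals, index=[f"m{i}" for i in range(6)],
                                columns=[f"f{j}" for j in range(10)])
        )

    def test_blocks_contiguous_after_clustering(self):
        out = cluster_association_matrix(self._block_matrix())
        row_groups = ["".join(sorted(set(m[0] for m in out.row_order[:3])))]
        rows = [out.row_order.index(f"m{i}") for i in range(3)]
        assert max(rows) - min(rows) == 2  # m0-m2 contiguous
        cols = [out.col_order.index(f"f{j}") for j in range(5)]
        assert max(cols) - min(cols) == 4

    def test_row_permutation_invariance(self):
        mat = self._block_matrix()
        perm = [3, 0, 5, 1, 4, 2]
        shuffled = AssociationMatrix(values=mat.values.iloc[perm])
        o1 = cluster_association_matrix(mat)
        o2 = cluster_association_matrix(shuffled)
        assert set(map(frozenset, [o1.row_order[:3], o1.row_order[3:]])) == set(
            map(frozenset, [o2.row_order[:3], o2.row_order[3:]])
        )

    def test_all_zero_matrix_blank_display(self):
        mat = AssociationMatrix(values=pd.DataFrame(np.zeros((4, 6))))
        out = cluster_association_matrix(mat)
        assert (out.display.to_numpy() == 0).all()

    def test_display_thresholds(self):
        vals = pd.DataFrame([[0.2, 0.4, 0.7], [0.35, 0.5, 0.9]])
        out = cluster_association_matrix(AssociationMatrix(values=vals))
        disp = out.display.sort_index().sort_index(axis=1).to_numpy()
        assert disp[0, 0] == 0.0 and disp[1, 0] == 0.0  # <= 0.35 blanked
        assert disp[0, 2] == 0.5 and disp[1, 2] == 0.5  # saturated at ceiling
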