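"""Region-pair pooling and directionality statistics tests."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats as sps

from mtlnet.metrics import ConnectivityResult
from mtlnet.stats import (
    RegionPairGroup,
    anova_direction,
    asymmetry_differences,
    directionality_table,
    pool_ccep_pairs,
    pool_region_pairs,
    significance_stars,
    soz_contrast,
    ttest_zero_mean,
)

LABELS4 = ["AMG1", "AMG2", "HPC1", "HPC2", "TP1", "TP2", "PHP1", "PHP2"]
REGIONS4 = {l: l[:-1] for l in LABELS4}
LABELS2 = ["AMG1", "AMG2", "HPC1", "HPC2"]
REGIONS2 = {l: l[:-1] for l in LABELS2}


class TestPooling:
    def test_four_regions_give_six_groups(self, rng):
        M = rng.random((8, 8))
        groups = pool_region_pairs(M, LABELS4, REGIONS4)
        assert len(groups) == 6
        assert all(len(g.forward) == len(g.reverse) == 4 for g in groups)

    def test_two_regions_give_one_group(self, rng):
        groups = pool_region_pairs(rng.random((4, 4)), LABELS2, REGIONS2)
        assert len(groups) == 1
        assert groups[0].pair == ("AMG", "HPC")

    def test_forward_and_reverse_are_mirrored_elements(self):
        M = np.arange(16, dtype=float).reshape(4, 4)
        (g,) = pool_region_pairs(M, LABELS2, REGIONS2)
        assert list(g.forward) == [M[0, 2], M[0, 3], M[1, 2], M[1, 3]]
        assert list(g.reverse) == [M[2, 0], M[3, 0], M[2, 1], M[3, 1]]

    def test_empty_region_omitted_with_warning(self, rng):
        regions = dict(REGIONS4, X1="X")  # declared but without contacts
        with pytest.warns(RuntimeWarning, match="X"):
            groups = pool_region_pairs(rng.random((8, 8)), LABELS4, regions)
        assert len(groups) == 6  # X-involving pairs absent

    def test_ccep_table_pooling(self):
        rows = []
        for src, tgt in (("AMG", "HPC"), ("HPC", "AMG"), ("AMG", "TP")):
            rows.append({"stim_pair": "x", "channel": "y",
                         "source_region": src, "target_region": tgt,
                         "z": 1.0, "latency_s": 0.02})
        with pytest.warns(RuntimeWarning, match="lacks one direction"):
            groups = pool_ccep_pairs(pd.DataFrame(rows))
        assert len(groups) == 1  # AMG<->TP lacks the reverse direction
        assert groups[0].pair == ("AMG", "HPC")


class TestAsymmetryDifferences:
    def test_symmetric_matrix_gives_zero(self):
        M = np.ones((4, 4))
        diffs = asymmetry_differences(M, LABELS2, REGIONS2)
        for d in diffs.values():
            np.testing.assert_allclose(d, 0.0)

    def test_plain_arithmetic(self):
        M = np.zeros((4, 4))
        M[0, 2], M[2, 0] = 0.4, 0.1
        diffs = asymmetry_differences(M, LABELS2, REGIONS2)
        assert diffs[("AMG", "HPC")][0] == pytest.approx(0.3)

    def test_transpose_negates(self, rng):
        M = rng.random((4, 4))
        d1 = asymmetry_differences(M, LABELS2, REGIONS2)
        d2 = asymmetry_differences(M.T, LABELS2, REGIONS2)
        for k in d1:
            np.testing.assert_allclose(d1[k], -d2[k])

    def test_non_square_rejected(self):
        with pytest.raises(ValueError):
            asymmetry_differences(np.zeros((3, 4)), LABELS2, REGIONS2)


class TestTTest:
    def test_type_one_error_calibrated(self, rng):
        """Null rejections at alpha = 0.05 land in [0.03, 0.07]."""
        rejections = 0
        for _ in range(1000):
            t = ttest_zero_mean(rng.standard_normal(50))
            rejections += t.p < 0.05
        assert 0.03 <= rejections / 1000 <= 0.07

    def test_power_against_shifted_mean(self, rng):
        hits = 0
        for _ in range(200):
            t = ttest_zero_mean(rng.standard_normal(50) + 0.5)
            hits += t.p < 0.05
        assert hits / 200 > 0.9

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError, match="variance"):
            ttest_zero_mean([1.0, 1.0, 1.0])
        with pytest.raises(ValueError):
            ttest_zero_mean([1.0])

    def test_favored_direction_follows_sign(self):
        t = ttest_zero_mean([0.2, 0.3, 0.25], pair=("A", "B"))
        assert t.favored == "A->B" and t.diff_mean > 0


class TestAnova:
    def test_identical_groups_give_zero_f(self):
        g = RegionPairGroup(("A", "B"), [1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        r = anova_direction(g)
        assert r.F == pytest.approx(0.0)

    def test_f_equals_squared_pooled_t(self, rng):
        """Two-level one-way ANOVA F is identically t^2."""
        for _ in range(20):
            f = rng.standard_normal(7) + 0.4
            v = rng.standard_normal(5)
            r = anova_direction(RegionPairGroup(("A", "B"), f, v))
            t, p = sps.ttest_ind(f, v, equal_var=True)
            assert r.F == pytest.approx(t**2, abs=1e-10)
            assert r.p == pytest.approx(p, abs=1e-12)
            assert r.df1 == 1 and r.df2 == 10

    def test_bonferroni_correction_bounds(self, rng):
        g = RegionPairGroup(("A", "B"), rng.standard_normal(6) + 1.0,
                            rng.standard_normal(6))
        r1 = anova_direction(g, n_comparisons=1)
        r30 = anova_direction(g, n_comparisons=30)
        assert r30.p_corrected >= r1.p_corrected
        assert r30.p_corrected >= r30.p
        assert r30.p_corrected <= 1.0

    def test_favored_direction_matches_group_means(self, rng):
        for _ in range(20):
            f = rng.standard_normal(5)
            v = rng.standard_normal(5)
            r = anova_direction(RegionPairGroup(("A", "B"), f, v))
            expect = "A->B" if f.mean() > v.mean() else "B->A"
            assert r.favored == expect

    def test_empty_direction_rejected(self):
        g = RegionPairGroup(("A", "B"), [1.0], [])
        with pytest.raises(ValueError, match="empty"):
            anova_direction(g)

    def test_stars(self):
        assert significance_stars(0.0005) == "***"
        assert significance_stars(0.005) == "**"
        assert significance_stars(0.049) == "*"
        assert significance_stars(0.2) == ""


class TestDirectionalityTable:
    def _result(self, rng, asym=0.0):
        bands = {}
        for name in ("beta", "low_gamma"):
            M = rng.random((8, 8)) * 0.01
            M[0:2, 2:4] += asym  # AMG -> HPC boost
            bands[name] = M
        return ConnectivityResult(
            "GC", np.zeros((8, 8, 2)), np.array([1.0, 2.0]), LABELS4,
            band_values=bands,
        )

    def test_table_shape_and_family_size(self, rng):
        tab = directionality_table(self._result(rng, 0.5), REGIONS4,
                                   bands=("beta", "low_gamma"))
        assert len(tab) == 12  # 6 pairs x 2 bands
        amg_hpc = tab[(tab["pair"] == "AMG-HPC") & (tab["band"] == "beta")]
        assert amg_hpc.iloc[0]["direction"] == "AMG->HPC"
        assert amg_hpc.iloc[0]["p_corrected"] >= amg_hpc.iloc[0]["p_raw"]

    def test_missing_band_aggregates_rejected(self):
        res = ConnectivityResult("GC", np.zeros((8, 8, 2)),
                                 np.array([1.0, 2.0]), LABELS4)
        with pytest.raises(ValueError, match="band"):
            directionality_table(res, REGIONS4)


class TestSozContrast:
    def _table(self, direction="AMG->HPC", p=0.001):
        return pd.DataFrame(
            [{"pair": "AMG-HPC", "band": "beta", "metric": "GC",
              "direction": direction, "p_corrected": p}]
        )

    def test_identical_tables_report_no_changes(self):
        out = soz_contrast(self._table(), self._table())
        assert not out["direction_flip"].any()
        assert not out["significance_change"].any()

    def test_direction_flip_detected(self):
        out = soz_contrast(self._table("AMG->HPC"), self._table("HPC->AMG"))
        assert out["direction_flip"].all()

    def test_significance_change_detected(self):
        out = soz_contrast(self._table(p=0.001), self._table(p=0.5))
        assert out["significance_change"].all()
        assert not out["direction_flip"].any()  # ns results cannot flip

    def test_dropped_pair_reported(self):
        full = pd.concat(
            [self._table(),
             pd.DataFrame([{"pair": "HPC-TP", "band": "beta", "metric": "GC",
                            "direction": "TP->HPC", "p_corrected": 0.01}])],
            ignore_index=True,
        )
        out = soz_contrast(full, self._table())
        assert out.loc[out["pair"] == "HPC-TP", "pair_dropped"].all()

    def test_unknown_pair_in_reduced_rejected(self):
        extra = pd.concat(
            [self._table(),
             pd.DataFrame([{"pair": "X-Y", "band": "beta", "metric": "GC",
                            "direction": "X->Y", "p_corrected": 0.01}])],
            ignore_index=True,
        )
        with pytest.raises(ValueError, match="unknown"):
            soz_contrast(self._table(), extra)
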