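"""Connectivity metric tests: oracle equivalence, normalisations, recovery."""

import numpy as np
import pytest
from conftest import make_epochset
from oracles import (
    bruteforce_dtf,
    bruteforce_gc,
    bruteforce_pdc,
    bruteforce_spectral,
)

from mtlnet.metrics import (
    DEFAULT_BANDS,
    BandScheme,
    ConnectivityResult,
    band_aggregate,
    dtf,
    epoch_average,
    granger_spectral,
    pdc,
)
from mtlnet.mvar import MVARModel, SpectralDecomposition, evaluate_spectral, fit_mvar
from mtlnet.synth import (
    CouplingEdge,
    RegionSpec,
    make_ground_truth_mvar,
    simulate_mvar_recording,
)

FREQS = np.arange(1.0, 41.0)


def model(A, C=None, fs=250.0):
    A = np.asarray(A, dtype=float)
    return MVARModel(order=A.shape[0], A=A,
                     C_n=np.eye(A.shape[1]) if C is None else np.asarray(C),
                     sampling_rate=fs)


TWO_CHANNEL = model(
    [[[0.5, 0.0], [0.5, 0.3]], [[-0.2, 0.0], [0.1, -0.1]]],
    C=np.array([[1.0, 0.3], [0.3, 0.8]]),
)  # unidirectional 1->2, correlated innovations

THREE_CHAIN = model(
    [[[0.5, 0, 0], [0.4, 0.3, 0], [0, 0.4, 0.2]],
     [[-0.2, 0, 0], [0, 0.1, 0], [0, 0, -0.1]]],
    C=np.array([[1.0, 0.2, 0.0], [0.2, 0.8, 0.1], [0.0, 0.1, 1.2]]),
)  # chain 1 -> 2 -> 3 with no direct 1 -> 3 path


class TestOracleEquivalence:
    @pytest.mark.parametrize("m", [TWO_CHANNEL, THREE_CHAIN],
                             ids=["2ch", "3chain"])
    def test_metrics_match_bruteforce(self, m):
        """Vectorised GC/DTF/PDC equal explicit-loop evaluations to 1e-10."""
        dec = evaluate_spectral(m, FREQS)
        Abar, H, S = bruteforce_spectral(list(m.A), m.C_n, m.sampling_rate,
                                         FREQS)
        assert np.abs(dec.A_bar - Abar).max() < 1e-10
        assert np.abs(dec.H - H).max() < 1e-10
        assert np.abs(dec.S - S).max() < 1e-10
        off = ~np.eye(m.n_channels, dtype=bool)
        gc = granger_spectral(dec, m).values
        assert np.abs(gc - bruteforce_gc(H, S, m.C_n))[off].max() < 1e-10
        assert np.abs(dtf(dec).values - bruteforce_dtf(H)).max() < 1e-10
        assert np.abs(pdc(dec).values - bruteforce_pdc(Abar)).max() < 1e-10


class TestNormalisationsAndBounds:
    @pytest.mark.parametrize("m", [TWO_CHANNEL, THREE_CHAIN],
                             ids=["2ch", "3chain"])
    def test_dtf_rows_and_pdc_columns_sum_to_one(self, m):
        dec = evaluate_spectral(m, FREQS)
        d = dtf(dec).values
        p = pdc(dec).values
        # DTF^2: sources sum to 1 for every target and frequency
        assert np.abs(d.sum(axis=0) - 1).max() < 1e-10
        # PDC: squared magnitudes over targets sum to 1 per source column
        assert np.abs((p**2).sum(axis=1) - 1).max() < 1e-10
        assert d.min() >= 0 and d.max() <= 1
        assert p.min() >= 0 and p.max() <= 1

    def test_gc_nonnegative_and_identity_h_patterns(self):
        dec = evaluate_spectral(TWO_CHANNEL, FREQS)
        assert granger_spectral(dec, TWO_CHANNEL).values.min() >= 0
        ident = evaluate_spectral(model(np.zeros((1, 3, 3))), FREQS)
        d = dtf(ident).values
        eye = np.broadcast_to(np.eye(3)[:, :, None], d.shape)
        np.testing.assert_allclose(d, eye, atol=1e-12)

    def test_diagonal_model_has_no_cross_terms(self):
        m = model([np.diag([0.5, -0.3, 0.2]), np.diag([-0.1, 0.05, 0.1])])
        dec = evaluate_spectral(m, FREQS)
        off = ~np.eye(3, dtype=bool)
        assert granger_spectral(dec, m).values[off].max() < 1e-10
        assert dtf(dec).values[off].max() < 1e-10
        assert pdc(dec).values[off].max() < 1e-10

    def test_fitted_diagonal_generator_floors_shrink_with_n(
        self, epochs_from_array
    ):
        """Fitting noise leaves only O(1/N)-scale spurious cross terms."""
        spec = RegionSpec({"A": 1, "B": 1, "C": 1})
        gt = make_ground_truth_mvar(spec, [], order=2, seed=0,
                                    sampling_rate=250.0,
                                    within_region_coupling=0.0)
        rec = simulate_mvar_recording(gt, 800.0, seed=1)  # 200k samples
        ep = epochs_from_array([rec.data], 250.0, rec.channel_labels)
        m = fit_mvar(ep, 2)
        dec = evaluate_spectral(m)
        off = ~np.eye(3, dtype=bool)
        assert granger_spectral(dec, m).values[off].max() < 1e-3
        assert dtf(dec).values[off].max() < 5e-3
        assert pdc(dec).values[off].max() < 0.05


class TestDirectionality:
    def test_unidirectional_coupling_dominates_at_every_frequency(self):
        dec = evaluate_spectral(TWO_CHANNEL, FREQS)
        gc = granger_spectral(dec, TWO_CHANNEL).values
        assert np.all(gc[0, 1, :] > gc[1, 0, :])

    def test_chain_separates_direct_from_cascaded_influence(self):
        """PDC sees no 1->3 link; DTF carries the cascade through 2."""
        dec = evaluate_spectral(THREE_CHAIN, FREQS)
        p = pdc(dec).values
        d = dtf(dec).values
        assert p[0, 2, :].max() < 1e-10
        assert d[0, 2, :].min() > 1e-3

    def test_single_edge_direction_recovered_from_data(self):
        """metric(source->target) > metric(target->source) in >= 95/100 runs."""
        spec = RegionSpec({"AMG": 1, "HPC": 1})
        wins = {"gc": 0, "dtf": 0, "pdc": 0}
        for seed in range(100):
            gt = make_ground_truth_mvar(
                spec, [CouplingEdge("AMG", "HPC", 0.3, 2)], order=4,
                seed=seed, sampling_rate=250.0,
            )
            rec = simulate_mvar_recording(gt, 60.0, seed=5000 + seed)
            ep = make_epochset([rec.data], 250.0, rec.channel_labels)
            m = fit_mvar(ep, 4)
            dec = evaluate_spectral(m)
            gc = band_aggregate(granger_spectral(dec, m))
            dd = band_aggregate(dtf(dec))
            pp = band_aggregate(pdc(dec))
            for name, res in (("gc", gc), ("dtf", dd), ("pdc", pp)):
                fwd = np.mean([b[0, 1] for b in res.band_values.values()])
                rev = np.mean([b[1, 0] for b in res.band_values.values()])
                wins[name] += fwd > rev
        assert min(wins.values()) >= 95, wins


class TestBandAggregation:
    def test_constant_metric_gives_constant_bands(self):
        vals = np.full((2, 2, 40), 0.37)
        res = ConnectivityResult("DTF", vals, FREQS, ["a", "b"])
        out = band_aggregate(res)
        for b in out.band_values.values():
            np.testing.assert_allclose(b, 0.37)

    def test_delta_band_is_mean_over_1_to_4_hz(self):
        vals = np.zeros((1, 1, 40))
        vals[0, 0, :] = np.arange(1, 41)  # value == frequency
        res = ConnectivityResult("GC", vals, FREQS, ["a"])
        out = band_aggregate(res)
        assert out.band_values["delta"][0, 0] == pytest.approx((1 + 2 + 3 + 4) / 4)
        assert out.band_values["low_gamma"][0, 0] == pytest.approx(
            np.mean(np.arange(25, 41))
        )

    def test_hand_averaged_toy_cube(self):
        freqs = np.array([1.0, 2.0, 3.0])
        vals = np.array([[[0.1, 0.2, 0.6]]])
        scheme = BandScheme(bands=(("lo", 1, 2), ("hi", 3, 3)))
        out = band_aggregate(ConnectivityResult("GC", vals, freqs, ["a"]),
                             scheme)
        assert out.band_values["lo"][0, 0] == pytest.approx(0.15)
        assert out.band_values["hi"][0, 0] == pytest.approx(0.6)

    def test_band_outside_grid_rejected(self):
        res = ConnectivityResult("GC", np.zeros((1, 1, 10)),
                                 np.arange(1.0, 11.0), ["a"])
        with pytest.raises(ValueError, match="outside"):
            band_aggregate(res, DEFAULT_BANDS)

    def test_band_scheme_validation(self):
        with pytest.raises(ValueError):
            BandScheme(bands=(("a", 1, 4), ("b", 3, 8)))  # overlap
        with pytest.raises(ValueError):
            BandScheme(bands=(("a", 5, 4),))


class TestEpochAverage:
    def _res(self, fill):
        return ConnectivityResult("GC", np.full((2, 2, 5), fill),
                                  np.arange(1.0, 6.0), ["a", "b"])

    def test_identical_inputs_are_a_fixed_point(self):
        out = epoch_average([self._res(0.4), self._res(0.4)])
        np.testing.assert_allclose(out.values, 0.4)
        assert out.n_epochs_averaged == 2

    def test_two_inputs_give_half_sum(self):
        out = epoch_average([self._res(0.2), self._res(0.6)])
        np.testing.assert_allclose(out.values, 0.4)

    def test_empty_and_mixed_inputs_rejected(self):
        with pytest.raises(ValueError):
            epoch_average([])
        other = ConnectivityResult("DTF", np.zeros((2, 2, 5)),
                                   np.arange(1.0, 6.0), ["a", "b"])
        with pytest.raises(ValueError, match="metric"):
            epoch_average([self._res(0.1), other])

    def test_half_vs_full_epoch_averages_agree_for_stationary_data(
        self, epochs_from_array
    ):
        """Split-half stability at the metric level for a small model."""
        rec = simulate_mvar_recording(TWO_CHANNEL, 600.0, seed=9)
        ep = epochs_from_array(
            np.array_split(rec.data, 60), 250.0, ["a", "b"]
        )
        results = []
        for i in range(ep.n_epochs):
            m = fit_mvar(ep.subset([i]), 2)
            results.append(granger_spectral(evaluate_spectral(m, FREQS), m))
        first = epoch_average(results[:30])
        full = epoch_average(results)
        # Monte-Carlo agreement of the off-diagonal mean metric
        assert abs(first.values[0, 1].mean() - full.values[0, 1].mean()) < 0.01


class TestErrorPaths:
    def test_zero_inflow_row_rejected_by_dtf(self):
        H = np.ones((2, 2, 2), dtype=complex)
        H[:, 0, :] = 0.0
        dec = SpectralDecomposition(np.array([1.0, 2.0]), H.copy(), H,
                                    H.copy(), ["a", "b"])
        with pytest.raises(ValueError, match="inflow"):
            dtf(dec)

    def test_zero_outflow_column_rejected_by_pdc(self):
        Ab = np.ones((2, 2, 2), dtype=complex)
        Ab[:, :, 1] = 0.0
        dec = SpectralDecomposition(np.array([1.0, 2.0]), Ab, Ab.copy(),
                                    Ab.copy(), ["a", "b"])
        with pytest.raises(ValueError, match="outflow"):
            pdc(dec)
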