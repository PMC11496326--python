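"""Frequency-resolved directed connectivity metrics from a fitted MVAR model.

Three measures are computed from the spectral decomposition (Abar, H, S) and
the innovation covariance C_n, all stored with the fixed orientation
``values[source, target, frequency]``:

Granger causality (GC)
    Pairwise Geweke spectral measure evaluated from the full multivariate
    model. For source s and target t,

        f_{s->t}(w) = ln[ S_tt(w) / (S_tt(w) - C_ss|t |H_ts(w)|^2) ]

    where C_ss|t = C_ss - C_ts^2 / C_tt is the source innovation variance
    after removing its instantaneous correlation with the target. (The
    standard noise-decorrelating transformation of H leaves the (t, s)
    element unchanged, so H_ts appears directly.) Negative round-off is
    clipped at 0.

Directed transfer function (DTF, reported squared)
    DTF^2_{j->i}(w) = |H_ij(w)|^2 / sum_m |H_im(w)|^2 — the inflow from j to
    i relative to all inflows to i; rows over sources sum to 1 for each
    target, so values lie in [0, 1]. Captures direct plus cascaded influence.

Partial directed coherence (PDC, reported as magnitude)
    PDC_ij(w) = |Abar_ij(w)| / sqrt(a_j(w)^H a_j(w)) with a_j the j-th
    column of Abar — the outflow from source j to i relative to all outflows
    of j; squared magnitudes over targets sum to 1 per source column.
    Captures direct influence only (sinks are emphasised).

Band aggregation averages a metric over the integer frequencies inside each
of the classical EEG bands (delta 1-4, theta 5-8, alpha 9-12, beta 13-24 Hz)
plus low gamma (25-40 Hz), edges inclusive.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .mvar import MVARModel, SpectralDecomposition

__all__ = [
    "BandScheme",
    "DEFAULT_BANDS",
    "ConnectivityResult",
    "granger_spectral",
    "dtf",
    "pdc",
    "band_aggregate",
    "epoch_average",
]


@dataclass(frozen=True)
class BandScheme:
    """Named frequency bands with inclusive integer-Hz edges."""

    bands: tuple  # of (name, lo, hi)

    def __post_init__(self):
        prev_hi = 0
        for name, lo, hi in self.bands:
            if lo > hi:
                raise ValueError(f"band {name}: lo > hi")
            if lo <= prev_hi:
                raise ValueError("bands must be ordered and non-overlapping")
            prev_hi = hi

    @property
    def names(self):
        return [b[0] for b in self.bands]

    def edges(self, name):
        for n, lo, hi in self.bands:
            if n == name:
                return lo, hi
        raise KeyError(name)


DEFAULT_BANDS = BandScheme(
    bands=(
        ("delta", 1, 4),
        ("theta", 5, 8),
        ("alpha", 9, 12),
        ("beta", 13, 24),
        ("low_gamma", 25, 40),
    )
)


@dataclass
class ConnectivityResult:
    """Metric cube [source, target, frequency] plus band aggregates.

    ``values[s, t, f]`` quantifies the influence of channel s on channel t
    at ``frequencies[f]``. The diagonal is computed but is to be excluded
    from statistics. ``band_values`` maps a band name to an (n, n) matrix.
    """

    metric: str
    values: np.ndarray
    frequencies: np.ndarray
    channel_labels: list
    band_values: dict = field(default_factory=dict)
    n_epochs_averaged: int = 1

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 3 or self.values.shape[0] != self.values.shape[1]:
            raise ValueError("values must be (n, n, F)")
        if self.values.shape[2] != len(self.frequencies):
            raise ValueError("frequency axis mismatch")

    @property
    def n_channels(self):
        return self.values.shape[0]


def granger_spectral(decomp: SpectralDecomposition, model: MVARModel) -> ConnectivityResult:
    """Pairwise Geweke spectral Granger causality from the full model."""
    if decomp.n_channels != model.n_channels:
        raise ValueError("decomposition and model disagree on channel count")
    H, S, C = decomp.H, decomp.S, model.C_n
    n = model.n_channels
    S_diag = np.real(np.einsum("fii->fi", S))  # (F, n)
    if np.any(S_diag <= 0):
        f_bad = decomp.frequencies[np.argwhere(S_diag <= 0)[0][0]]
        raise ValueError(f"non-positive spectral density diagonal at {f_bad:g} Hz")
    c_diag = np.diag(C)
    # cond[s, t] = C_ss - C_ts^2 / C_tt (source noise given target noise)
    cond = c_diag[:, None] - C.T**2 / c_diag[None, :]
    H2 = np.abs(H) ** 2  # (F, n, n); H2[f, t, s] = |H_ts|^2
    # numer/denom arranged as [s, t, f]
    Stt = S_diag.T[None, :, :]  # (1, n, F) -> broadcast over source axis
    term = cond[:, :, None] * np.transpose(H2, (2, 1, 0))
    denom = Stt - term
    # Guard against round-off driving the denominator non-positive.
    denom = np.maximum(denom, np.asarray(Stt) * 1e-12)
    vals = np.log(Stt / denom)
    vals = np.clip(vals, 0.0, None)
    idx = np.arange(n)
    vals[idx, idx, :] = 0.0
    return ConnectivityResult(
        metric="GC",
        values=vals,
        frequencies=decomp.frequencies,
        channel_labels=list(decomp.channel_labels),
    )


def dtf(decomp: SpectralDecomposition) -> ConnectivityResult:
    """Squared directed transfer function DTF^2 (inflow normalisation)."""
    H2 = np.abs(decomp.H) ** 2  # (F, n, n), [f, target, source]
    denom = H2.sum(axis=2, keepdims=True)  # row sums over sources
    if np.any(denom <= 0):
        raise ValueError("zero inflow row in transfer matrix")
    vals = np.transpose(H2 / denom, (2, 1, 0))  # -> [source, target, f]
    return ConnectivityResult(
        metric="DTF",
        values=vals,
        frequencies=decomp.frequencies,
        channel_labels=list(decomp.channel_labels),
    )


def pdc(decomp: SpectralDecomposition) -> ConnectivityResult:
    """Partial directed coherence |Abar_ij| / ||Abar column j|| (outflow)."""
    Ab = decomp.A_bar  # (F, n, n), [f, target, source]
    colnorm = np.sqrt(np.sum(np.abs(Ab) ** 2, axis=1, keepdims=True))
    if np.any(colnorm <= 0):
        raise ValueError("zero outflow column in Abar")
    vals = np.transpose(np.abs(Ab) / colnorm, (2, 1, 0))
    return ConnectivityResult(
        metric="PDC",
        values=vals,
        frequencies=decomp.frequencies,
        channel_labels=list(decomp.channel_labels),
    )


def band_aggregate(result: ConnectivityResult, scheme: BandScheme = DEFAULT_BANDS) -> ConnectivityResult:
    """Average the metric over the inclusive integer band edges.

    Returns a copy of `result` with ``band_values`` filled; every band must
    be covered by the evaluated frequency grid.
    """
    freqs = np.asarray(result.frequencies)
    band_values = {}
    for name, lo, hi in scheme.bands:
        mask = (freqs >= lo) & (freqs <= hi)
        if not mask.any() or freqs.min() > lo or freqs.max() < hi:
            raise ValueError(f"band {name} [{lo}, {hi}] outside evaluated grid")
        band_values[name] = result.values[:, :, mask].mean(axis=2)
    return ConnectivityResult(
        metric=result.metric,
        values=result.values,
        frequencies=result.frequencies,
        channel_labels=result.channel_labels,
        band_values=band_values,
        n_epochs_averaged=result.n_epochs_averaged,
    )


def epoch_average(results) -> ConnectivityResult:
    """Element-wise mean of per-epoch connectivity results.

    All inputs must share metric, shape and frequency grid; band values (if
    present on all inputs) are averaged too.
    """
    results = list(results)
    if not results:
        raise ValueError("empty result list")
    first = results[0]
    for r in results[1:]:
        if r.metric != first.metric:
            raise ValueError("mixed metrics cannot be averaged")
        if r.values.shape != first.values.shape or not np.array_equal(
            r.frequencies, first.frequencies
        ):
            raise ValueError("results have mismatched shapes or grids")
    vals = np.mean([r.values for r in results], axis=0)
    band_values = {}
    if all(r.band_values for r in results):
        for name in first.band_values:
            band_values[name] = np.mean(
                [r.band_values[name] for r in results], axis=0
            )
    return ConnectivityResult(
        metric=first.metric,
        values=vals,
        frequencies=first.frequencies,
        channel_labels=first.channel_labels,
        band_values=band_values,
        n_epochs_averaged=sum(r.n_epochs_averaged for r in results),
    )
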