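"""Multivariate autoregressive (MVAR) modelling and spectral evaluation.

The model of an n-channel recording x(t) at order p is

    x(t) = sum_{k=1..p} A(k) x(t-k) + eps(t),      Cov[eps] = C_n

with n x n lag-coefficient matrices A(k) (row i of A(k) predicts channel i,
so A[i, j] carries the influence j -> i at lag k) and white innovations eps.
Its frequency-domain counterparts on a grid of frequencies f (Hz), with
omega = 2*pi*f/fs, are

    Abar(omega) = I - sum_k A(k) exp(-1j*k*omega)
    H(omega)    = Abar(omega)^{-1}          (transfer matrix)
    S(omega)    = H(omega) C_n H(omega)^H   (spectral density matrix)

Fitting pools ordinary least squares across epochs: each epoch is mean-
removed per channel and contributes regression rows only from within itself
(no rows straddle epoch boundaries). Model order is selected by Schwarz's
Bayesian Criterion over a configurable range (default 8-40).
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg as sp_linalg

from .recording import EpochSet

__all__ = [
    "MVARModel",
    "SpectralDecomposition",
    "fit_mvar",
    "select_order",
    "evaluate_spectral",
    "companion_spectral_radius",
]

logger = logging.getLogger(__name__)

#: Companion spectral radii above this are treated as unstable.
STABILITY_RADIUS = 1.0 - 1e-7


def companion_spectral_radius(A):
    """Spectral radius of the companion matrix of lag coefficients `A`.

    Parameters
    ----------
    A : ndarray, shape (p, n, n)
        Lag coefficient matrices A(1..p).

    Returns
    -------
    float
        Largest eigenvalue magnitude; the process is stable iff < 1.
    """
    A = np.asarray(A, dtype=float)
    p, n, _ = A.shape
    comp = np.zeros((n * p, n * p))
    comp[:n, :] = np.concatenate(list(A), axis=1)
    if p > 1:
        comp[n:, : n * (p - 1)] = np.eye(n * (p - 1))
    return float(np.max(np.abs(np.linalg.eigvals(comp))))


@dataclass
class MVARModel:
    """Fitted (or constructed) MVAR model.

    Attributes
    ----------
    order : int
        Model order p.
    A : ndarray, shape (p, n, n)
        Lag coefficients; ``A[k-1][i, j]`` is the influence of channel j on
        channel i at lag k.
    C_n : ndarray, shape (n, n)
        Residual (innovation) covariance, symmetric positive semi-definite.
    sampling_rate : float
        Hz; carried along so spectral grids can be expressed in Hz.
    n_samples_used : int
        Pooled regression rows behind the fit (0 for constructed models).
    stable : bool
        Whether the companion spectral radius is below 1.
    """

    order: int
    A: np.ndarray
    C_n: np.ndarray
    sampling_rate: float
    n_samples_used: int = 0
    channel_labels: list = None
    stable: bool = True

    def __post_init__(self):
        self.A = np.asarray(self.A, dtype=float)
        self.C_n = np.asarray(self.C_n, dtype=float)
        p, n, m = self.A.shape
        if p != self.order or n != m:
            raise ValueError("A must have shape (order, n, n)")
        if self.C_n.shape != (n, n):
            raise ValueError("C_n shape does not match A")
        if not np.allclose(self.C_n, self.C_n.T, atol=1e-10):
            raise ValueError("C_n must be symmetric")
        if np.min(np.linalg.eigvalsh((self.C_n + self.C_n.T) / 2)) < -1e-10:
            raise ValueError("C_n must be positive semi-definite")
        if self.channel_labels is None:
            self.channel_labels = [f"ch{i}" for i in range(n)]

    @property
    def n_channels(self):
        return self.A.shape[1]

    @property
    def spectral_radius(self):
        return companion_spectral_radius(self.A)

    def to_json(self):
        """Serialize to a JSON document (coefficients row-major)."""
        return json.dumps(
            {
                "order": self.order,
                "n_channels": self.n_channels,
                "sampling_rate": self.sampling_rate,
                "n_samples_used": self.n_samples_used,
                "channel_labels": list(self.channel_labels),
                "A": self.A.tolist(),
                "C_n": self.C_n.tolist(),
                "stable": bool(self.stable),
            }
        )

    @classmethod
    def from_json(cls, doc):
        d = json.loads(doc)
        return cls(
            order=d["order"],
            A=np.array(d["A"]),
            C_n=np.array(d["C_n"]),
            sampling_rate=d["sampling_rate"],
            n_samples_used=d["n_samples_used"],
            channel_labels=d["channel_labels"],
            stable=d["stable"],
        )


@dataclass
class SpectralDecomposition:
    """Frequency-domain objects Abar, H, S of an MVAR model on a Hz grid."""

    frequencies: np.ndarray  # (F,) Hz
    A_bar: np.ndarray  # (F, n, n) complex
    H: np.ndarray  # (F, n, n) complex
    S: np.ndarray  # (F, n, n) complex
    channel_labels: list = None

    @property
    def n_channels(self):
        return self.A_bar.shape[1]


def _regression_rows(epochs: EpochSet, order, start_lag=None):
    """Stack pooled (Y, X) regression rows over epochs.

    Rows for epoch samples t >= start_lag (default: `order`); regressor block
    order is lag 1 first. Each epoch is mean-removed per channel.
    """
    if start_lag is None:
        start_lag = order
    n = epochs.n_channels
    Xs, Ys = [], []
    for e in epochs.epochs:
        e = e - e.mean(axis=0, keepdims=True)
        T = e.shape[0]
        if T <= start_lag:
            continue
        rows = T - start_lag
        X = np.empty((rows, n * order))
        for k in range(1, order + 1):
            X[:, (k - 1) * n : k * n] = e[start_lag - k : T - k]
        Xs.append(X)
        Ys.append(e[start_lag:])
    if not Xs:
        raise ValueError("no epoch is long enough for the requested order")
    return np.concatenate(Ys), np.concatenate(Xs)


def fit_mvar(epochs: EpochSet, order) -> MVARModel:
    """Fit an MVAR(`order`) model by pooled multi-epoch least squares.

    Each epoch contributes one-step prediction rows independently (presample
    lags never cross epoch boundaries); coefficients minimise the pooled
    squared prediction error and ``C_n`` is the pooled residual covariance.

    Raises
    ------
    ValueError
        If the pooled sample count is too small (needs more than
        ``10 * n_channels * order`` rows) or the regressor matrix is
        rank-deficient.
    """
    order = int(order)
    if order < 1:
        raise ValueError("order must be >= 1")
    n = epochs.n_channels
    usable = sum(max(0, e.shape[0] - order) for e in epochs.epochs)
    if usable <= 10 * n * order:
        raise ValueError(
            f"insufficient data: {usable} pooled rows for "
            f"{n} channels at order {order} (need > {10 * n * order})"
        )
    Y, X = _regression_rows(epochs, order)
    # Normal equations with a Cholesky solve; a rank-deficient Gram matrix
    # either fails the factorisation or leaves a negligible pivot.
    G = X.T @ X
    g = X.T @ Y
    try:
        c, low = sp_linalg.cho_factor(G)
        diag = np.abs(np.diag(c))
        if diag.min() < 1e-7 * diag.max():
            raise ValueError("rank-deficient regressor matrix")
        B = sp_linalg.cho_solve((c, low), g)
    except np.linalg.LinAlgError:
        raise ValueError("rank-deficient regressor matrix") from None
    resid = Y - X @ B
    N = Y.shape[0]
    C = resid.T @ resid / N
    # B is (n*order, n) with lag blocks stacked; A[k][i, j] predicts row i.
    A = np.stack([B[(k - 1) * n : k * n, :].T for k in range(1, order + 1)])
    model = MVARModel(
        order=order,
        A=A,
        C_n=(C + C.T) / 2,
        sampling_rate=epochs.sampling_rate,
        n_samples_used=N,
        channel_labels=list(epochs.channel_labels),
    )
    if model.spectral_radius >= STABILITY_RADIUS:
        warnings.warn("fitted MVAR model is unstable", RuntimeWarning)
        model.stable = False
    return model


def select_order(epochs: EpochSet, min_order=8, max_order=40,
                 return_trace=False):
    """Select the MVAR order by Schwarz's Bayesian Criterion.

    SBC(p) = ln det C_n(p) + (ln N / N) * p * n**2, minimised over the
    inclusive range [min_order, max_order]; ties break toward the smaller
    order. All candidate orders are scored on the same regression rows
    (those available at `max_order`), so their likelihoods are comparable
    and the Gram matrix is built once.

    Returns the selected order, or ``(order, {p: sbc})`` with
    ``return_trace=True``. If the data cannot support `max_order` the range
    is shrunk with a warning.
    """
    if min_order > max_order:
        raise ValueError("min_order must be <= max_order")
    if min_order < 1:
        raise ValueError("orders must be >= 1")
    n = epochs.n_channels

    def usable(p):
        return sum(max(0, e.shape[0] - p) for e in epochs.epochs)

    requested_max = max_order
    while max_order > min_order and usable(max_order) <= 10 * n * max_order:
        max_order -= 1
    if max_order < requested_max:
        warnings.warn(
            f"insufficient data for order {requested_max}; "
            f"search range shrunk to [{min_order}, {max_order}]",
            RuntimeWarning,
        )
    if usable(max_order) <= 10 * n * max_order:
        raise ValueError("insufficient data even for min_order")
    Y, X = _regression_rows(epochs, max_order)
    N = Y.shape[0]
    G = X.T @ X
    g = X.T @ Y
    YY = Y.T @ Y
    trace = {}
    for p in range(min_order, max_order + 1):
        d = n * p
        try:
            B = np.linalg.solve(G[:d, :d], g[:d])
        except np.linalg.LinAlgError:
            trace[p] = np.inf
            continue
        C = (YY - g[:d].T @ B) / N
        sign, logdet = np.linalg.slogdet((C + C.T) / 2)
        if sign <= 0:
            trace[p] = np.inf
            continue
        trace[p] = logdet + (np.log(N) / N) * p * n * n
    best = min(trace, key=lambda p: (trace[p], p))
    logger.debug("SBC trace: %s -> selected %d", trace, best)
    if return_trace:
        return best, trace
    return best


def evaluate_spectral(model: MVARModel, frequencies=None) -> SpectralDecomposition:
    """Evaluate Abar(omega), H(omega) and S(omega) on a frequency grid.

    Parameters
    ----------
    model : MVARModel
    frequencies : array-like of float, optional
        Grid in Hz, each in (0, Nyquist]. Defaults to integers 1..40 Hz.

    Notes
    -----
    H is obtained by a linear solve of Abar(omega) H = I per frequency
    rather than forming an explicit inverse.
    """
    fs = model.sampling_rate
    if frequencies is None:
        frequencies = np.arange(1, 41, dtype=float)
    freqs = np.asarray(frequencies, dtype=float)
    nyq = fs / 2
    if np.any(freqs <= 0) or np.any(freqs > nyq):
        raise ValueError(f"frequencies must lie in (0, {nyq}] Hz")
    if not np.all(np.isfinite(model.A)):
        raise ValueError("model coefficients are not finite")
    n, p = model.n_channels, model.order
    omega = 2 * np.pi * freqs / fs  # (F,)
    lags = np.arange(1, p + 1)
    # phase[f, k] = exp(-1j * k * omega_f)
    phase = np.exp(-1j * np.outer(omega, lags))
    A_bar = np.eye(n)[None, :, :] - np.einsum("fk,kij->fij", phase, model.A)
    I = np.eye(n, dtype=complex)
    H = np.empty_like(A_bar)
    for fi in range(len(freqs)):
        try:
            sv = np.linalg.svd(A_bar[fi], compute_uv=False)
            if sv[-1] < 1e-12 * max(1.0, sv[0]):
                raise np.linalg.LinAlgError
            H[fi] = np.linalg.solve(A_bar[fi], I)
        except np.linalg.LinAlgError:
            raise ValueError(
                f"Abar is numerically singular at {freqs[fi]:g} Hz"
            ) from None
    S = np.einsum("fij,jk,flk->fil", H, model.C_n, H.conj())
    return SpectralDecomposition(
        frequencies=freqs,
        A_bar=A_bar,
        H=H,
        S=S,
        channel_labels=list(model.channel_labels),
    )
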