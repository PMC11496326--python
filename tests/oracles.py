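"""Independent brute-force evaluations of the spectral connectivity formulas.

These deliberately avoid the package's vectorised code paths: the
frequency-domain coefficient matrix is assembled with explicit scalar
loops, the transfer matrix comes from an explicit inverse, and each metric
is computed element by element from its defining ratio. They serve as
oracles for equivalence tests.
"""

import numpy as np


def bruteforce_spectral(A_list, C, fs, freqs):
    """Return (Abar, H, S) stacked over `freqs`, via explicit loops."""
    n = A_list[0].shape[0]
    F = len(freqs)
    Abar = np.zeros((F, n, n), dtype=complex)
    H = np.zeros_like(Abar)
    S = np.zeros_like(Abar)
    for fi, f in enumerate(freqs):
        w = 2 * np.pi * f / fs
        M = np.eye(n, dtype=complex)
        for k, Ak in enumerate(A_list, start=1):
            for i in range(n):
                for j in range(n):
                    M[i, j] -= Ak[i, j] * np.exp(-1j * k * w)
        Abar[fi] = M
        H[fi] = np.linalg.inv(M)
        S[fi] = H[fi] @ C @ H[fi].conj().T
    return Abar, H, S


def bruteforce_dtf(H):
    """DTF^2 cube [source, target, freq] from a stacked transfer matrix."""
    F, n, _ = H.shape
    out = np.zeros((n, n, F))
    for fi in range(F):
        for t in range(n):
            denom = sum(abs(H[fi, t, m]) ** 2 for m in range(n))
            for s in range(n):
                out[s, t, fi] = abs(H[fi, t, s]) ** 2 / denom
    return out


def bruteforce_pdc(Abar):
    """PDC magnitude cube [source, target, freq]."""
    F, n, _ = Abar.shape
    out = np.zeros((n, n, F))
    for fi in range(F):
        for s in range(n):
            norm = np.sqrt(sum(abs(Abar[fi, i, s]) ** 2 for i in range(n)))
            for t in range(n):
                out[s, t, fi] = abs(Abar[fi, t, s]) / norm
    return out


def bruteforce_gc(H, S, C):
    """Pairwise Geweke spectral GC cube [source, target, freq]."""
    F, n, _ = H.shape
    out = np.zeros((n, n, F))
    for fi in range(F):
        for s in range(n):
            for t in range(n):
                if s == t:
                    continue
                cond = C[s, s] - C[t, s] ** 2 / C[t, t]
                denom = S[fi, t, t].real - cond * abs(H[fi, t, s]) ** 2
                out[s, t, fi] = max(0.0, np.log(S[fi, t, t].real / denom))
    return out
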