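"""Time-frequency measures and permutation statistics.

ERSP/ITC use fixed 5-cycle complex Morlet wavelets on a log-spaced 3-40 Hz
grid.  ERSP is 10*log10(power / mean baseline power), averaged over epochs;
ITC is the resultant length of the per-epoch unit phase vectors.  Pointwise
significance uses sign-flip permutation of paired differences (paired t) or
within-unit label permutation (one-way repeated-measures ANOVA), followed by
Benjamini-Hochberg FDR masking.  With 2000 permutations the smallest
attainable p is 1/2001.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal as sps

from .errors import ParameterError
from .preprocess import EpochSet

N_CYCLES = 5.0
DEFAULT_FREQS = np.logspace(np.log10(3.0), np.log10(40.0), 30)


@dataclass
class TFMap:
    freqs_hz: np.ndarray
    times_ms: np.ndarray
    values: np.ndarray            # freqs x times
    kind: str                     # "ersp" (dB) | "itc" ([0, 1])
    baseline_ms: tuple[float, float] | None = None


@dataclass
class SignificanceMask:
    mask: np.ndarray              # bool, same shape as the tested grid
    pvals: np.ndarray
    alpha: float
    n_permutations: int
    method: str


def _morlet_kernel(freq: float, srate: float) -> np.ndarray:
    sigma_t = N_CYCLES / (2 * np.pi * freq)
    half = int(np.ceil(4 * sigma_t * srate))
    t = np.arange(-half, half + 1) / srate
    kernel = np.exp(2j * np.pi * freq * t) * np.exp(-t ** 2 / (2 * sigma_t ** 2))
    return kernel / np.abs(kernel).sum() * 2.0


def wavelet_transform(data: np.ndarray, srate: float,
                      freqs: np.ndarray) -> np.ndarray:
    """Complex Morlet coefficients: (epochs, freqs, times) for 2-D input
    (epochs x times)."""
    data = np.atleast_2d(data)
    out = np.empty((data.shape[0], len(freqs), data.shape[1]),
                   dtype=complex)
    for fi, f in enumerate(freqs):
        k = _morlet_kernel(f, srate)
        for ei in range(data.shape[0]):
            out[ei, fi] = sps.fftconvolve(data[ei], k, mode="same")
    return out


def ersp(epochs: EpochSet, channel: str,
         freqs: np.ndarray | None = None,
         baseline_ms: tuple[float, float] = (-400.0, -100.0)) -> TFMap:
    """Baseline-normalized spectral power change in dB."""
    freqs = DEFAULT_FREQS if freqs is None else np.asarray(freqs, float)
    if freqs.max() > epochs.srate_hz / 2:
        raise ParameterError("frequency above Nyquist")
    lo, hi = baseline_ms
    bmask = (epochs.times_ms >= lo) & (epochs.times_ms <= hi)
    if not bmask.any():
        raise ParameterError("baseline window outside epoch")
    ci = epochs.channel_index(channel)
    coef = wavelet_transform(epochs.data[:, ci, :], epochs.srate_hz, freqs)
    power = (np.abs(coef) ** 2).mean(axis=0)          # freqs x times
    base = power[:, bmask].mean(axis=1, keepdims=True)
    vals = 10.0 * np.log10(power / base)
    return TFMap(freqs, epochs.times_ms, vals, "ersp", baseline_ms)


def itc(epochs: EpochSet, channel: str,
        freqs: np.ndarray | None = None) -> TFMap:
    """Inter-trial coherence: resultant length of unit phase vectors."""
    freqs = DEFAULT_FREQS if freqs is None else np.asarray(freqs, float)
    if epochs.n_epochs < 2:
        import warnings
        warnings.warn("single epoch: ITC is degenerately 1 everywhere")
    ci = epochs.channel_index(channel)
    coef = wavelet_transform(epochs.data[:, ci, :], epochs.srate_hz, freqs)
    phases = coef / np.maximum(np.abs(coef), 1e-30)
    vals = np.abs(phases.mean(axis=0))
    return TFMap(freqs, epochs.times_ms, vals, "itc")


def power_spectrum(epochs: EpochSet, channel: str,
                   nperseg: int | None = None) -> tuple[np.ndarray, np.ndarray]:
    """Welch periodogram averaged over epochs -> (freqs_hz, power)."""
    ci = epochs.channel_index(channel)
    data = epochs.data[:, ci, :]
    if nperseg is None:
        nperseg = min(data.shape[1], int(epochs.srate_hz * 2))
    f, p = sps.welch(data, fs=epochs.srate_hz, nperseg=nperseg, axis=1)
    return f, p.mean(axis=0)


# ---------------------------------------------------------------------------
# Permutation statistics

def _tstat_paired(diff: np.ndarray) -> np.ndarray:
    n = diff.shape[0]
    m = diff.mean(axis=0)
    se = diff.std(axis=0, ddof=1) / np.sqrt(n)
    return m / np.maximum(se, 1e-30)


def perm_paired_test(data_a: np.ndarray, data_b: np.ndarray,
                     n_perm: int = 2000, seed: int = 0) -> np.ndarray:
    """Two-sided sign-flip permutation p-values per point.

    ``data_a``/``data_b`` are (units, points...) arrays paired on axis 0.
    """
    a, b = np.asarray(data_a, float), np.asarray(data_b, float)
    if a.shape != b.shape:
        raise ParameterError("paired inputs must have identical shapes")
    if a.shape[0] < 5:
        raise ParameterError("need >= 5 paired units")
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    rng = np.random.default_rng(seed)
    diff = a - b
    flat = diff.reshape(diff.shape[0], -1)
    t_obs = np.abs(_tstat_paired(flat))
    count = np.zeros(flat.shape[1])
    for _ in range(n_perm):
        signs = rng.choice([-1.0, 1.0], size=(flat.shape[0], 1))
        count += np.abs(_tstat_paired(flat * signs)) >= t_obs
    p = (count + 1.0) / (n_perm + 1.0)
    return p.reshape(diff.shape[1:]) if diff.ndim > 1 else p


def _fstat_rm(data: np.ndarray) -> np.ndarray:
    """Repeated-measures one-way F per point; data (units, k, points)."""
    n, k = data.shape[0], data.shape[1]
    grand = data.mean(axis=(0, 1))
    cond_m = data.mean(axis=0)                  # k x points
    subj_m = data.mean(axis=1)                  # n x points
    ss_cond = n * ((cond_m - grand) ** 2).sum(axis=0)
    resid = data - cond_m[None] - subj_m[:, None, :] + grand
    ss_err = (resid ** 2).sum(axis=(0, 1))
    df_cond, df_err = k - 1, (n - 1) * (k - 1)
    return (ss_cond / df_cond) / np.maximum(ss_err / df_err, 1e-30)


def perm_rm_anova(conditions: np.ndarray, n_perm: int = 2000,
                  seed: int = 0) -> np.ndarray:
    """One-way repeated-measures ANOVA with within-unit label permutation.

    ``conditions`` is (units, k, points...) with k >= 3.
    """
    data = np.asarray(conditions, float)
    if data.ndim < 2 or data.shape[1] < 3:
        raise ParameterError("need k >= 3 conditions; use the paired test "
                             "for k = 2")
    if n_perm < 1:
        raise ParameterError("n_perm must be >= 1")
    if data.ndim == 2:
        data = data[:, :, None]
    orig_shape = data.shape[2:]
    flat = data.reshape(data.shape[0], data.shape[1], -1)
    rng = np.random.default_rng(seed)
    f_obs = _fstat_rm(flat)
    count = np.zeros(flat.shape[2])
    n, k = flat.shape[0], flat.shape[1]
    for _ in range(n_perm):
        perm = np.empty_like(flat)
        for u in range(n):
            perm[u] = flat[u, rng.permutation(k)]
        count += _fstat_rm(perm) >= f_obs
    p = (count + 1.0) / (n_perm + 1.0)
    return p.reshape(orig_shape) if orig_shape else p


def fdr_bh(pvals: np.ndarray, q: float = 0.05) -> SignificanceMask:
    """Benjamini-Hochberg step-up mask over a p-value grid."""
    p = np.asarray(pvals, float)
    if p.size == 0:
        raise ParameterError("empty p-value input")
    if (p < 0).any() or (p > 1).any():
        raise ParameterError("p-values must lie in [0, 1]")
    flat = p.ravel()
    m = flat.size
    order = np.argsort(flat)
    ranked = flat[order]
    thresh = q * (np.arange(1, m + 1)) / m
    passing = np.flatnonzero(ranked <= thresh)
    mask = np.zeros(m, dtype=bool)
    if passing.size:
        mask[order[: passing.max() + 1]] = True
    return SignificanceMask(mask=mask.reshape(p.shape), pvals=p, alpha=q,
                            n_permutations=0, method="fdr_bh")
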