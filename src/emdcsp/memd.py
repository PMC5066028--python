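"""Multivariate empirical mode decomposition and rhythm-band assignment.

Implements the standard multivariate sifting scheme: the multichannel signal
is projected onto a set of low-discrepancy direction vectors on the unit
hypersphere; for each direction the signal values at the projection's
extrema are interpolated with natural cubic splines (mirror boundary), and
the mean of the upper/lower envelopes over all directions drives the sift.
A Rilling-style three-parameter stopping rule terminates each sift.

The noise-assisted variant appends white Gaussian noise channels before
sifting and discards their modes afterwards, stabilizing the dyadic mode
alignment.

Modes are numbered 1-based, fastest first, matching the usual IMF indexing
convention.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy.interpolate import CubicSpline
from scipy.special import ndtri

from .data import DataError

__all__ = [
    "SiftConfig",
    "IMFSet",
    "SpectrumTable",
    "RhythmAssignment",
    "SelectionError",
    "ConfigurationError",
    "direction_vectors",
    "memd_decompose",
    "na_memd_decompose",
    "periodogram_bartlett",
    "select_rhythm_imfs",
    "reconstruct_band",
]

MU_BAND = (8.0, 13.0)
BETA_BAND = (13.0, 25.0)


class ConfigurationError(ValueError):
    """Invalid sifting or spectrum configuration."""


class SelectionError(RuntimeError):
    """Automated rhythm assignment failed; carries diagnostic spectra."""

    def __init__(self, message: str, spectra: "SpectrumTable | None" = None):
        super().__init__(message)
        self.spectra = spectra


@dataclass(frozen=True)
class SiftConfig:
    """Sifting parameters.

    ``stop_thresholds`` is the (theta1, theta2, alpha) triple of the
    three-parameter stopping rule: sifting stops once the normalized mean
    envelope is below theta1 on at least (1 - alpha) of the samples and
    below theta2 everywhere.
    """

    n_directions: int = 64
    max_imfs: int = 11
    stop_thresholds: tuple[float, float, float] = (0.05, 0.5, 0.05)
    max_sift_iters: int = 100
    envelope_interp: str = "cubic_spline"
    boundary: str = "mirror"

    def __post_init__(self) -> None:
        if any(t <= 0 for t in self.stop_thresholds):
            raise ConfigurationError("stop thresholds must be positive")
        if self.envelope_interp != "cubic_spline":
            raise ConfigurationError("only cubic_spline envelopes are supported")
        if self.boundary != "mirror":
            raise ConfigurationError("only mirror boundary handling is supported")
        if self.max_imfs < 1 or self.max_sift_iters < 1:
            raise ConfigurationError("max_imfs and max_sift_iters must be >= 1")


@dataclass
class IMFSet:
    """Ordered intrinsic mode functions for one trial.

    ``imfs`` has shape (n_modes, n_channels, n_samples); mode k (1-based)
    is ``imfs[k - 1]``.  The completeness identity
    ``input = imfs.sum(axis=0) + residue`` holds to floating precision.
    """

    imfs: np.ndarray
    residue: np.ndarray
    fs: float
    trial_id: int | None = None

    @property
    def n_modes(self) -> int:
        return self.imfs.shape[0]

    @property
    def n_channels(self) -> int:
        return self.residue.shape[0]

    def reconstruct(self) -> np.ndarray:
        if self.n_modes == 0:
            return self.residue.copy()
        return self.imfs.sum(axis=0) + self.residue


@dataclass
class SpectrumTable:
    """Bartlett-periodogram power per mode on a common frequency grid."""

    freqs: np.ndarray
    power: np.ndarray  # (n_modes, n_freqs)
    window: str = "bartlett"
    nfft: int = 0

    def band_fraction(self, mode: int, band: tuple[float, float]) -> float:
        """Fraction of mode's total power inside ``band`` (1-based mode)."""
        p = self.power[mode - 1]
        total = p.sum()
        if total <= 0:
            return 0.0
        mask = (self.freqs >= band[0]) & (self.freqs < band[1])
        return float(p[mask].sum() / total)


@dataclass(frozen=True)
class RhythmAssignment:
    """Disjoint 1-based mode index sets for the mu and beta rhythms."""

    mu_modes: frozenset[int]
    beta_modes: frozenset[int]

    def __post_init__(self) -> None:
        if self.mu_modes & self.beta_modes:
            raise ValueError("mu and beta mode sets must be disjoint")


# ---------------------------------------------------------------------------
# direction vectors

_PRIMES = (2, 3, 5, 7, 11, 13, 17, 19, 23, 29, 31, 37, 41, 43, 47, 53, 59,
           61, 67, 71, 73, 79, 83, 89, 97, 101, 103, 107, 109, 113)


def _van_der_corput(n: int, base: int) -> np.ndarray:
    seq = np.zeros(n)
    for i in range(n):
        x, denom, k = 0.0, 1.0, i + 1
        while k > 0:
            denom *= base
            k, rem = divmod(k, base)
            x += rem / denom
        seq[i] = x
    return seq


def direction_vectors(n_directions: int, dim: int) -> np.ndarray:
    """Low-discrepancy (Hammersley) points on the unit hypersphere.

    Hammersley points in the unit hypercube are pushed through the inverse
    normal CDF and normalized, yielding well-spread unit vectors in any
    dimension.
    """
    if dim < 2:
        raise ConfigurationError("direction vectors need dimension >= 2")
    if dim - 1 > len(_PRIMES):
        raise ConfigurationError(f"dimension {dim} unsupported (too many channels)")
    pts = np.empty((n_directions, dim))
    pts[:, 0] = (np.arange(n_directions) + 0.5) / n_directions
    for j in range(1, dim):
        pts[:, j] = _van_der_corput(n_directions, _PRIMES[j - 1])
    eps = 1e-10
    g = ndtri(np.clip(pts, eps, 1 - eps))
    return g / np.linalg.norm(g, axis=1, keepdims=True)


# ---------------------------------------------------------------------------
# envelopes and sifting

def _local_extrema(p: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Indices of strict local maxima and minima of a 1-D series."""
    d = np.sign(np.diff(p))
    # collapse plateau zeros to the preceding slope sign
    for i in range(1, d.size):
        if d[i] == 0:
            d[i] = d[i - 1]
    turn = np.diff(d)
    imax = np.flatnonzero(turn < 0) + 1
    imin = np.flatnonzero(turn > 0) + 1
    return imax, imin


def _mirror_extend(idx: np.ndarray, vals: np.ndarray, n: int) -> tuple[np.ndarray, np.ndarray]:
    """Mirror up to two extrema beyond each boundary to anchor the spline."""
    k = min(2, idx.size)
    left_idx = (-idx[:k])[::-1]
    left_vals = vals[:k][::-1]
    right_idx = (2 * (n - 1) - idx[-k:])[::-1]
    right_vals = vals[-k:][::-1]
    xi = np.concatenate([left_idx, idx, right_idx])
    vi = np.concatenate([left_vals, vals, right_vals], axis=0)
    keep = np.concatenate([[True], np.diff(xi) > 0])
    return xi[keep], vi[keep]


def _vector_envelopes(x: np.ndarray, dirs: np.ndarray):
    """Mean envelope and mean envelope amplitude over all directions.

    Returns ``(mean_env, amplitude, n_usable)`` or ``None`` when no
    direction has enough extrema (monotone residue).
    """
    n_ch, n = x.shape
    grid = np.arange(n)
    acc = np.zeros((n, n_ch))
    amp = np.zeros(n)
    usable = 0
    proj = dirs @ x  # (n_dirs, n)
    for d in range(dirs.shape[0]):
        imax, imin = _local_extrema(proj[d])
        if imax.size < 2 or imin.size < 2:
            continue
        xi, vi = _mirror_extend(imax, x[:, imax].T, n)
        upper = CubicSpline(xi, vi, bc_type="natural")(grid)
        xi, vi = _mirror_extend(imin, x[:, imin].T, n)
        lower = CubicSpline(xi, vi, bc_type="natural")(grid)
        acc += 0.5 * (upper + lower)
        # scalar envelope of the projection = projection of the vector envelope
        amp += 0.5 * np.abs((upper - lower) @ dirs[d])
        usable += 1
    if usable == 0:
        return None
    return (acc / usable).T, amp / usable, usable


def _sift_one_imf(x: np.ndarray, dirs: np.ndarray, cfg: SiftConfig) -> np.ndarray | None:
    """Extract a single IMF from ``x``; None if ``x`` is already a residue."""
    theta1, theta2, alpha = cfg.stop_thresholds
    h = x.copy()
    env = _vector_envelopes(h, dirs)
    if env is None:
        return None
    for _ in range(cfg.max_sift_iters):
        mean_env, amp, _ = env
        sx = np.linalg.norm(mean_env, axis=0)
        safe_amp = np.where(amp > 1e-12 * max(sx.max(), 1e-300), amp, np.inf)
        ratio = sx / safe_amp
        if (ratio > theta1).mean() <= alpha and not (ratio > theta2).any():
            return h
        h -= mean_env.astype(h.dtype)
        env = _vector_envelopes(h, dirs)
        if env is None:
            return h
    return h


def memd_decompose(trial: np.ndarray, cfg: SiftConfig | None = None,
                   fs: float = 1.0, trial_id: int | None = None) -> IMFSet:
    """Decompose a (channel x sample) trial into aligned multivariate IMFs.

    All channels share the same number of modes by construction.  The sum of
    all modes plus the residue reconstructs the input to floating precision.
    """
    cfg = cfg or SiftConfig()
    x = np.asarray(trial, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2:
        raise DataError(f"expected (channels >= 2, samples) input; got shape {x.shape}")
    if x.shape[1] < 64:
        raise DataError(f"need at least 64 samples; got {x.shape[1]}")
    if not np.isfinite(x).all():
        raise DataError("non-finite values in input")
    n_ch = x.shape[0]
    n_dirs = max(cfg.n_directions, 2 * n_ch)
    dirs = direction_vectors(n_dirs, n_ch)

    residue = x.copy()
    imfs: list[np.ndarray] = []
    while len(imfs) < cfg.max_imfs:
        imf = _sift_one_imf(residue, dirs, cfg)
        if imf is None:
            break
        imfs.append(imf)
        residue = residue - imf
    imf_arr = np.stack(imfs) if imfs else np.zeros((0,) + x.shape)
    # enforce exact completeness: residue is the leftover by construction
    return IMFSet(imfs=imf_arr, residue=x - imf_arr.sum(axis=0), fs=fs,
                  trial_id=trial_id)


def na_memd_decompose(trial: np.ndarray, cfg: SiftConfig | None = None,
                      noise_sd: float = 0.02, n_noise_channels: int = 1,
                      seed: int = 0, fs: float = 1.0,
                      trial_id: int | None = None) -> IMFSet:
    """Noise-assisted MEMD: sift with appended white-noise channels, then
    discard the noise channels' modes.  Deterministic given ``seed``."""
    if noise_sd <= 0:
        raise ConfigurationError("noise_sd must be positive for noise assistance")
    if n_noise_channels < 1:
        raise ConfigurationError("need at least one noise channel")
    x = np.asarray(trial, dtype=float)
    if x.ndim != 2:
        raise DataError(f"expected (channels, samples); got {x.shape}")
    rng = np.random.default_rng(seed)
    noise = noise_sd * rng.standard_normal((n_noise_channels, x.shape[1]))
    augmented = np.vstack([x, noise])
    full = memd_decompose(augmented, cfg, fs=fs, trial_id=trial_id)
    n_ch = x.shape[0]
    return IMFSet(imfs=full.imfs[:, :n_ch, :], residue=full.residue[:n_ch, :],
                  fs=fs, trial_id=trial_id)


# ---------------------------------------------------------------------------
# spectra and rhythm assignment

def periodogram_bartlett(series: np.ndarray, nfft: int | None = None,
                         window_len: int | None = None,
                         fs: float = 1.0) -> tuple[np.ndarray, np.ndarray]:
    """Bartlett-window periodogram with exact Parseval normalization.

    When ``window_len`` is shorter than the series, non-overlapping windowed
    segments are averaged (Bartlett's method).  The returned power satisfies
    ``power.sum() == mean(windowed_segment ** 2)`` (averaged over segments).
    """
    x = np.asarray(series, dtype=float)
    if x.ndim != 1:
        raise DataError("series must be 1-D")
    n = x.size
    window_len = window_len or n
    nfft = nfft or window_len
    if window_len > n:
        raise ConfigurationError(f"window_len {window_len} > series length {n}")
    if nfft < window_len:
        raise ConfigurationError(f"nfft {nfft} < window_len {window_len}")
    w = np.bartlett(window_len)
    n_seg = n // window_len
    power = np.zeros(nfft // 2 + 1)
    for s in range(n_seg):
        xw = x[s * window_len:(s + 1) * window_len] * w
        spec = np.fft.rfft(xw, nfft)
        p = np.abs(spec) ** 2
        # fold negative frequencies so the sum obeys Parseval
        p[1:] *= 2.0
        if nfft % 2 == 0:
            p[-1] /= 2.0
        power += p / (nfft * window_len)
    power /= n_seg
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    return freqs, power


def mode_spectra(imfsets: Sequence[IMFSet], nfft: int | None = None,
                 window_len: int | None = None) -> SpectrumTable:
    """Average the Bartlett periodogram of each mode over trials and channels."""
    if not imfsets:
        raise DataError("empty IMFSet collection")
    n_modes = min(s.n_modes for s in imfsets)
    if n_modes == 0:
        raise DataError("IMFSets contain no modes")
    fs = imfsets[0].fs
    n = imfsets[0].imfs.shape[2]
    nfft = nfft or n
    window_len = window_len or n
    freqs = np.fft.rfftfreq(nfft, d=1.0 / fs)
    power = np.zeros((n_modes, freqs.size))
    count = 0
    for s in imfsets:
        for k in range(n_modes):
            for ch in range(s.n_channels):
                _, p = periodogram_bartlett(s.imfs[k, ch], nfft=nfft,
                                            window_len=window_len, fs=fs)
                power[k] += p
        count += s.n_channels
    power /= count
    return SpectrumTable(freqs=freqs, power=power, nfft=nfft)


def select_rhythm_imfs(imfset_population: Sequence[IMFSet],
                       mu_band: tuple[float, float] = MU_BAND,
                       beta_band: tuple[float, float] = BETA_BAND,
                       policy: str = "auto") -> RhythmAssignment:
    """Assign modes to the mu and beta rhythms.

    ``fixed`` policy uses the conventional assignment mu = {4},
    beta = {2, 3} and requires at least 4 modes everywhere.  ``auto``
    averages each mode's spectrum over the population and assigns it to the
    band holding the largest fraction of its power; modes dominated by
    out-of-band power are left unassigned.
    """
    if policy == "fixed":
        if min(s.n_modes for s in imfset_population) < 4:
            raise SelectionError("fixed policy requires >= 4 modes in every IMFSet")
        return RhythmAssignment(mu_modes=frozenset({4}), beta_modes=frozenset({2, 3}))
    if policy != "auto":
        raise ConfigurationError(f"unknown policy {policy!r}")

    table = mode_spectra(imfset_population)
    mu, beta = set(), set()
    for mode in range(1, table.power.shape[0] + 1):
        f_mu = table.band_fraction(mode, mu_band)
        f_beta = table.band_fraction(mode, beta_band)
        f_out = 1.0 - f_mu - f_beta
        best = max(f_mu, f_beta, f_out)
        if best == f_out:
            continue
        (mu if f_mu >= f_beta else beta).add(mode)
    if not mu or not beta:
        raise SelectionError(
            f"auto assignment left a band empty (mu={sorted(mu)}, beta={sorted(beta)})",
            spectra=table,
        )
    return RhythmAssignment(mu_modes=frozenset(mu), beta_modes=frozenset(beta))


def reconstruct_band(imfset: IMFSet, modes: Iterable[int]) -> np.ndarray:
    """Partial sum of the selected (1-based) modes; empty set gives zeros."""
    modes = sorted(set(modes))
    out = np.zeros_like(imfset.residue)
    for m in modes:
        if not 1 <= m <= imfset.n_modes:
            raise DataError(f"mode {m} out of range 1..{imfset.n_modes}")
        out += imfset.imfs[m - 1]
    return out
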