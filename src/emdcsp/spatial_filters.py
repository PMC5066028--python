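"""The CSP family: real CSP, complex CSP, and the strong-uncorrelating-
transform complex CSP (SUTCCSP).

The complex construction places the mu-band series in the real part and the
beta-band series in the imaginary part of each trial, so the covariance
carries the mu + beta power sum while the pseudocovariance carries the
mu - beta power difference and the cross-correlation.  SUTCCSP whitens the
composite covariance, Takagi-factorizes the whitened composite
pseudocovariance, and derives two filter banks:

* ``W``  — diagonalizes the per-class covariances (power-sum route);
* ``W_hat`` — diagonalizes the per-class pseudocovariances (power-difference
  route), available only for the SUTCCSP variant.

Takagi factorization of a complex symmetric matrix P is computed through
the real symmetric embedding K = [[Re P, Im P], [Im P, -Re P]]: each
eigenpair (sigma, (x, y)) of K with sigma > 0 yields a con-eigenvector
u = x + i y with P conj(u) = sigma u, which is exactly a column of the
Takagi factor.  Zero singular values are completed from the orthogonal
complement.  This handles degenerate singular-value clusters without any
phase-correction heuristics.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import scipy.linalg

from .data import DataError, EEGTrialSet

__all__ = [
    "FittingError",
    "DegenerateInputError",
    "ComplexTrialSet",
    "ClassCovariances",
    "WhiteningTransform",
    "TakagiFactors",
    "SUTTransform",
    "FilterBank",
    "build_complex_trials",
    "build_real_trials",
    "estimate_class_covariances",
    "whiten",
    "takagi_factorize",
    "compute_sut",
    "csp_fit",
    "ccsp_fit",
    "sutccsp_fit",
    "apply_filters",
    "save_filterbank",
    "load_filterbank",
]


class FittingError(ValueError):
    """Raised when a filter bank cannot be fitted from the given trials."""


class DegenerateInputError(ValueError):
    """Raised for degenerate matrix inputs (e.g. the zero matrix)."""


# ---------------------------------------------------------------------------
# trial containers


@dataclass
class ComplexTrialSet:
    """Complex-valued trials z = mu + i * beta, zero-mean per channel."""

    data: np.ndarray  # (trial, channel, sample) complex
    labels: np.ndarray
    channel_names: list[str] | None = None

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=complex)
        self.labels = np.asarray(self.labels, dtype=str)
        if self.data.ndim != 3:
            raise DataError(f"expected (trial, channel, sample); got {self.data.shape}")
        if self.labels.shape[0] != self.data.shape[0]:
            raise DataError("label count does not match trial count")

    @property
    def n_channels(self) -> int:
        return self.data.shape[1]

    def class_indices(self, label: str) -> np.ndarray:
        return np.flatnonzero(self.labels == label)

    def select(self, idx) -> "ComplexTrialSet":
        idx = np.asarray(idx, dtype=int)
        return ComplexTrialSet(self.data[idx], self.labels[idx], self.channel_names)


def _center(series: np.ndarray) -> np.ndarray:
    return series - series.mean(axis=-1, keepdims=True)


def build_complex_trials(mu: np.ndarray, beta: np.ndarray, labels,
                         channel_names=None) -> ComplexTrialSet:
    """Combine mu/beta band series into complex trials (both parts centered)."""
    mu = np.asarray(mu, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if mu.shape != beta.shape:
        raise DataError(f"mu shape {mu.shape} != beta shape {beta.shape}")
    if mu.ndim != 3:
        raise DataError(f"expected (trial, channel, sample); got {mu.shape}")
    data = _center(mu) + 1j * _center(beta)
    return ComplexTrialSet(data=data, labels=np.asarray(labels, dtype=str),
                           channel_names=channel_names)


def build_real_trials(mu: np.ndarray, beta: np.ndarray, labels, fs: float = 1.0,
                      channel_names=None) -> EEGTrialSet:
    """Summed real series mu + beta (the classical-CSP input), centered."""
    mu = np.asarray(mu, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if mu.shape != beta.shape:
        raise DataError(f"mu shape {mu.shape} != beta shape {beta.shape}")
    data = _center(mu) + _center(beta)
    names = channel_names if channel_names is not None else \
        [f"ch{i}" for i in range(mu.shape[1])]
    return EEGTrialSet(data=data, labels=np.asarray(labels, dtype=str),
                       channel_names=names, fs=fs)


# ---------------------------------------------------------------------------
# covariance estimation


@dataclass
class ClassCovariances:
    """Per-class covariance / pseudocovariance averages and their composites."""

    C_L: np.ndarray
    C_R: np.ndarray
    P_L: np.ndarray
    P_R: np.ndarray
    n_trials_per_class: dict[str, int]

    @property
    def C_c(self) -> np.ndarray:
        return self.C_L + self.C_R

    @property
    def P_c(self) -> np.ndarray:
        return self.P_L + self.P_R


def estimate_class_covariances(trials: ComplexTrialSet,
                               normalization: str = "trace") -> ClassCovariances:
    """Average per-trial covariance E[AA^H]/S and pseudocovariance E[AA^T]/S
    within each class.

    With ``normalization="trace"`` both matrices of a trial are divided by
    the trace of that trial's covariance (one shared scale, keeping the
    covariance/pseudocovariance pair consistent).
    """
    if normalization not in ("trace", "none"):
        raise FittingError(f"unknown normalization {normalization!r}")
    out: dict[str, list[np.ndarray]] = {}
    counts: dict[str, int] = {}
    for label in ("L", "R"):
        idx = trials.class_indices(label)
        if idx.size < 2:
            raise FittingError(f"class {label!r} has {idx.size} trials; need >= 2")
        counts[label] = int(idx.size)
        C_acc = np.zeros((trials.n_channels, trials.n_channels), dtype=complex)
        P_acc = np.zeros_like(C_acc)
        for t in idx:
            A = trials.data[t]
            S = A.shape[1]
            C_t = A @ A.conj().T / S
            P_t = A @ A.T / S
            if normalization == "trace":
                scale = float(np.trace(C_t).real)
                if scale <= 0:
                    raise FittingError(f"trial {t} has zero power")
                C_t = C_t / scale
                P_t = P_t / scale
            C_acc += C_t
            P_acc += P_t
        C = C_acc / idx.size
        P = P_acc / idx.size
        out[label] = [0.5 * (C + C.conj().T), 0.5 * (P + P.T)]
    return ClassCovariances(C_L=out["L"][0], C_R=out["R"][0],
                            P_L=out["L"][1], P_R=out["R"][1],
                            n_trials_per_class=counts)


# ---------------------------------------------------------------------------
# whitening


@dataclass
class WhiteningTransform:
    """Eigen-based whitening G of a Hermitian PSD composite covariance."""

    U_c: np.ndarray
    lambda_c: np.ndarray
    G: np.ndarray  # (rank, n)
    rank_tol: float

    @property
    def rank(self) -> int:
        return self.G.shape[0]


def whiten(C_c: np.ndarray, rank_tol: float = 1e-10) -> WhiteningTransform:
    """Whiten a Hermitian PSD matrix: G C_c G^H = I on the retained subspace.

    Eigenvalues below ``rank_tol`` times the largest are dropped.  A tiny
    ridge is added when the matrix is catastrophically ill conditioned.
    """
    C = np.asarray(C_c, dtype=complex)
    if C.ndim != 2 or C.shape[0] != C.shape[1]:
        raise DataError(f"expected a square matrix; got {C.shape}")
    herm_err = np.linalg.norm(C - C.conj().T) / max(1.0, np.linalg.norm(C))
    if herm_err > 1e-8:
        raise DataError(f"matrix is not Hermitian (relative error {herm_err:.2e})")
    C = 0.5 * (C + C.conj().T)
    if not np.any(C):
        raise DegenerateInputError("cannot whiten the zero matrix")
    n = C.shape[0]
    vals, vecs = np.linalg.eigh(C)
    pos = vals[vals > 0]
    if pos.size and pos.max() / max(pos.min(), 1e-300) > 1e12:
        C = C + (1e-10 * np.trace(C).real / n) * np.eye(n)
        vals, vecs = np.linalg.eigh(C)
    order = np.argsort(vals)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    keep = vals > rank_tol * vals[0]
    vals, vecs = vals[keep], vecs[:, keep]
    G = (vals[:, None] ** -0.5) * vecs.conj().T
    if np.isrealobj(np.asarray(C_c)):
        G = G.real.astype(complex)
    return WhiteningTransform(U_c=vecs, lambda_c=vals, G=G, rank_tol=rank_tol)


# ---------------------------------------------------------------------------
# Takagi factorization


@dataclass
class TakagiFactors:
    """Takagi factorization target = Y diag(lam) Y^T with unitary Y and
    real nonnegative descending lam."""

    Y: np.ndarray
    lam: np.ndarray
    target: np.ndarray


def _fix_column_signs(M: np.ndarray) -> np.ndarray:
    """Flip column signs so the largest-magnitude entry has nonnegative real
    part (imaginary part breaking ties).  Sign flips preserve Y Lam Y^T."""
    M = M.copy()
    for j in range(M.shape[1]):
        k = int(np.argmax(np.abs(M[:, j])))
        v = M[k, j]
        if v.real < 0 or (v.real == 0 and v.imag < 0):
            M[:, j] = -M[:, j]
    return M


def takagi_factorize(P_sym: np.ndarray, sym_tol: float = 1e-8) -> TakagiFactors:
    """Takagi-factorize a complex symmetric matrix via the real embedding.

    Degenerate singular-value clusters are handled naturally: within a
    cluster the real eigenvectors of the embedding are automatically
    complex-orthonormal, and exact zeros are completed from the orthogonal
    complement of the positive-singular-value columns.
    """
    P = np.asarray(P_sym, dtype=complex)
    if P.ndim != 2 or P.shape[0] != P.shape[1]:
        raise DataError(f"expected a square matrix; got {P.shape}")
    asym = np.linalg.norm(P - P.T) / max(1.0, np.linalg.norm(P))
    if asym > sym_tol:
        raise DataError(f"matrix is not symmetric (relative asymmetry {asym:.2e})")
    P = 0.5 * (P + P.T)
    n = P.shape[0]
    A, B = P.real, P.imag
    K = np.block([[A, B], [B, -A]])
    w, V = np.linalg.eigh(K)
    order = np.argsort(w)[::-1]
    w, V = w[order], V[:, order]
    cutoff = 1e-12 * max(1.0, abs(w[0]) if w.size else 1.0)
    pos = np.flatnonzero(w > cutoff)[:n]
    U_pos = V[:n, pos] + 1j * V[n:, pos]
    lam = w[pos].copy()
    r = U_pos.shape[1]
    if r < n:
        # complete with an orthonormal basis of null(P^H): P conj(v) = 0 there
        null = scipy.linalg.null_space(U_pos.conj().T) if r else np.eye(n, dtype=complex)
        Y = np.hstack([U_pos, null[:, : n - r]])
        lam = np.concatenate([lam, np.zeros(n - r)])
    else:
        Y = U_pos
    Y = _fix_column_signs(Y)
    return TakagiFactors(Y=Y, lam=lam, target=P)


# ---------------------------------------------------------------------------
# strong uncorrelating transform


@dataclass
class SUTTransform:
    """SUT pair: Q whitens the covariance and diagonalizes the
    pseudocovariance; Q_hat additionally whitens the pseudocovariance."""

    Q: np.ndarray
    Q_hat: np.ndarray
    lam: np.ndarray


def compute_sut(white: WhiteningTransform, tak: TakagiFactors,
                lam_tol: float = 1e-10) -> SUTTransform:
    """Combine whitening and Takagi factors into the SUT pair."""
    Q = tak.Y.conj().T @ white.G
    lam = tak.lam
    small = lam <= lam_tol * max(1.0, lam.max() if lam.size else 1.0)
    if small.any():
        warnings.warn(
            f"{int(small.sum())} near-zero pseudocovariance singular values: "
            "data is (close to) circular; using pseudo-inverse square root",
            RuntimeWarning, stacklevel=2,
        )
    inv_sqrt = np.where(small, 0.0, 1.0 / np.sqrt(np.where(small, 1.0, lam)))
    Q_hat = inv_sqrt[:, None] * Q
    return SUTTransform(Q=Q, Q_hat=Q_hat, lam=lam)


# ---------------------------------------------------------------------------
# filter banks


@dataclass
class FilterBank:
    """Fitted spatial filters.

    ``W`` rows are covariance-route filters ordered by descending class-L
    eigenvalue; ``W_hat`` (SUTCCSP only) are the pseudocovariance-route
    filters.  ``diagnostics`` records the residuals of the internal
    identity checks.
    """

    W: np.ndarray
    W_hat: np.ndarray | None
    eigvals: np.ndarray          # class-L covariance-route eigenvalues
    eigvals_hat: np.ndarray | None
    variant: str
    channel_names: list[str] | None = None
    rank: int = 0
    diagnostics: dict[str, float] = field(default_factory=dict)

    @property
    def n_components(self) -> int:
        return self.W.shape[0]


def save_filterbank(path, bank: FilterBank):
    """Lossless single-file serialization of a fitted bank."""
    payload = {
        "W": bank.W,
        "eigvals": bank.eigvals,
        "variant": np.asarray(bank.variant),
        "rank": np.asarray(bank.rank),
        "channel_names": np.asarray(bank.channel_names or [], dtype="U16"),
    }
    if bank.W_hat is not None:
        payload["W_hat"] = bank.W_hat
        payload["eigvals_hat"] = bank.eigvals_hat
    np.savez(path, **payload)
    return path


def load_filterbank(path) -> FilterBank:
    with np.load(path, allow_pickle=False) as npz:
        names = [str(c) for c in npz["channel_names"]]
        return FilterBank(
            W=npz["W"],
            W_hat=npz["W_hat"] if "W_hat" in npz.files else None,
            eigvals=npz["eigvals"],
            eigvals_hat=npz["eigvals_hat"] if "eigvals_hat" in npz.files else None,
            variant=str(npz["variant"]),
            channel_names=names or None,
            rank=int(npz["rank"]),
        )


def _joint_diag_hermitian(S_L: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Unitary B and descending eigenvalues of a Hermitian S_L (with
    S_L + S_R = I the same B diagonalizes S_R)."""
    S = 0.5 * (S_L + S_L.conj().T)
    vals, vecs = np.linalg.eigh(S)
    order = np.argsort(vals)[::-1]
    return _fix_column_signs(vecs[:, order]), vals[order]


def _complex_orthogonal_eig(S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Eigendecomposition of a complex symmetric matrix with a
    complex-orthogonal eigenvector matrix (B^T B = I), so that
    B^T S B = diag and B^{-1} = B^T.

    Eigenvalues are sorted by descending real part.
    """
    S = 0.5 * (S + S.T)
    vals, vecs = np.linalg.eig(S)
    order = np.argsort(vals.real)[::-1]
    vals, vecs = vals[order], vecs[:, order]
    B = vecs.astype(complex)
    # re-orthogonalize within (near-)degenerate eigenvalue clusters under the
    # bilinear form v^T w, then normalize each column to v^T v = 1
    i = 0
    n = B.shape[1]
    while i < n:
        j = i + 1
        while j < n and abs(vals[j] - vals[i]) <= 1e-8 * max(1.0, abs(vals[i])):
            j += 1
        for a in range(i, j):
            for b in range(i, a):
                B[:, a] = B[:, a] - (B[:, b].T @ B[:, a]) * B[:, b]
            nrm2 = B[:, a].T @ B[:, a]
            if abs(nrm2) < 1e-10:
                raise FittingError(
                    "quasi-null eigenvector in pseudocovariance diagonalization"
                )
            B[:, a] = B[:, a] / np.sqrt(nrm2)
        i = j
    return _fix_column_signs(B), vals


def _fit_complex(trials: ComplexTrialSet, include_pseudo: bool,
                 normalization: str, rank_tol: float) -> FilterBank:
    cov = estimate_class_covariances(trials, normalization=normalization)
    white = whiten(cov.C_c, rank_tol=rank_tol)
    G = white.G
    P_bar = G @ cov.P_c @ G.T
    tak = takagi_factorize(P_bar)
    sut = compute_sut(white, tak)
    Q = sut.Q

    S_L = Q @ cov.C_L @ Q.conj().T
    B, lam_L = _joint_diag_hermitian(S_L)
    W = B.conj().T @ Q

    diagnostics = {
        "whiten_identity": float(np.linalg.norm(
            G @ cov.C_c @ G.conj().T - np.eye(white.rank))),
        "takagi_residual": float(np.linalg.norm(
            P_bar - tak.Y @ np.diag(tak.lam) @ tak.Y.T)),
        "sut_cov_identity": float(np.linalg.norm(
            Q @ cov.C_c @ Q.conj().T - np.eye(white.rank))),
        "eigval_sum": float(np.linalg.norm(
            W @ cov.C_L @ W.conj().T + W @ cov.C_R @ W.conj().T
            - np.eye(white.rank))),
    }

    W_hat = None
    lam_hat = None
    if include_pseudo:
        Q_hat = sut.Q_hat
        S_hat_L = Q_hat @ cov.P_L @ Q_hat.T
        B_hat, lam_hat_c = _complex_orthogonal_eig(S_hat_L)
        W_hat = B_hat.T @ Q_hat
        lam_hat = lam_hat_c.real
        diagnostics["sut_pcov_identity"] = float(np.linalg.norm(
            Q_hat @ cov.P_c @ Q_hat.T - np.eye(white.rank)))
        diagnostics["eigval_hat_sum"] = float(np.linalg.norm(
            W_hat @ cov.P_c @ W_hat.T - np.eye(white.rank)))

    return FilterBank(
        W=W, W_hat=W_hat, eigvals=lam_L, eigvals_hat=lam_hat,
        variant="SUTCCSP" if include_pseudo else "CCSP",
        channel_names=trials.channel_names, rank=white.rank,
        diagnostics=diagnostics,
    )


def sutccsp_fit(trials: ComplexTrialSet, normalization: str = "trace",
                rank_tol: float = 1e-10) -> FilterBank:
    """Fit the SUTCCSP filter pair (covariance and pseudocovariance routes)."""
    return _fit_complex(trials, include_pseudo=True,
                        normalization=normalization, rank_tol=rank_tol)


def ccsp_fit(trials: ComplexTrialSet, normalization: str = "trace",
             rank_tol: float = 1e-10) -> FilterBank:
    """Fit complex CSP: identical covariance-route W, no pseudocovariance bank."""
    return _fit_complex(trials, include_pseudo=False,
                        normalization=normalization, rank_tol=rank_tol)


def csp_fit(trials: EEGTrialSet, normalization: str = "trace",
            rank_tol: float = 1e-10) -> FilterBank:
    """Classical real-valued CSP via whitening + joint diagonalization."""
    trials.require_both_classes()
    complex_view = ComplexTrialSet(trials.data.astype(complex), trials.labels,
                                   trials.channel_names)
    cov = estimate_class_covariances(complex_view, normalization=normalization)
    white = whiten(cov.C_c.real, rank_tol=rank_tol)
    G = white.G.real
    S_L = G @ cov.C_L.real @ G.T
    B, lam_L = _joint_diag_hermitian(S_L)
    W = B.real.T @ G
    diagnostics = {
        "whiten_identity": float(np.linalg.norm(G @ cov.C_c.real @ G.T
                                                - np.eye(white.rank))),
        "eigval_sum": float(np.linalg.norm(
            W @ (cov.C_L.real + cov.C_R.real) @ W.T - np.eye(white.rank))),
    }
    return FilterBank(W=W, W_hat=None, eigvals=lam_L, eigvals_hat=None,
                      variant="CSP", channel_names=trials.channel_names,
                      rank=white.rank, diagnostics=diagnostics)


def apply_filters(bank: FilterBank, trials) -> tuple[np.ndarray, np.ndarray | None]:
    """Project trials through the bank: V = W A (and V_hat = W_hat A).

    ``trials`` may be a ComplexTrialSet, an EEGTrialSet, or a raw
    (trial, channel, sample) array.
    """
    data = getattr(trials, "data", trials)
    data = np.asarray(data)
    if data.ndim != 3:
        raise DataError(f"expected (trial, channel, sample); got {data.shape}")
    if data.shape[1] != bank.W.shape[1]:
        raise DataError(
            f"channel mismatch: trials have {data.shape[1]}, bank expects "
            f"{bank.W.shape[1]}")
    V = np.einsum("fc,tcs->tfs", bank.W, data)
    V_hat = None
    if bank.W_hat is not None:
        V_hat = np.einsum("fc,tcs->tfs", bank.W_hat, data)
    return V, V_hat
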