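"""Power features, repeated stratified cross-validation, and the binomial
significant-subject criterion."""

from __future__ import annotations

import copy
import hashlib
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
from scipy import stats
from sklearn.base import clone
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier

from .data import DataError

__all__ = [
    "ConfigurationError",
    "FeatureMatrix",
    "CVConfig",
    "ClassificationReport",
    "SignificancePool",
    "extract_power_features",
    "combine_csp_pd_features",
    "make_classifier",
    "repeated_stratified_cv",
    "significance_threshold",
    "select_significant_subjects",
    "paired_comparison",
]


class ConfigurationError(ValueError):
    pass


@dataclass
class FeatureMatrix:
    """Trial-by-feature matrix with labels and feature provenance names."""

    X: np.ndarray
    labels: np.ndarray
    feature_names: list[str]
    m_pairs: int

    def __post_init__(self) -> None:
        self.X = np.asarray(self.X, dtype=float)
        self.labels = np.asarray(self.labels, dtype=str)
        if self.X.ndim != 2:
            raise DataError(f"feature matrix must be 2-D; got {self.X.shape}")
        if self.X.shape[0] != self.labels.shape[0]:
            raise DataError("label count does not match trial count")
        if not np.isfinite(self.X).all():
            raise DataError("non-finite feature values")


def _block_features(V: np.ndarray, m_pairs: int, transform: str,
                    tag: str) -> tuple[np.ndarray, list[str]]:
    n_comp = V.shape[1]
    if n_comp < 2 * m_pairs:
        raise ConfigurationError(
            f"m_pairs={m_pairs} needs >= {2 * m_pairs} components; bank has {n_comp}")
    sel = list(range(m_pairs)) + list(range(n_comp - m_pairs, n_comp))
    comps = V[:, sel, :]
    centered = comps - comps.mean(axis=2, keepdims=True)
    if tag == "pcov":
        # the pseudocovariance route carries its class information in the
        # sample pseudo-variance E[v^2] (real part = power difference between
        # the real and imaginary series); its magnitude is the nonnegative
        # "power" of the noncircular component
        power = np.abs((centered ** 2).mean(axis=2))
    else:
        power = (np.abs(centered) ** 2).mean(axis=2)
    if transform == "log":
        total = power.sum(axis=1, keepdims=True)
        floor = 1e-300
        feats = np.log(np.clip(power, floor, None)
                       / np.clip(total, floor, None))
    elif transform == "raw":
        feats = power
    else:
        raise ConfigurationError(f"unknown transform {transform!r}")
    names = [f"{tag}:{'top' if i < m_pairs else 'bottom'}:{sel[i]}"
             for i in range(len(sel))]
    return feats, names


def extract_power_features(V: np.ndarray, V_hat: np.ndarray | None, labels,
                           m_pairs: int = 2,
                           transform: str = "log") -> FeatureMatrix:
    """Per-trial variance of the first/last ``m_pairs`` filtered components.

    For the log transform each variance is normalized by the summed variance
    of the selected components, making the features scale invariant.
    The pseudocovariance block (when present) doubles the feature count.
    """
    feats, names = _block_features(np.asarray(V), m_pairs, transform, "cov")
    blocks = [feats]
    if V_hat is not None:
        f2, n2 = _block_features(np.asarray(V_hat), m_pairs, transform, "pcov")
        blocks.append(f2)
        names += n2
    return FeatureMatrix(X=np.hstack(blocks), labels=np.asarray(labels, dtype=str),
                         feature_names=names, m_pairs=m_pairs)


def combine_csp_pd_features(csp_features: FeatureMatrix, mu: np.ndarray,
                            beta: np.ndarray,
                            channel_names: Sequence[str] | None = None
                            ) -> FeatureMatrix:
    """Append per-channel (mu power - beta power) trial features to CSP
    features (the CSP + PD combination)."""
    mu = np.asarray(mu, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if mu.shape != beta.shape or mu.ndim != 3:
        raise DataError("mu/beta must be matching (trial, channel, sample) arrays")
    if mu.shape[0] != csp_features.X.shape[0]:
        raise DataError("trial count mismatch between CSP features and series")
    pd_block = mu.var(axis=2) - beta.var(axis=2)
    names = channel_names if channel_names is not None else \
        [f"ch{i}" for i in range(mu.shape[1])]
    return FeatureMatrix(
        X=np.hstack([csp_features.X, pd_block]),
        labels=csp_features.labels,
        feature_names=csp_features.feature_names + [f"pd:{n}" for n in names],
        m_pairs=csp_features.m_pairs,
    )


# ---------------------------------------------------------------------------
# classifiers


def make_classifier(spec, seed: int = 0):
    """Resolve a classifier spec: 'rf' (100 trees), 'knn' (k=1), or any
    object exposing fit/predict (cloned per fold)."""
    if isinstance(spec, str):
        key = spec.lower()
        if key == "rf":
            return RandomForestClassifier(n_estimators=100, max_depth=None,
                                          random_state=seed)
        if key in ("knn", "knn1", "1nn"):
            return KNeighborsClassifier(n_neighbors=1)
        raise ConfigurationError(f"unknown classifier {spec!r}")
    if not (hasattr(spec, "fit") and hasattr(spec, "predict")):
        raise ConfigurationError("classifier plug-in must expose fit and predict")
    try:
        est = clone(spec)
    except Exception:
        est = copy.deepcopy(spec)
    if hasattr(est, "random_state"):
        try:
            est.set_params(random_state=seed)
        except Exception:
            pass
    return est


# ---------------------------------------------------------------------------
# cross-validation


@dataclass(frozen=True)
class CVConfig:
    k_folds: int = 5
    repetitions: int = 30
    seed: int = 0
    stratified: bool = True

    def __post_init__(self) -> None:
        if self.k_folds < 2:
            raise ConfigurationError("k_folds must be >= 2")
        if self.repetitions < 1:
            raise ConfigurationError("repetitions must be >= 1")


@dataclass
class ClassificationReport:
    """Fold accuracies for every repetition plus summary statistics."""

    fold_accuracies: np.ndarray  # (repetitions, k_folds), fractions in [0, 1]
    classifier_id: str
    variant: str
    fold_signature: str = ""

    @property
    def mean_accuracy(self) -> float:
        """Mean accuracy in percent."""
        return float(100.0 * self.fold_accuracies.mean())

    @property
    def sem(self) -> float:
        """Standard error (percent) of the per-repetition mean accuracies."""
        reps = self.fold_accuracies.shape[0]
        if reps < 2:
            return 0.0
        rep_means = self.fold_accuracies.mean(axis=1)
        return float(100.0 * rep_means.std(ddof=1) / np.sqrt(reps))


RefitCallback = Callable[[np.ndarray, np.ndarray],
                         tuple[np.ndarray, np.ndarray]]


def repeated_stratified_cv(features: FeatureMatrix | None, clf="rf",
                           cfg: CVConfig = CVConfig(),
                           refit_filters: RefitCallback | None = None,
                           labels: np.ndarray | None = None,
                           variant: str = "") -> ClassificationReport:
    """Repeated stratified k-fold cross-validation.

    Fold assignments depend only on ``cfg.seed`` and the labels, so runs
    with different variants or classifiers share folds (common random
    numbers).  When ``refit_filters`` is given it is called per fold with
    (train_idx, test_idx) and must return the train/test feature matrices
    computed from the training fold only (no leakage); ``labels`` must then
    be supplied explicitly.
    """
    if refit_filters is not None:
        if labels is None:
            raise ConfigurationError("labels required when refit_filters is used")
        y = np.asarray(labels, dtype=str)
    else:
        if features is None:
            raise ConfigurationError("either features or refit_filters is required")
        y = features.labels
    classes, counts = np.unique(y, return_counts=True)
    if counts.min() < cfg.k_folds:
        raise ConfigurationError(
            f"smallest class has {counts.min()} trials; need >= k_folds={cfg.k_folds}")

    accs = np.zeros((cfg.repetitions, cfg.k_folds))
    sig = hashlib.sha256()
    clf_id = clf if isinstance(clf, str) else type(clf).__name__
    for rep in range(cfg.repetitions):
        splitter = StratifiedKFold(n_splits=cfg.k_folds, shuffle=True,
                                   random_state=cfg.seed + rep)
        for fold, (tr, te) in enumerate(splitter.split(np.zeros(y.size), y)):
            sig.update(tr.tobytes())
            sig.update(te.tobytes())
            if refit_filters is not None:
                X_tr, X_te = refit_filters(tr, te)
            else:
                X_tr, X_te = features.X[tr], features.X[te]
            est = make_classifier(clf, seed=cfg.seed * 1000 + rep * cfg.k_folds + fold)
            est.fit(X_tr, y[tr])
            accs[rep, fold] = float(np.mean(est.predict(X_te) == y[te]))
    return ClassificationReport(fold_accuracies=accs, classifier_id=clf_id,
                                variant=variant, fold_signature=sig.hexdigest())


# ---------------------------------------------------------------------------
# significance machinery


def significance_threshold(n_trials: int, alpha: float = 0.05,
                           method: str = "exact") -> float:
    """Chance-level accuracy threshold (percent) for a binary classifier.

    ``exact``: 100 * k / n for the smallest k with one-sided binomial tail
    P(X >= k | n, p=0.5) <= alpha.  ``normal``: the normal-approximation
    confidence limit 50 + 100 * z_alpha / (2 sqrt(n)).
    """
    if n_trials < 10:
        raise ConfigurationError("n_trials must be >= 10")
    if method == "normal":
        z = stats.norm.ppf(1 - alpha)
        return float(100.0 * (0.5 + z * 0.5 / np.sqrt(n_trials)))
    if method != "exact":
        raise ConfigurationError(f"unknown method {method!r}")
    for k in range(n_trials // 2, n_trials + 1):
        if stats.binom.sf(k - 1, n_trials, 0.5) <= alpha:
            return float(100.0 * k / n_trials)
    return 100.0


@dataclass
class SignificancePool:
    """Union pool of subjects significant under at least one variant."""

    pool: set
    flags: dict  # subject -> {variant: bool}


def select_significant_subjects(
        reports: Mapping[object, Mapping[str, ClassificationReport]],
        thresholds: Mapping[object, float] | float) -> SignificancePool:
    """Union over variants of subjects whose mean accuracy exceeds their
    threshold."""
    pool = set()
    flags: dict = {}
    for subject, per_variant in reports.items():
        thr = thresholds if isinstance(thresholds, (int, float)) \
            else thresholds[subject]
        flags[subject] = {
            variant: report.mean_accuracy > thr
            for variant, report in per_variant.items()
        }
        if any(flags[subject].values()):
            pool.add(subject)
    return SignificancePool(pool=pool, flags=flags)


def paired_comparison(accuracies_a: Sequence[float], accuracies_b: Sequence[float],
                      alternative: str = "two-sided",
                      paired: bool = True) -> tuple[float, float]:
    """Student's t-test on per-subject accuracies; returns (statistic, p)."""
    a = np.asarray(accuracies_a, dtype=float)
    b = np.asarray(accuracies_b, dtype=float)
    if paired:
        if a.shape != b.shape:
            raise DataError("paired comparison needs equal-length inputs")
        if np.allclose(a, b):
            return 0.0, 1.0
        res = stats.ttest_rel(a, b, alternative=alternative)
    else:
        res = stats.ttest_ind(a, b, alternative=alternative)
    return float(res.statistic), float(res.pvalue)
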