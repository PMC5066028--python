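"""Spatial-pattern maps and hemispheric asymmetry statistics.

The asymmetry index (CH_L - CH_R) / (CH_L + CH_R) compares a quantity —
here the mu/beta power difference or power sum — at mirror-symmetric
electrode pairs, per trial.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import DataError
from .spatial_filters import FilterBank

__all__ = [
    "SpatialPatternMap",
    "spatial_patterns",
    "channel_band_power",
    "asymmetry",
    "build_asymmetry_records",
    "exclude_outliers",
    "asymmetry_summary",
]


@dataclass
class SpatialPatternMap:
    """Forward-model patterns (columns of the filter pseudo-inverse)."""

    patterns: np.ndarray                  # (channel, component), complex or real
    patterns_hat: np.ndarray | None
    eigvals: np.ndarray
    channel_names: list[str] | None

    def display_values(self, which: str = "cov") -> np.ndarray:
        """Real scalars for topography display: magnitude signed by the real
        part."""
        pats = self.patterns if which == "cov" else self.patterns_hat
        if pats is None:
            raise DataError("bank has no pseudocovariance patterns")
        sign = np.where(pats.real < 0, -1.0, 1.0)
        return np.abs(pats) * sign


def _invert_filters(W: np.ndarray) -> np.ndarray:
    r, n = W.shape
    if r == n:
        cond = np.linalg.cond(W)
        if cond < 1e12:
            return np.linalg.inv(W)
    warnings.warn("rank-deficient filter matrix; using pseudo-inverse",
                  RuntimeWarning, stacklevel=3)
    return np.linalg.pinv(W)


def spatial_patterns(bank: FilterBank) -> SpatialPatternMap:
    """Invert a filter bank into forward-model patterns.

    Satisfies W @ patterns = I on the retained subspace; components follow
    the bank's eigenvalue order.
    """
    patterns = _invert_filters(bank.W)
    patterns_hat = _invert_filters(bank.W_hat) if bank.W_hat is not None else None
    return SpatialPatternMap(patterns=patterns, patterns_hat=patterns_hat,
                             eigvals=bank.eigvals,
                             channel_names=bank.channel_names)


def channel_band_power(mu: np.ndarray, beta: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Per-trial per-channel variance (mean removed) of each rhythm series."""
    mu = np.asarray(mu, dtype=float)
    beta = np.asarray(beta, dtype=float)
    if mu.shape != beta.shape or mu.ndim != 3:
        raise DataError("mu/beta must be matching (trial, channel, sample) arrays")
    return mu.var(axis=2), beta.var(axis=2)


def asymmetry(ch_l: float, ch_r: float) -> float:
    """(CH_L - CH_R) / (CH_L + CH_R); NaN when the denominator vanishes.

    Antisymmetric under swapping arguments; bounded by +/-1 for nonnegative
    inputs.
    """
    denom = ch_l + ch_r
    if denom == 0:
        return float("nan")
    return (ch_l - ch_r) / denom


def build_asymmetry_records(mu: np.ndarray, beta: np.ndarray, labels,
                            pairs: list[tuple[str, str]],
                            channel_names: list[str]) -> pd.DataFrame:
    """Per-trial, per-pair asymmetry of the mu/beta power difference and sum.

    Returns a tidy frame with columns pair, trial, label, quantity, ch_l,
    ch_r, asymmetry.  Undefined values (zero denominator) are NaN.
    """
    p_mu, p_beta = channel_band_power(mu, beta)
    labels = np.asarray(labels, dtype=str)
    name_to_idx = {n: i for i, n in enumerate(channel_names)}
    rows = []
    for left, right in pairs:
        try:
            il, ir = name_to_idx[left], name_to_idx[right]
        except KeyError as exc:
            raise DataError(f"pair channel {exc.args[0]!r} not in channel list")
        for quantity, values in (
            ("power_difference", (p_mu - p_beta)),
            ("power_sum", (p_mu + p_beta)),
        ):
            for t in range(p_mu.shape[0]):
                ch_l, ch_r = float(values[t, il]), float(values[t, ir])
                rows.append({
                    "pair": f"{left}-{right}",
                    "trial": t,
                    "label": labels[t],
                    "quantity": quantity,
                    "ch_l": ch_l,
                    "ch_r": ch_r,
                    "asymmetry": asymmetry(ch_l, ch_r),
                })
    return pd.DataFrame(rows)


def exclude_outliers(records: pd.DataFrame, sd_cutoff: float = 5.0
                     ) -> tuple[pd.DataFrame, int]:
    """Single-pass removal of records beyond mean +/- sd_cutoff * sd within
    each (pair, quantity) group; NaN asymmetries are also dropped."""
    df = records.dropna(subset=["asymmetry"])
    n_nan = len(records) - len(df)
    if not np.isfinite(sd_cutoff):
        return df.reset_index(drop=True), n_nan
    keep_parts = []
    for _, group in df.groupby(["pair", "quantity"], sort=False):
        mean = group["asymmetry"].mean()
        sd = group["asymmetry"].std(ddof=1)
        if not np.isfinite(sd) or sd == 0:
            keep_parts.append(group)
            continue
        keep_parts.append(
            group[(group["asymmetry"] - mean).abs() <= sd_cutoff * sd])
    kept = pd.concat(keep_parts) if keep_parts else df.iloc[:0]
    n_excluded = len(records) - len(kept)
    return kept.sort_index().reset_index(drop=True), n_excluded


def asymmetry_summary(mu: np.ndarray, beta: np.ndarray, labels,
                      pairs: list[tuple[str, str]],
                      channel_names: list[str],
                      sd_cutoff: float = 5.0) -> pd.DataFrame:
    """Per-pair, per-class mean +/- sem of both asymmetry quantities,
    computed after outlier exclusion."""
    records = build_asymmetry_records(mu, beta, labels, pairs, channel_names)
    kept, n_excluded = exclude_outliers(records, sd_cutoff=sd_cutoff)
    grouped = kept.groupby(["pair", "label", "quantity"], sort=False)["asymmetry"]
    summary = grouped.agg(mean="mean", sem="sem", n="count").reset_index()
    summary["n_excluded_total"] = n_excluded
    return summary
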