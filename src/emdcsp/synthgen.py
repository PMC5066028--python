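"""Synthetic multichannel EEG with known lateralized rhythm structure.

Generates epoch-segmented two-class trial sets in which narrowband sources
(by default a mu-band and a beta-band source) are mixed linearly into
channels with class- and hemisphere-dependent amplitudes, plus broadband
noise.  Ground truth (mixing matrix, per-trial effective source amplitudes,
per-trial per-channel band powers) is returned alongside the data so every
downstream stage has an oracle to test against.

A special "difference-only" construction swaps the mu/beta hemisphere
amplitudes between classes so that the summed band power at every channel is
class-invariant while the mu-beta power *difference* is lateralized with
opposite sign across classes.  Covariance-only methods see nothing; methods
that exploit the pseudocovariance see a large effect.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, replace

import numpy as np
import yaml
from scipy import signal

from .data import EEGTrialSet

__all__ = [
    "MU_BAND",
    "BETA_BAND",
    "ConfigurationError",
    "SourceSpec",
    "SynthConfig",
    "generate_dataset",
    "make_difference_only_config",
    "default_mixing",
    "config_to_yaml",
    "config_from_yaml",
]

MU_BAND = (8.0, 13.0)
BETA_BAND = (13.0, 25.0)

#: Default 14-channel montage order (see io_cli.default_montage).
DEFAULT_CHANNELS = [
    "Fz", "FC5", "FC1", "FC2", "FC6", "C3", "Cz",
    "C4", "CP5", "CP6", "P1", "Pz", "P2", "Oz",
]
DEFAULT_HEMISPHERES = [
    "M", "L", "L", "R", "R", "L", "M",
    "R", "L", "R", "L", "M", "R", "M",
]


class ConfigurationError(ValueError):
    """Raised for invalid generator configurations."""


@dataclass(frozen=True)
class SourceSpec:
    """One narrowband source and its class/hemisphere amplitude layout.

    ``amp_left_class`` and ``amp_right_class`` are ``(left_hemisphere,
    right_hemisphere)`` amplitude pairs used when the trial label is ``L``
    or ``R`` respectively.  Midline channels receive the average of the two
    hemisphere amplitudes.
    """

    band_low: float
    band_high: float
    amp_left_class: tuple[float, float] = (1.0, 1.0)
    amp_right_class: tuple[float, float] = (1.0, 1.0)
    waveform: str = "bandlimited_noise"

    def __post_init__(self) -> None:
        if not (0.0 < self.band_low < self.band_high):
            raise ConfigurationError(
                f"need 0 < band_low < band_high; got ({self.band_low}, {self.band_high})"
            )
        for pair in (self.amp_left_class, self.amp_right_class):
            if len(pair) != 2 or any(a < 0 for a in pair):
                raise ConfigurationError(f"amplitudes must be nonnegative pairs; got {pair}")
        if self.waveform not in ("bandlimited_noise", "amplitude_modulated_sinusoid"):
            raise ConfigurationError(f"unknown waveform {self.waveform!r}")

    def amps(self, label: str) -> tuple[float, float]:
        return self.amp_left_class if label == "L" else self.amp_right_class


def default_mixing(n_channels: int, n_sources: int) -> np.ndarray:
    """Deterministic full-column-rank mixing with unit-magnitude entries.

    Column ``s`` is a Walsh-style sign pattern; equal column magnitudes keep
    per-channel band powers directly comparable across sources.
    """
    if n_sources > n_channels:
        raise ConfigurationError("more sources than channels")
    cols = []
    for s in range(n_sources):
        if s == 0:
            cols.append(np.ones(n_channels))
        else:
            c = np.arange(n_channels)
            cols.append(np.where((c >> (s - 1)) & 1, -1.0, 1.0))
    return np.column_stack(cols)


@dataclass(frozen=True)
class SynthConfig:
    """Full generator configuration; deterministic given ``seed``."""

    fs: float = 160.0
    n_samples: int = 640
    n_channels: int = 14
    n_trials_per_class: int = 50
    sources: tuple[SourceSpec, ...] = (
        SourceSpec(*MU_BAND),
        SourceSpec(*BETA_BAND),
    )
    mixing: np.ndarray | None = None
    noise_sd: float = 0.2
    seed: int = 0
    channel_names: tuple[str, ...] | None = None
    hemispheres: tuple[str, ...] | None = None
    amp_jitter_sd: float = 0.1

    def resolved_mixing(self) -> np.ndarray:
        if self.mixing is None:
            return default_mixing(self.n_channels, len(self.sources))
        return np.asarray(self.mixing, dtype=float)

    def resolved_channel_names(self) -> list[str]:
        if self.channel_names is not None:
            return list(self.channel_names)
        if self.n_channels == len(DEFAULT_CHANNELS):
            return list(DEFAULT_CHANNELS)
        return [f"ch{i}" for i in range(self.n_channels)]

    def resolved_hemispheres(self) -> list[str]:
        if self.hemispheres is not None:
            return list(self.hemispheres)
        if self.n_channels == len(DEFAULT_HEMISPHERES):
            return list(DEFAULT_HEMISPHERES)
        # generic fallback: first half left, second half right, odd middle is midline
        half = self.n_channels // 2
        hemis = ["L"] * half + ["M"] * (self.n_channels % 2) + ["R"] * half
        return hemis

    def validate(self) -> None:
        if self.fs <= 0:
            raise ConfigurationError("fs must be positive")
        if self.n_trials_per_class < 1:
            raise ConfigurationError("need at least one trial per class")
        if not self.sources:
            raise ConfigurationError("at least one source required")
        slowest = min(s.band_low for s in self.sources)
        for s in self.sources:
            if s.band_high >= self.fs / 2:
                raise ConfigurationError(
                    f"source band ({s.band_low}, {s.band_high}) exceeds Nyquist {self.fs / 2}"
                )
        if self.n_samples < 2 * self.fs / slowest:
            raise ConfigurationError(
                f"n_samples={self.n_samples} too small for slowest band "
                f"({slowest} Hz needs >= {2 * self.fs / slowest:.0f} samples)"
            )
        mix = self.resolved_mixing()
        if mix.shape != (self.n_channels, len(self.sources)):
            raise ConfigurationError(
                f"mixing shape {mix.shape} != (n_channels, n_sources) "
                f"= ({self.n_channels}, {len(self.sources)})"
            )
        if np.linalg.matrix_rank(mix) < len(self.sources):
            raise ConfigurationError("mixing matrix is rank deficient")
        hemis = self.resolved_hemispheres()
        if len(hemis) != self.n_channels or set(hemis) - {"L", "R", "M"}:
            raise ConfigurationError("hemisphere map must assign L/R/M to every channel")


def _bandlimited_noise(rng: np.random.Generator, n: int, band: tuple[float, float],
                       fs: float) -> np.ndarray:
    """Band-pass filtered white noise, transients discarded, unit variance."""
    pad = int(2 * fs)
    sos = signal.butter(4, band, btype="bandpass", fs=fs, output="sos")
    raw = rng.standard_normal(n + 2 * pad)
    x = signal.sosfiltfilt(sos, raw)[pad:pad + n]
    sd = x.std()
    return x / sd if sd > 0 else x


def _am_sinusoid(rng: np.random.Generator, n: int, band: tuple[float, float],
                 fs: float) -> np.ndarray:
    """Amplitude-modulated carrier at the band center, unit variance."""
    t = np.arange(n) / fs
    fc = 0.5 * (band[0] + band[1])
    phase = rng.uniform(0, 2 * np.pi)
    env = 1.0 + 0.5 * np.sin(2 * np.pi * 0.7 * t + rng.uniform(0, 2 * np.pi))
    x = env * np.sin(2 * np.pi * fc * t + phase)
    x = x - x.mean()
    return x / x.std()


_WAVEFORMS = {
    "bandlimited_noise": _bandlimited_noise,
    "amplitude_modulated_sinusoid": _am_sinusoid,
}


def generate_dataset(config: SynthConfig) -> tuple[EEGTrialSet, dict[str, np.ndarray]]:
    """Generate a labeled trial set with per-trial ground truth.

    Returns
    -------
    trials : EEGTrialSet
    ground_truth : dict
        ``mixing`` (channel x source), ``source_amplitudes`` (trial x source
        x hemisphere, jitter included), ``band_power`` (trial x channel x
        source, expected narrowband power contributed by each source at each
        channel) and ``labels``.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    mix = config.resolved_mixing()
    hemis = config.resolved_hemispheres()
    n_src = len(config.sources)
    n_tr = 2 * config.n_trials_per_class
    labels = np.array(["L"] * config.n_trials_per_class + ["R"] * config.n_trials_per_class)

    data = np.zeros((n_tr, config.n_channels, config.n_samples))
    amp_eff = np.zeros((n_tr, n_src, 2))  # effective (jittered) amps, hemi L/R
    band_power = np.zeros((n_tr, config.n_channels, n_src))
    hemi_idx = {"L": 0, "R": 1}

    for t in range(n_tr):
        label = labels[t]
        for s, src in enumerate(config.sources):
            gen = _WAVEFORMS[src.waveform]
            waves = {h: gen(rng, config.n_samples, (src.band_low, src.band_high), config.fs)
                     for h in ("L", "R")}
            base = src.amps(label)
            jitter = rng.lognormal(mean=0.0, sigma=config.amp_jitter_sd, size=2) \
                if config.amp_jitter_sd > 0 else np.ones(2)
            eff = (base[0] * jitter[0], base[1] * jitter[1])
            amp_eff[t, s] = eff
            for c in range(config.n_channels):
                h = hemis[c]
                if h == "M":
                    contrib = 0.5 * (eff[0] * waves["L"] + eff[1] * waves["R"])
                    power = 0.25 * (eff[0] ** 2 + eff[1] ** 2)
                else:
                    contrib = eff[hemi_idx[h]] * waves[h]
                    power = eff[hemi_idx[h]] ** 2
                data[t, c] += mix[c, s] * contrib
                band_power[t, c, s] = mix[c, s] ** 2 * power
        if config.noise_sd > 0:
            data[t] += config.noise_sd * rng.standard_normal(
                (config.n_channels, config.n_samples))

    trials = EEGTrialSet(data=data, labels=labels,
                         channel_names=config.resolved_channel_names(), fs=config.fs)
    ground_truth = {
        "mixing": mix,
        "source_amplitudes": amp_eff,
        "band_power": band_power,
        "labels": labels,
    }
    return trials, ground_truth


def _classify_band(src: SourceSpec) -> str:
    """Tag a source as mu-like or beta-like by band-overlap."""
    def overlap(band):
        return max(0.0, min(src.band_high, band[1]) - max(src.band_low, band[0]))

    o_mu, o_beta = overlap(MU_BAND), overlap(BETA_BAND)
    if o_mu == o_beta == 0.0:
        return "other"
    return "mu" if o_mu >= o_beta else "beta"


def make_difference_only_config(base: SynthConfig) -> SynthConfig:
    """Engineer a config whose classes differ only in the mu-beta power split.

    For every channel the expected mu + beta power is identical across
    classes, while mu - beta power is lateralized with opposite sign across
    hemispheres and classes.  Requires the base config to contain exactly one
    mu-band and one beta-band source.
    """
    tags = [_classify_band(s) for s in base.sources]
    if tags.count("mu") != 1 or tags.count("beta") != 1:
        raise ConfigurationError(
            f"base config needs exactly one mu and one beta source; got {tags}"
        )
    i_mu, i_beta = tags.index("mu"), tags.index("beta")
    mu_src, beta_src = base.sources[i_mu], base.sources[i_beta]

    a, b = mu_src.amp_left_class
    if np.isclose(a, b):
        # equal base amplitudes cannot discriminate; split around their mean
        mean = a if a > 0 else 1.0
        a, b = 1.5 * mean, 0.5 * mean

    sources = list(base.sources)
    sources[i_mu] = replace(mu_src, amp_left_class=(a, b), amp_right_class=(b, a))
    sources[i_beta] = replace(beta_src, amp_left_class=(b, a), amp_right_class=(a, b))

    # A class-invariant baseline mu source keeps the composite
    # pseudocovariance positive-dominant (the lateralized parts cancel in
    # the composite).  Its power is set below the lateralized power
    # difference a^2 - b^2 so the per-hemisphere sign of the mu - beta
    # difference is preserved.
    baseline_amp = float(np.sqrt((a ** 2 - b ** 2) / 2.0))
    baseline = SourceSpec(mu_src.band_low, mu_src.band_high,
                          amp_left_class=(baseline_amp, baseline_amp),
                          amp_right_class=(baseline_amp, baseline_amp),
                          waveform=mu_src.waveform)
    sources.append(baseline)

    # Class-invariance of the full covariance of mu + beta (not just the
    # per-channel power) requires the beta mixing column to equal the mu
    # column up to a constant sign within each hemisphere.  Flipping the
    # sign on one hemisphere keeps the columns linearly independent, and
    # zeroing the midline rows decouples the two hemispheres so the
    # flipped sign never shows up in a cross-covariance.
    hemis = np.asarray(base.resolved_hemispheres())
    mix = base.resolved_mixing().copy()
    mix[hemis == "M", i_mu] = 0.0
    mix[hemis == "M", i_beta] = 0.0
    sign = np.where(hemis == "R", -1.0, 1.0)
    mix[:, i_beta] = mix[:, i_mu] * sign
    mix = np.column_stack([mix, np.ones(base.n_channels)])
    if np.linalg.matrix_rank(mix) < mix.shape[1]:
        raise ConfigurationError(
            "difference-only mixing is rank deficient; base mixing must give "
            "both hemispheres nonzero mu-source weight")

    cfg = replace(base, sources=tuple(sources), mixing=mix)
    cfg.validate()
    return cfg


# ---------------------------------------------------------------------------
# plain-text config round trip


def config_to_yaml(config: SynthConfig) -> str:
    doc = {
        "fs": config.fs,
        "n_samples": config.n_samples,
        "n_channels": config.n_channels,
        "n_trials_per_class": config.n_trials_per_class,
        "noise_sd": config.noise_sd,
        "seed": config.seed,
        "amp_jitter_sd": config.amp_jitter_sd,
        "sources": [
            {
                "band_low": s.band_low,
                "band_high": s.band_high,
                "amp_left_class": list(s.amp_left_class),
                "amp_right_class": list(s.amp_right_class),
                "waveform": s.waveform,
            }
            for s in config.sources
        ],
    }
    if config.mixing is not None:
        doc["mixing"] = np.asarray(config.mixing).tolist()
    if config.channel_names is not None:
        doc["channel_names"] = list(config.channel_names)
    if config.hemispheres is not None:
        doc["hemispheres"] = list(config.hemispheres)
    return yaml.safe_dump(doc, sort_keys=False)


def config_from_yaml(text: str) -> SynthConfig:
    doc = yaml.safe_load(io.StringIO(text)) or {}
    sources = tuple(
        SourceSpec(
            band_low=float(s["band_low"]),
            band_high=float(s["band_high"]),
            amp_left_class=tuple(s.get("amp_left_class", (1.0, 1.0))),
            amp_right_class=tuple(s.get("amp_right_class", (1.0, 1.0))),
            waveform=s.get("waveform", "bandlimited_noise"),
        )
        for s in doc.get("sources", [])
    ) or SynthConfig().sources
    kwargs: dict = {}
    for key in ("fs", "noise_sd", "amp_jitter_sd"):
        if key in doc:
            kwargs[key] = float(doc[key])
    for key in ("n_samples", "n_channels", "n_trials_per_class", "seed"):
        if key in doc:
            kwargs[key] = int(doc[key])
    if "mixing" in doc:
        kwargs["mixing"] = np.asarray(doc["mixing"], dtype=float)
    if "channel_names" in doc:
        kwargs["channel_names"] = tuple(doc["channel_names"])
    if "hemispheres" in doc:
        kwargs["hemispheres"] = tuple(doc["hemispheres"])
    return SynthConfig(sources=sources, **kwargs)
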