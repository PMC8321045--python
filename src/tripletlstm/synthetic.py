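"""Synthetic multi-region crop-phenology simulator.

Emulates the statistical structure of parcel-aggregated Sentinel-2 time
series: each crop class has a smooth class-specific seasonal profile per
band (a double-logistic curve, the canonical vegetation-phenology form),
regions impose small smooth intra-class shifts, class sizes are strongly
imbalanced, raw sequence lengths vary, and observations carry additive
noise truncated at zero (reflectances are non-negative).

Deliberately confusable class groups (e.g. fodder and the two meadow
classes) share base curve parameters with small offsets, reproducing the
kind of inter-class similarity the metric-learning objective targets.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from .io import TimeSeriesSample

__all__ = [
    "PhenologyProfile",
    "SyntheticConfig",
    "make_profiles",
    "generate",
    "easy_config",
    "DEFAULT_CLASS_NAMES",
    "DEFAULT_PROPORTIONS",
]

DEFAULT_CLASS_NAMES = [
    "barley",
    "wheat",
    "corn",
    "fodder",
    "fallow",
    "miscellaneous",
    "orchards",
    "cereals",
    "perm_meadows",
    "protein_crops",
    "rapeseed",
    "temp_meadows",
    "vegetables",
]

# Strong imbalance mirroring real regional crop inventories: three dominant
# classes (corn, meadows), several rare ones (orchards, protein crops).
DEFAULT_PROPORTIONS = [
    0.0483,  # barley
    0.1172,  # wheat
    0.2015,  # corn
    0.0301,  # fodder
    0.0159,  # fallow
    0.0871,  # miscellaneous
    0.0040,  # orchards
    0.0265,  # cereals
    0.1673,  # perm_meadows
    0.0043,  # protein_crops
    0.0193,  # rapeseed
    0.2386,  # temp_meadows
    0.0397,  # vegetables
]


@dataclass
class PhenologyProfile:
    """Per-band double-logistic seasonal curve parameters for one class.

    Each parameter array has one entry per band: baseline ``b``, amplitude
    ``a`` (negative only for bands modeled as absorption features), peak time
    ``t0``, plateau half-width ``w`` and rise/fall widths ``r``, ``f`` (all
    time quantities in timestep units).
    """

    class_id: int
    baseline: np.ndarray
    amplitude: np.ndarray
    peak_time: np.ndarray
    half_width: np.ndarray
    rise: np.ndarray
    fall: np.ndarray

    def __post_init__(self) -> None:
        if np.any(self.baseline < 0):
            raise ValueError("baseline reflectance must be non-negative")
        if np.any(self.rise <= 0) or np.any(self.fall <= 0):
            raise ValueError("rise/fall widths must be positive")

    def curve(self, t: np.ndarray) -> np.ndarray:
        """Evaluate the profile at times ``t``; returns (len(t), B)."""
        t = np.asarray(t, dtype=float)[:, None]
        b, a = self.baseline[None], self.amplitude[None]
        t0, w = self.peak_time[None], self.half_width[None]
        r, f = self.rise[None], self.fall[None]
        up = 1.0 / (1.0 + np.exp(-(t - t0 + w) / r))
        down = 1.0 / (1.0 + np.exp(-(t - t0 - w) / f))
        return b + a * (up - down)


@dataclass
class SyntheticConfig:
    """Generator settings; ``seed`` fully determines the output."""

    n_classes: int = 13
    n_regions: int = 4
    n_bands: int = 13
    n_samples: int = 5000
    t_raw_range: tuple[int, int] = (40, 52)
    season_length: int = 45
    class_proportions: Sequence[float] | None = None
    region_shift_scale: float = 0.02
    noise_sd: float = 0.01
    confusable_class_groups: list[list[int]] = field(default_factory=lambda: [[3, 8, 11]])
    confusable_offset: float = 0.015
    seed: int = 0

    def __post_init__(self) -> None:
        if self.class_proportions is None:
            if self.n_classes == 13:
                self.class_proportions = list(DEFAULT_PROPORTIONS)
            else:
                # fall back to a geometric imbalance profile
                raw = [0.7**k for k in range(self.n_classes)]
                self.class_proportions = [p / sum(raw) for p in raw]
        p = np.asarray(self.class_proportions, dtype=float)
        if len(p) != self.n_classes:
            raise ValueError("class_proportions length must equal n_classes")
        if np.any(p <= 0):
            raise ValueError("class proportions must be positive")
        self.class_proportions = list(p / p.sum())
        if self.n_samples < 1 or self.n_regions < 1 or self.n_bands < 1:
            raise ValueError("all counts must be >= 1")
        lo, hi = self.t_raw_range
        if lo < 1 or hi < lo:
            raise ValueError("invalid t_raw_range")
        for group in self.confusable_class_groups:
            if any(not 0 <= c < self.n_classes for c in group):
                raise ValueError("confusable group contains an invalid class id")

    @property
    def region_names(self) -> list[str]:
        return [f"R{i + 1:02d}" for i in range(self.n_regions)]


def easy_config(n_samples: int = 5000, seed: int = 0, **overrides) -> SyntheticConfig:
    """The 'easy' separable condition: small region shift, low noise."""
    cfg = SyntheticConfig(
        n_samples=n_samples, region_shift_scale=0.02, noise_sd=0.01, seed=seed
    )
    return replace(cfg, **overrides) if overrides else cfg


def make_profiles(config: SyntheticConfig) -> list[PhenologyProfile]:
    """Draw one double-logistic profile per class from the seeded generator.

    Classes inside a confusable group share their base parameters and differ
    only by small offsets, so their curves stay mutually closer than any
    cross-group pair.
    """
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 101]))
    B, T = config.n_bands, config.season_length

    group_of = {}
    for gi, group in enumerate(config.confusable_class_groups):
        for c in group:
            group_of[c] = gi

    def draw_base():
        baseline = rng.uniform(0.05, 0.25, size=B)
        amplitude = rng.uniform(0.15, 0.55, size=B)
        # model up to two absorption bands: amplitude dips below baseline
        n_abs = rng.integers(0, 3)
        if n_abs:
            idx = rng.choice(B, size=n_abs, replace=False)
            amplitude[idx] *= -0.6
            baseline[idx] += 0.2
        peak_time = rng.uniform(0.25 * T, 0.75 * T, size=B)
        half_width = rng.uniform(3.0, 9.0, size=B)
        rise = rng.uniform(1.5, 5.0, size=B)
        fall = rng.uniform(1.5, 5.0, size=B)
        return baseline, amplitude, peak_time, half_width, rise, fall

    group_bases = {gi: draw_base() for gi in range(len(config.confusable_class_groups))}

    profiles = []
    for c in range(config.n_classes):
        if c in group_of:
            b, a, t0, w, r, f = (arr.copy() for arr in group_bases[group_of[c]])
            eps = config.confusable_offset
            b = np.clip(b + rng.normal(0.0, eps, size=B), 0.0, None)
            a = a + rng.normal(0.0, eps, size=B)
            t0 = t0 + rng.normal(0.0, 1.0, size=B)
        else:
            b, a, t0, w, r, f = draw_base()
        profiles.append(
            PhenologyProfile(
                class_id=c, baseline=b, amplitude=a, peak_time=t0,
                half_width=w, rise=r, fall=f,
            )
        )
    return profiles


def _region_perturbations(config: SyntheticConfig) -> np.ndarray:
    """Smooth per-(region, class, band) offset curves, (n_regions, n_classes, T, B)."""
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 202]))
    T, B = config.season_length, config.n_bands
    t = np.arange(T, dtype=float)
    out = np.zeros((config.n_regions, config.n_classes, T, B))
    s = config.region_shift_scale
    if s == 0:
        return out
    for ri in range(config.n_regions):
        for c in range(config.n_classes):
            alpha = rng.normal(0.0, 1.0, size=B)
            beta = rng.normal(0.0, 1.0, size=B)
            phase = rng.uniform(0.0, 2 * np.pi, size=B)
            wave = np.sin(2 * np.pi * t[:, None] / T + phase[None])
            out[ri, c] = s * (alpha[None] + beta[None] * wave)
    return out


def _allocate_counts(config: SyntheticConfig, rng: np.random.Generator) -> np.ndarray:
    """Multinomial class counts distributed over regions, every cell non-empty
    whenever the class count allows (so each region carries every crop type)."""
    n, R = config.n_samples, config.n_regions
    class_counts = rng.multinomial(n, config.class_proportions)
    cells = np.zeros((R, config.n_classes), dtype=int)
    for c, total in enumerate(class_counts):
        if total >= R:
            base = np.ones(R, dtype=int)
            extra = rng.multinomial(total - R, np.full(R, 1.0 / R))
            cells[:, c] = base + extra
        else:
            regions = rng.choice(R, size=total, replace=False)
            for ri in regions:
                cells[ri, c] += 1
    return cells


def generate(config: SyntheticConfig) -> list[TimeSeriesSample]:
    """Generate the full labeled multi-region dataset.

    Each sample is its class's profile evaluated on a raw time grid of
    ``T_raw`` points spanning the season, plus its (region, class) smooth
    perturbation interpolated to that grid, plus i.i.d. Gaussian noise,
    clipped at zero.
    """
    profiles = make_profiles(config)
    perturb = _region_perturbations(config)
    rng = np.random.default_rng(np.random.SeedSequence([config.seed, 303]))
    cells = _allocate_counts(config, rng)
    lo, hi = config.t_raw_range
    T = config.season_length
    season_t = np.arange(T, dtype=float)

    samples: list[TimeSeriesSample] = []
    uid = 0
    for ri, region in enumerate(config.region_names):
        for c in range(config.n_classes):
            count = int(cells[ri, c])
            if count == 0:
                continue
            for _ in range(count):
                t_raw = int(rng.integers(lo, hi + 1))
                t_grid = np.linspace(0.0, T - 1.0, t_raw)
                curve = profiles[c].curve(t_grid)
                shift = np.empty((t_raw, config.n_bands))
                for b in range(config.n_bands):
                    shift[:, b] = np.interp(t_grid, season_t, perturb[ri, c, :, b])
                noise = rng.normal(0.0, config.noise_sd, size=curve.shape)
                series = np.clip(curve + shift + noise, 0.0, None)
                samples.append(
                    TimeSeriesSample(
                        parcel_id=f"p{uid:07d}", region=region, label=c, series=series
                    )
                )
                uid += 1
    # deterministic shuffle so splits see interleaved classes
    order = rng.permutation(len(samples))
    return [samples[i] for i in order]
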