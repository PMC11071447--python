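"""Lucas-Washburn flow modeling of paper-channel imbibition.

Horizontal capillary flow in a porous strip follows the Lucas-Washburn
(L-W) law

    L = sqrt(D t),    D = R * gamma_LG * cos(theta) / (2 mu),

with front distance ``L`` growing as the square root of time.  The lumped
diffusion coefficient ``D`` (cm^2/s) carries the effective capillary
radius ``R``, liquid-gas interfacial tension ``gamma_LG``, contact angle
``theta`` and dynamic viscosity ``mu``.  Particle immunoagglutination at
the wetting front perturbs these liquid properties, so ``D`` is high in
an early regime (where the assay signal lives) and relaxes to a lower,
constant late value.  This module estimates ``D`` two ways — pointwise as
L^2/t and by least-squares fits of L = sqrt(D t) over frame windows —
compares windows, and selects the operating (detection) frame as half the
early/late crossover.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .flow_tracking import FlowProfile, frames_to_seconds

__all__ = [
    "DiffusionSeries",
    "LWFit",
    "PhysicalParams",
    "pointwise_diffusion",
    "fit_lw",
    "compare_windows",
    "select_detection_frame",
    "diffusion_from_physics",
]


class DegenerateFitError(ValueError):
    """The fit window contains no usable flow signal."""


@dataclass(frozen=True)
class DiffusionSeries:
    """Per-frame pointwise diffusion estimates D = L^2/t, smoothed."""

    frame_index: np.ndarray
    D_value: np.ndarray  # cm^2/s
    ma_window: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "frame_index", np.asarray(self.frame_index, dtype=int))
        object.__setattr__(self, "D_value", np.asarray(self.D_value, dtype=float))


@dataclass(frozen=True)
class LWFit:
    """A least-squares L = sqrt(D t) fit over one frame window."""

    D_hat: float  # cm^2/s
    window: tuple[int, int]  # inclusive frame range
    rss: float
    r2: float

    def to_dict(self, channel_id: str | None = None) -> dict:
        d = {"window": list(self.window), "D_hat": self.D_hat, "rss": self.rss, "r2": self.r2}
        if channel_id is not None:
            d = {"channel_id": channel_id, **d}
        return d


@dataclass(frozen=True)
class PhysicalParams:
    """Liquid/substrate parameters of the L-W diffusion coefficient.

    Units are CGS-consistent: R in cm, gamma_LG in dyn/cm, mu in poise
    (g/cm/s), theta in degrees; the resulting D is then in cm^2/s.
    """

    R: float
    gamma_LG: float
    theta: float
    mu: float

    def __post_init__(self) -> None:
        if self.R <= 0 or self.gamma_LG <= 0 or self.mu <= 0:
            raise ValueError("R, gamma_LG and mu must be > 0")
        if not 0 <= self.theta <= 180:
            raise ValueError("theta must be in [0, 180] degrees")


def diffusion_from_physics(p: PhysicalParams) -> float:
    """D = R * gamma_LG * cos(theta) / (2 mu); 0 (with warning) if non-wetting."""
    d = p.R * p.gamma_LG * math.cos(math.radians(p.theta)) / (2.0 * p.mu)
    if d < 0:
        warnings.warn(
            f"contact angle {p.theta} deg > 90: non-wetting liquid, no imbibition",
            stacklevel=2,
        )
        return 0.0
    return d


def pointwise_diffusion(profile: FlowProfile, ma_window: int = 10) -> DiffusionSeries:
    """Per-frame D = L^2/t, then a centered moving average of ``ma_window``.

    The t = 0 sample is excluded (division by zero); the moving window is
    centered and shrinks at both boundaries.
    """
    if len(profile) < ma_window + 1:
        raise ValueError(
            f"profile has {len(profile)} frames; need at least ma_window+1 = {ma_window + 1}"
        )
    mask = profile.frame_index > 0
    frames = profile.frame_index[mask]
    t = frames_to_seconds(frames, profile.frame_rate)
    d_raw = profile.distance_cm[mask] ** 2 / t
    smoothed = (
        pd.Series(d_raw).rolling(window=ma_window, center=True, min_periods=1).mean().to_numpy()
    )
    return DiffusionSeries(frame_index=frames, D_value=smoothed, ma_window=ma_window)


def _window_points(profile: FlowProfile, window: tuple[int, int]):
    lo, hi = window
    if lo > hi:
        raise ValueError(f"empty window {window}")
    mask = (profile.frame_index >= lo) & (profile.frame_index <= hi)
    frames = profile.frame_index[mask]
    if frames.size == 0 or lo < profile.frame_index.min() or hi > profile.frame_index.max():
        raise ValueError(f"window {window} outside profile frames")
    keep = frames > 0  # t = 0 excluded from all D computations
    t = frames_to_seconds(frames[keep], profile.frame_rate)
    L = profile.distance_cm[mask][keep]
    if t.size < 3:
        raise ValueError("need at least 3 nonzero-time points in the window")
    return t, L


def fit_lw(
    profile: FlowProfile, window: tuple[int, int] | None = None, method: str = "sqrt"
) -> LWFit:
    """Least-squares fit of L = sqrt(D t) over a frame window.

    ``method="sqrt"`` minimizes residuals on L (the default, matching the
    nonlinear square-root fit); ``method="linearized"`` regresses L^2 on t
    through the origin — a fast alternative that agrees on noiseless data.
    Both have closed forms because the model is linear in sqrt(D) (resp. D).
    """
    if window is None:
        window = (int(profile.frame_index.min()), int(profile.frame_index.max()))
    t, L = _window_points(profile, window)
    if np.all(L == 0):
        raise DegenerateFitError(f"all distances zero in window {window}")
    if method == "sqrt":
        sqrt_t = np.sqrt(t)
        sqrt_D = float(L @ sqrt_t / (t.sum()))
        D_hat = max(sqrt_D, 0.0) ** 2
    elif method == "linearized":
        D_hat = max(float((L**2) @ t / (t @ t)), 0.0)
    else:
        raise ValueError(f"unknown method {method!r}")
    pred = np.sqrt(D_hat * t)
    rss = float(np.sum((L - pred) ** 2))
    tss = float(np.sum((L - L.mean()) ** 2))
    r2 = 1.0 - rss / tss if tss > 0 else (1.0 if rss == 0 else 0.0)
    return LWFit(D_hat=D_hat, window=(int(window[0]), int(window[1])), rss=rss, r2=r2)


def compare_windows(
    profile: FlowProfile, windows: Sequence[tuple[int, int]]
) -> tuple[list[LWFit], np.ndarray]:
    """Fit each window and return fits plus the pairwise ratio matrix D_i/D_j."""
    fits = [fit_lw(profile, w) for w in windows]
    D = np.array([f.D_hat for f in fits])
    with np.errstate(divide="ignore", invalid="ignore"):
        ratios = D[:, None] / D[None, :]
    return fits, ratios


def select_detection_frame(
    profiles_by_concentration: Mapping[object, Sequence[FlowProfile]],
    method: str = "halfway",
    ma_window: int = 10,
    default_frame: int = 25,
) -> int:
    """Choose the frame at which flow distance best reports concentration.

    ``"halfway"`` pools the smoothed pointwise D series of every profile
    (smoothed per channel, then averaged), estimates the early/late
    crossover frame f_c, and returns round(f_c / 2) — the halfway point of
    the initial steep stage, which is where agglutination-driven
    differences between concentrations are largest.  Past the crossover
    the pointwise series decays as D(f) = D_late + (D_early - D_late)
    * f_c / f, so f * D(f) is linear in f with slope D_late and intercept
    (D_early - D_late) * f_c; an OLS line over the post-kink frames
    therefore gives f_c = intercept / (D_early - slope) without requiring
    the late plateau to have been reached.  Without a detectable
    crossover the configured ``default_frame`` is returned with a warning.

    ``"max_separation"`` returns the frame maximizing the one-way
    between/within variance ratio of flow distance across concentration
    groups (requires >= 2 groups).
    """
    all_profiles = [p for group in profiles_by_concentration.values() for p in group]
    if not all_profiles:
        raise ValueError("no profiles supplied")

    if method == "halfway":
        series = [pointwise_diffusion(p, ma_window=ma_window) for p in all_profiles]
        n = min(s.D_value.size for s in series)
        pooled = np.mean([s.D_value[:n] for s in series], axis=0)
        frames = series[0].frame_index[:n]
        mean_dist = np.mean(
            [p.distance_cm[p.frame_index > 0][:n] for p in all_profiles], axis=0
        )
        early = float(pooled[(frames >= 1) & (frames <= 15)].max())
        late_guess = float(np.median(pooled[-max(n // 3, 1) :]))
        if early - late_guess <= 0.05 * max(early, 1e-300):
            warnings.warn(
                "no early/late crossover detected (flat diffusion series); "
                f"returning default frame {default_frame}",
                stacklevel=2,
            )
            return default_frame
        # post-kink, unsaturated frames: D has clearly left the early level
        # and the front is still advancing (saturation bends f*D downward)
        decay = (pooled < 0.85 * early) & (frames > 15) & (mean_dist < 0.98 * mean_dist.max())
        if decay.sum() < 3:
            warnings.warn(
                f"no post-crossover frames found; returning default frame {default_frame}",
                stacklevel=2,
            )
            return default_frame
        slope, intercept = np.polyfit(frames[decay], frames[decay] * pooled[decay], 1)
        if early - slope <= 0:
            warnings.warn(
                f"degenerate crossover fit; returning default frame {default_frame}",
                stacklevel=2,
            )
            return default_frame
        f_c = intercept / (early - slope)
        return max(int(round(f_c / 2.0)), 1)

    if method == "max_separation":
        groups = [g for g in profiles_by_concentration.values() if g]
        if len(groups) < 2:
            raise ValueError("max_separation needs >= 2 concentration groups")
        n = min(len(p) for g in groups for p in g)
        best_frame, best_ratio = 0, -np.inf
        for f in range(1, n):
            per_group = [np.array([p.distance_cm[f] for p in g]) for g in groups]
            grand = np.concatenate(per_group).mean()
            between = sum(len(x) * (x.mean() - grand) ** 2 for x in per_group)
            within = sum(((x - x.mean()) ** 2).sum() for x in per_group)
            ratio = between / within if within > 0 else (np.inf if between > 0 else 0.0)
            if ratio > best_ratio:
                best_frame, best_ratio = f, ratio
        return best_frame

    raise ValueError(f"unknown method {method!r}")
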