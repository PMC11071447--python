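"""Synthetic ground-truth data: flow profiles, chip videos, assay tables.

Real recordings of the assay are not distributable, so every downstream
module is exercised against data generated here with known ground truth.
Three generators embody the assay's causal structure:

* :func:`gen_profile` — a two-regime square-root-of-time flow profile:
  Lucas-Washburn flow with a high early diffusion coefficient D_early up
  to a crossover frame, continuing with the lower D_late afterwards
  (continuous at the crossover), plus additive Gaussian distance noise.
* :func:`gen_video` — a luminance image stack rendering a profile inside
  rectangular channel ROIs (wetted pixels darkened), the fixture for the
  front tracker.
* :func:`gen_assay` — replicate signal tables chaining the model's own
  causal story: antigen concentration -> immunoagglutination (mass-action
  ODE at t = 1) -> interfacial tension (linear map) -> early-regime
  diffusion coefficient (L-W physics) -> flow distance at the detection
  frame.  More antigen means more agglutination, higher interfacial
  tension and quicker early flow — until antigen excess hooks the
  response back down.

Identical :class:`SynthConfig` (including seed) yields byte-identical
output.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np

from . import agglutination as agg
from .calibration import DoseResponse, signal_at_frame
from .flow_tracking import ChannelLayout, ChannelROI, FlowProfile, VideoStack, enforce_monotone
from .lw_model import PhysicalParams, diffusion_from_physics

__all__ = [
    "SynthConfig",
    "default_layout",
    "gen_profile",
    "gamma_from_agglutination",
    "gen_assay",
    "gen_video",
]


def default_layout(
    pixel_scale: float = 100.0, n_channels: int = 1, channel_length_cm: float = 2.1
) -> ChannelLayout:
    """Chip layout: 2.1 cm x 0.3 cm channels (length overridable for tests)."""
    w = int(round(channel_length_cm * pixel_scale))
    h = int(round(0.3 * pixel_scale))
    gap = max(h // 3, 2)
    rois = tuple(
        ChannelROI(x0=5, y0=5 + i * (h + gap), x1=5 + w, y1=5 + (i + 1) * h + i * gap,
                   axis="+x", channel_id=f"ch{i}")
        for i in range(n_channels)
    )
    return ChannelLayout(channel_rois=rois, channel_length_cm=channel_length_cm)


@dataclass(frozen=True)
class SynthConfig:
    """Study conditions for the generators.

    Flow defaults follow the two-regime structure seen on the chips: a
    steep early stage (D_early) up to ``crossover_frame`` (the initial
    ~50 frames at 30 fps), then a lower constant D_late.  The default
    magnitudes are physically consistent with the assay chain's CGS
    parameters (pore radius cm, interfacial tension dyn/cm, viscosity
    poise): D = R*gamma*cos(theta)/(2 mu) spans ~0.56-1.0 cm^2/s over
    [gamma_min, gamma_max], and D_late = 0.08 cm^2/s fills the 2.1 cm
    channel in roughly 1,300 frames at 30 fps, as real chips do.
    Normalized agglutination maps linearly onto [gamma_min, gamma_max].
    """

    seed: int = 0
    fps: float = 30.0
    n_frames: int = 300
    D_early: float = 1.0  # cm^2/s
    D_late: float = 0.08  # cm^2/s
    crossover_frame: int = 50
    noise_sd_cm: float = 0.01
    layout: ChannelLayout = field(default_factory=default_layout)
    pixel_scale: float = 100.0  # px/cm
    # video rendering
    background_level: float = 200.0
    wet_contrast: float = 80.0
    pixel_noise_sd: float = 0.0
    # assay chain: agglutination -> interfacial tension -> diffusion
    gamma_min: float = 40.0  # dyn/cm
    gamma_max: float = 72.0  # dyn/cm (DI water)
    pore_radius_cm: float = 2.8e-4
    contact_angle_deg: float = 0.0
    viscosity_poise: float = 0.01
    ag_per_pg_ml: float = 0.1  # model antigen units per pg/mL
    kinetic: agg.KineticParams = field(default_factory=agg.KineticParams)

    def __post_init__(self) -> None:
        if not self.D_early >= self.D_late > 0:
            raise ValueError("need D_early >= D_late > 0")
        if not 0 < self.crossover_frame < self.n_frames:
            raise ValueError("need 0 < crossover_frame < n_frames")
        if self.noise_sd_cm < 0:
            raise ValueError("noise_sd_cm must be >= 0")


def _truth_distance(cfg: SynthConfig, frames: np.ndarray, D_early: float | None = None) -> np.ndarray:
    d_e = cfg.D_early if D_early is None else D_early
    t = frames / cfg.fps
    t_c = cfg.crossover_frame / cfg.fps
    L_c2 = d_e * t_c
    L = np.where(t <= t_c, np.sqrt(d_e * t), np.sqrt(L_c2 + cfg.D_late * (t - t_c)))
    return np.minimum(L, cfg.layout.channel_length_cm)


def gen_profile(
    cfg: SynthConfig,
    channel_id: str = "ch0",
    D_early: float | None = None,
    rng: np.random.Generator | None = None,
) -> tuple[FlowProfile, dict]:
    """Two-regime L-W profile plus its ground truth.

    L(t) = sqrt(D_early t) up to the crossover, then
    sqrt(L_c^2 + D_late (t - t_c)) — continuous at the kink.  Gaussian
    noise of sd ``noise_sd_cm`` is added to frames >= 1, the result
    clipped at 0, monotone-enforced and capped at the channel length.
    """
    rng = np.random.default_rng(cfg.seed) if rng is None else rng
    frames = np.arange(cfg.n_frames)
    truth = _truth_distance(cfg, frames, D_early)
    noisy = truth.copy()
    if cfg.noise_sd_cm > 0:
        noisy[1:] = noisy[1:] + rng.normal(0.0, cfg.noise_sd_cm, size=cfg.n_frames - 1)
    noisy = np.clip(noisy, 0.0, cfg.layout.channel_length_cm)
    profile = enforce_monotone(
        FlowProfile(channel_id=channel_id, frame_index=frames, distance_cm=noisy,
                    frame_rate=cfg.fps)
    )
    ground_truth = {
        "D_early": cfg.D_early if D_early is None else D_early,
        "D_late": cfg.D_late,
        "crossover_frame": cfg.crossover_frame,
        "distance_cm": truth,
    }
    return profile, ground_truth


def gamma_from_agglutination(norm_agg: float, gamma_min: float, gamma_max: float) -> float:
    """Linear map from normalized agglutination in [0, 1] to interfacial tension.

    The chip data establish that agglutination raises the interfacial
    tension at the wetting front, which dominates the early flow rate; a
    linear map is the minimal assumption for that monotone link.
    """
    if not 0.0 <= norm_agg <= 1.0:
        warnings.warn(f"norm_agg {norm_agg} outside [0, 1]; clamping", stacklevel=2)
        norm_agg = min(max(norm_agg, 0.0), 1.0)
    return gamma_min + norm_agg * (gamma_max - gamma_min)


def _early_diffusion_for(cfg: SynthConfig, norm_agg: float) -> float:
    gamma = gamma_from_agglutination(norm_agg, cfg.gamma_min, cfg.gamma_max)
    return diffusion_from_physics(
        PhysicalParams(R=cfg.pore_radius_cm, gamma_LG=gamma,
                       theta=cfg.contact_angle_deg, mu=cfg.viscosity_poise)
    )


def gen_assay(
    cfg: SynthConfig,
    concentrations: Sequence[float],
    n_replicates: int = 8,
    detection_frame: int = 25,
) -> tuple[DoseResponse, dict]:
    """Replicate signal tables for a concentration series (must include 0).

    Antigen concentration (pg/mL, scaled by ``ag_per_pg_ml`` into the
    kinetic model's dimensionless ag0, so the hook peak of the default
    constants falls near 50 pg/mL) drives the agglutination dose curve at
    t = 1;
    normalized agglutination sets the interfacial tension, hence the
    early-regime diffusion coefficient, hence the noiseless flow distance
    at the detection frame.  ``n_replicates`` noisy profiles are drawn per
    concentration.  Ground truth carries the noiseless signal curve and
    the per-concentration D_early values.
    """
    concentrations = np.asarray(sorted(concentrations), dtype=float)
    if 0.0 not in concentrations:
        raise ValueError("concentrations must include the 0 negative control")
    curve = agg.dose_response(cfg.kinetic, concentrations * cfg.ag_per_pg_ml, t_sample=1.0)
    rng = np.random.default_rng(cfg.seed)
    reps, noiseless = [], []
    d_earlies = []
    for conc, norm in zip(concentrations, curve.norm_agglutination):
        d_early = _early_diffusion_for(cfg, float(norm))
        d_earlies.append(d_early)
        clean_profile, _ = gen_profile(
            replace(cfg, noise_sd_cm=0.0), D_early=d_early, rng=rng
        )
        noiseless.append(signal_at_frame(clean_profile, detection_frame))
        signals = np.empty(n_replicates)
        for r in range(n_replicates):
            prof, _ = gen_profile(cfg, D_early=d_early, rng=rng)
            signals[r] = signal_at_frame(prof, detection_frame)
        reps.append(signals)
    dr = DoseResponse(concentrations, tuple(reps))
    ground_truth = {
        "noiseless_signal_cm": np.array(noiseless),
        "D_early": np.array(d_earlies),
        "norm_agglutination": curve.norm_agglutination,
        "detection_frame": detection_frame,
    }
    return dr, ground_truth


def gen_video(
    profile: FlowProfile,
    layout: ChannelLayout | None = None,
    cfg: SynthConfig | None = None,
    profiles: Sequence[FlowProfile] | None = None,
) -> VideoStack:
    """Render profile(s) as a luminance stack over the chip layout.

    Pixels behind the front (along each ROI's flow axis) are darkened by
    ``wet_contrast``; the front column is round(L * pixel_scale).  With
    ``profiles`` given, one profile per ROI is rendered (ROI order).
    """
    cfg = cfg if cfg is not None else SynthConfig()
    layout = layout if layout is not None else cfg.layout
    plist = list(profiles) if profiles is not None else [profile]
    rois = layout.channel_rois
    if len(plist) == 1 and len(rois) > 1:
        plist = plist * len(rois)
    if len(plist) != len(rois):
        raise ValueError(f"{len(plist)} profiles for {len(rois)} ROIs")
    n_frames = min(len(p) for p in plist)
    height = max(r.y1 for r in rois) + 5
    width = max(r.x1 for r in rois) + 5
    rng = np.random.default_rng(cfg.seed + 1)
    frames = np.full((n_frames, height, width), cfg.background_level, dtype=float)
    for roi, prof in zip(rois, plist):
        extent = roi.along_extent_px
        for f in range(n_frames):
            n_wet = min(int(round(prof.distance_cm[f] * cfg.pixel_scale)), extent)
            if n_wet <= 0:
                continue
            if roi.axis == "+x":
                frames[f, roi.y0 : roi.y1, roi.x0 : roi.x0 + n_wet] -= cfg.wet_contrast
            elif roi.axis == "-x":
                frames[f, roi.y0 : roi.y1, roi.x1 - n_wet : roi.x1] -= cfg.wet_contrast
            elif roi.axis == "+y":
                frames[f, roi.y0 : roi.y0 + n_wet, roi.x0 : roi.x1] -= cfg.wet_contrast
            else:
                frames[f, roi.y1 - n_wet : roi.y1, roi.x0 : roi.x1] -= cfg.wet_contrast
    if cfg.pixel_noise_sd > 0:
        frames += rng.normal(0.0, cfg.pixel_noise_sd, size=frames.shape)
    return VideoStack(frames=frames, frame_rate=plist[0].frame_rate, pixel_scale=cfg.pixel_scale)
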