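"""Assay calibration and decision statistics.

The assay signal is the wetting-front distance at a fixed detection
frame (default frame 25, ~1 s at 30 fps).  Replicate signals per spiked
concentration form a :class:`DoseResponse`; from it this module derives

* the limit of detection (LOD): the lowest concentration whose replicates
  differ from the zero-concentration negative control by a Welch
  (unequal-variance) two-sample t-test at P < 0.05;
* a four-parameter logistic (4PL) calibration curve on log10
  concentration, with the hook (prozone) limb past the empirical peak
  excluded from the fit;
* the linear range: the widest contiguous concentration window whose
  mean-signal OLS fit reaches a minimum R^2;
* three-tier (low / middle / high) classification of unknown samples by
  inverting the calibration; and
* diluted <-> undiluted concentration conversion with the conventional
  pg/mL / ng/mL unit handling.

Each concentration-to-control comparison is made at raw P < 0.05 with no
multiple-testing correction — the field's customary LOD rule; the
resulting per-comparison false-positive rate is characterized in the
test suite.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from .flow_tracking import FlowProfile

__all__ = [
    "DoseResponse",
    "CalibrationFit",
    "TierLabel",
    "WelchResult",
    "LinearRange",
    "Concentration",
    "signal_at_frame",
    "welch_t_test",
    "find_lod",
    "fit_sigmoid",
    "linear_range",
    "classify_tier",
    "convert_dilution",
    "group_comparison",
]


@dataclass(frozen=True)
class DoseResponse:
    """Replicate signals (flow distances, cm) indexed by concentration (pg/mL)."""

    concentrations: np.ndarray
    replicates: tuple[np.ndarray, ...]  # parallel to concentrations

    def __post_init__(self) -> None:
        conc = np.asarray(self.concentrations, dtype=float)
        reps = tuple(np.asarray(r, dtype=float) for r in self.replicates)
        if len(conc) != len(reps):
            raise ValueError("one replicate array per concentration required")
        if np.any(np.diff(conc) <= 0):
            order = np.argsort(conc)
            conc, reps = conc[order], tuple(reps[i] for i in order)
        object.__setattr__(self, "concentrations", conc)
        object.__setattr__(self, "replicates", reps)

    @classmethod
    def from_dataframe(
        cls, df: pd.DataFrame, conc_col: str = "concentration_pg_ml", signal_col: str = "signal_cm"
    ) -> "DoseResponse":
        groups = df.groupby(conc_col)[signal_col]
        conc = np.array(sorted(groups.groups))
        reps = tuple(groups.get_group(c).to_numpy() for c in conc)
        return cls(conc, reps)

    def signals(self, concentration: float) -> np.ndarray:
        idx = np.flatnonzero(self.concentrations == concentration)
        if idx.size == 0:
            raise KeyError(f"no replicates at concentration {concentration}")
        return self.replicates[int(idx[0])]

    @property
    def mean(self) -> np.ndarray:
        return np.array([r.mean() for r in self.replicates])

    @property
    def sem(self) -> np.ndarray:
        return np.array([r.std(ddof=1) / math.sqrt(len(r)) if len(r) > 1 else np.nan
                         for r in self.replicates])

    @property
    def n(self) -> np.ndarray:
        return np.array([len(r) for r in self.replicates])


def signal_at_frame(profile: FlowProfile, frame: int = 25) -> float:
    """Flow distance at exactly the given frame index (no interpolation)."""
    idx = np.flatnonzero(profile.frame_index == frame)
    if idx.size == 0:
        raise IndexError(f"frame {frame} not in profile ({profile.frame_index.min()}"
                         f"..{profile.frame_index.max()})")
    return float(profile.distance_cm[int(idx[0])])


class WelchResult(NamedTuple):
    t: float
    df: float
    p: float


def welch_t_test(a: Sequence[float], b: Sequence[float]) -> WelchResult:
    """Two-sample t-test with unequal variances (Welch-Satterthwaite df).

    Degenerate samples with zero variance in both groups yield p = 1 for
    equal means and p = 0 (infinite t) otherwise.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs at least 2 observations")
    va, vb = a.var(ddof=1), b.var(ddof=1)
    na, nb = len(a), len(b)
    if va == 0 and vb == 0:
        if a.mean() == b.mean():
            return WelchResult(0.0, float(na + nb - 2), 1.0)
        warnings.warn("zero variance in both samples with unequal means", stacklevel=2)
        sign = math.copysign(1.0, a.mean() - b.mean())
        return WelchResult(sign * math.inf, float(na + nb - 2), 0.0)
    se2 = va / na + vb / nb
    t = (a.mean() - b.mean()) / math.sqrt(se2)
    df = se2**2 / ((va / na) ** 2 / (na - 1) + (vb / nb) ** 2 / (nb - 1))
    p = 2.0 * stats.t.sf(abs(t), df)
    return WelchResult(float(t), float(df), float(p))


def find_lod(dr: DoseResponse, alpha: float = 0.05) -> float | None:
    """Lowest nonzero concentration significantly above/below the control.

    The negative control is the 0-concentration group (required, n >= 2);
    each nonzero concentration is compared with it by Welch's t-test at
    raw two-sided ``alpha``; the smallest significant one is the LOD.
    Returns None when no concentration reaches significance.
    """
    if 0.0 not in dr.concentrations:
        raise ValueError("DoseResponse must contain the 0-concentration negative control")
    control = dr.signals(0.0)
    if len(control) < 2:
        raise ValueError("negative control needs n >= 2")
    for conc, reps in zip(dr.concentrations, dr.replicates):
        if conc == 0 or len(reps) < 2:
            continue
        if welch_t_test(reps, control).p < alpha:
            return float(conc)
    return None


# ---------------------------------------------------------------------------
# Calibration curve

@dataclass(frozen=True)
class CalibrationFit:
    """A fitted calibration curve (4PL sigmoid, or linear fallback).

    4PL params are (lower, upper, ec50, slope) with the logistic evaluated
    on x = log10(concentration); linear params are (intercept, slope) on
    concentration.  ``span`` is the concentration range the fit covers
    (inversion outside it sets the extrapolation flag).
    """

    model: str  # "4PL sigmoid" | "linear"
    params: tuple[float, ...]
    r2: float
    direction: str  # "increasing" | "decreasing"
    span: tuple[float, float]
    log_floor: float  # pseudo-log10 position of the 0-concentration control
    excluded_hook_concentrations: tuple[float, ...] = ()
    fallback: bool = False

    def predict(self, concentration) -> np.ndarray:
        c = np.asarray(concentration, dtype=float)
        if self.model == "4PL sigmoid":
            lower, upper, ec50, slope = self.params
            x = np.where(c > 0, np.log10(np.maximum(c, 1e-300)), self.log_floor)
            return lower + (upper - lower) / (1.0 + np.exp(-slope * (x - math.log10(ec50))))
        intercept, slope = self.params
        return intercept + slope * c

    def invert(self, signal: float) -> tuple[float, bool]:
        """Concentration producing ``signal``; second value flags extrapolation."""
        if self.model == "4PL sigmoid":
            lower, upper, ec50, slope = self.params
            lo, hi = (lower, upper) if lower < upper else (upper, lower)
            extrapolated = not lo < signal < hi
            eps = 1e-9 * max(hi - lo, 1e-12)
            y = min(max(signal, lo + eps), hi - eps)
            x = math.log10(ec50) - math.log((upper - lower) / (y - lower) - 1.0) / slope
            conc = 10.0**x
        else:
            intercept, slope = self.params
            if slope == 0:
                raise ValueError("flat linear calibration is not invertible")
            conc = (signal - intercept) / slope
            extrapolated = False
        if not self.span[0] <= conc <= self.span[1]:
            extrapolated = True
            conc = min(max(conc, self.span[0]), self.span[1])
        return float(conc), extrapolated


def _four_pl(x, lower, upper, log_ec50, slope):
    return lower + (upper - lower) / (1.0 + np.exp(-slope * (x - log_ec50)))


def fit_sigmoid(dr: DoseResponse, exclude_hook: bool = True) -> CalibrationFit:
    """Least-squares 4PL fit of mean signal on log10 concentration.

    The 0-concentration control is placed one decade below the smallest
    nonzero concentration on the log axis.  When the means show an
    interior maximum (hook effect) and enough points remain, the
    post-peak limb is excluded and recorded.  Non-convergent or flat fits
    fall back to an ordinary linear fit with ``fallback=True``.
    """
    conc = dr.concentrations
    means = dr.mean
    nonzero = conc[conc > 0]
    if len(np.unique(conc)) < 5:
        raise ValueError("need at least 5 distinct concentrations")
    log_floor = math.log10(nonzero.min()) - 1.0

    excluded: tuple[float, ...] = ()
    if exclude_hook:
        peak = int(np.argmax(means))
        declines = peak < len(means) - 1 and means[-1] < means[peak]
        if declines and peak + 1 >= 5:
            excluded = tuple(float(c) for c in conc[peak + 1 :])
            conc, means = conc[: peak + 1], means[: peak + 1]

    x = np.where(conc > 0, np.log10(np.maximum(conc, 1e-300)), log_floor)
    y = means
    span = (float(conc.min()), float(conc.max()))
    tss = float(np.sum((y - y.mean()) ** 2))

    rho = np.corrcoef(x, y)[0, 1] if np.std(y) > 0 else 0.0
    p0 = (float(y.min()), float(y.max()), float(np.median(x)), 4.0 * math.copysign(1.0, rho or 1.0))
    try:
        if np.std(y) == 0:
            raise RuntimeError("flat response")
        popt, _ = optimize.curve_fit(
            _four_pl,
            x,
            y,
            p0=p0,
            bounds=([-np.inf, -np.inf, x.min(), -np.inf], [np.inf, np.inf, x.max(), np.inf]),
            maxfev=20000,
            xtol=1e-14,
            ftol=1e-14,
        )
        lower, upper, log_ec50, slope = (float(v) for v in popt)
        rss = float(np.sum((y - _four_pl(x, *popt)) ** 2))
        r2 = 1.0 - rss / tss if tss > 0 else 1.0
        return CalibrationFit(
            model="4PL sigmoid",
            params=(lower, upper, 10.0**log_ec50, slope),
            r2=r2,
            direction="increasing" if slope >= 0 else "decreasing",
            span=span,
            log_floor=log_floor,
            excluded_hook_concentrations=excluded,
        )
    except (RuntimeError, optimize.OptimizeWarning):
        warnings.warn("sigmoid fit did not converge; falling back to linear", stacklevel=2)
        slope, intercept = np.polyfit(conc, y, 1) if np.std(y) > 0 else (0.0, float(y.mean()))
        pred = intercept + slope * conc
        rss = float(np.sum((y - pred) ** 2))
        r2 = 1.0 - rss / tss if tss > 0 else 1.0
        return CalibrationFit(
            model="linear",
            params=(float(intercept), float(slope)),
            r2=r2,
            direction="increasing" if slope >= 0 else "decreasing",
            span=span,
            log_floor=log_floor,
            excluded_hook_concentrations=excluded,
            fallback=True,
        )


class LinearRange(NamedTuple):
    conc_lo: float
    conc_hi: float
    slope: float
    r2: float


def linear_range(
    dr: DoseResponse, r2_min: float = 0.75, min_points: int = 3
) -> LinearRange | None:
    """Widest contiguous concentration window with a linear mean response.

    Every contiguous window of >= ``min_points`` concentrations is fitted
    by OLS (mean signal vs concentration); the widest window reaching
    ``r2_min`` wins, ties broken by higher R^2.  Returns None (after a
    warning with diagnostics) when no window qualifies.
    """
    conc, means = dr.concentrations, dr.mean
    if len(conc) < min_points:
        raise ValueError(f"need at least {min_points} concentrations, got {len(conc)}")
    best: tuple[int, float, LinearRange] | None = None  # (width, r2, result)
    for i in range(len(conc)):
        for j in range(i + min_points, len(conc) + 1):
            c, m = conc[i:j], means[i:j]
            res = stats.linregress(c, m)
            r2 = res.rvalue**2
            if r2 < r2_min:
                continue
            cand = (j - i, r2, LinearRange(float(c[0]), float(c[-1]), float(res.slope), float(r2)))
            if best is None or (cand[0], cand[1]) > (best[0], best[1]):
                best = cand
    if best is None:
        warnings.warn(
            f"no contiguous window of >= {min_points} concentrations reaches R^2 >= {r2_min}",
            stacklevel=2,
        )
        return None
    return best[2]


@dataclass(frozen=True)
class TierLabel:
    """Three-tier concentration call for one sample signal."""

    label: str  # "low" | "middle" | "high"
    concentration: float
    boundaries: tuple[float, float]
    extrapolated: bool = False


def classify_tier(
    signal: float, calib: CalibrationFit, cuts: tuple[float, float]
) -> TierLabel:
    """Invert the calibration and bin the concentration at the two cuts.

    A signal exactly on a cut is assigned to the higher tier.  Decreasing
    calibrations are handled by the inversion itself (a high signal maps
    to a low concentration).  Signals outside the fitted span are flagged
    extrapolated and assigned the nearest tier.
    """
    lo_cut, hi_cut = cuts
    if not lo_cut < hi_cut:
        raise ValueError("cuts must satisfy low < high")
    conc, extrapolated = calib.invert(signal)
    label = "high" if conc >= hi_cut else ("middle" if conc >= lo_cut else "low")
    return TierLabel(label=label, concentration=conc, boundaries=(float(lo_cut), float(hi_cut)),
                     extrapolated=extrapolated)


class Concentration(NamedTuple):
    value: float
    unit: str  # "pg/mL" | "ng/mL"


_UNIT_PG = {"pg/mL": 1.0, "ng/mL": 1000.0}


def convert_dilution(
    conc: float,
    dilution_fraction: float,
    direction: str,
    unit: str = "pg/mL",
) -> Concentration:
    """Convert between diluted-sample and undiluted-equivalent concentrations.

    ``dilution_fraction`` is the volume fraction of original specimen in
    the assayed sample (10% blood -> 0.10).  ``to_undiluted`` divides by
    it, ``to_diluted`` multiplies.  Units follow the reporting convention
    of the assay literature: undiluted equivalents are expressed in ng/mL
    once >= 0.1 ng/mL, diluted concentrations in pg/mL while < 1000 pg/mL
    (so 50 pg/mL at 1% dilution reads 5 ng/mL undiluted).
    """
    if not 0 < dilution_fraction <= 1:
        raise ValueError("dilution_fraction must be in (0, 1]")
    if unit not in _UNIT_PG:
        raise ValueError(f"unknown unit {unit!r}")
    pg = conc * _UNIT_PG[unit]
    if direction == "to_undiluted":
        pg /= dilution_fraction
        out_unit = "ng/mL" if pg >= 100.0 else "pg/mL"
    elif direction == "to_diluted":
        pg *= dilution_fraction
        out_unit = "pg/mL" if pg < 1000.0 else "ng/mL"
    else:
        raise ValueError(f"direction must be 'to_undiluted' or 'to_diluted', got {direction!r}")
    return Concentration(pg / _UNIT_PG[out_unit], out_unit)


def group_comparison(
    groups: Mapping[str, Sequence[float]], alpha: float = 0.05
) -> dict[tuple[str, str], tuple[WelchResult, bool]]:
    """All pairwise Welch t-tests between tiers, with significance flags."""
    names = list(groups)
    for name in names:
        if len(groups[name]) < 2:
            raise ValueError(f"group {name!r} needs n >= 2")
    out: dict[tuple[str, str], tuple[WelchResult, bool]] = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            res = welch_t_test(groups[a], groups[b])
            out[(a, b)] = (res, res.p < alpha)
    return out
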