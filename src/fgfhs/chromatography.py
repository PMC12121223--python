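"""Heparin-affinity chromatography analytics.

On a heparin column developed with a linear 0.5-2 M NaCl gradient, the
salt concentration at which a protein elutes is a direct readout of its
electrostatic affinity for the resin. Conductivity is linearly
proportional to [NaCl] over this range, so a two-parameter calibration
``conductivity = slope * M + intercept`` converts between the recorded
conductivity trace and molar salt. Peaks are located by 3-point parabolic
interpolation around the discrete absorbance maximum, the convention of
chromatography software for near-symmetric peaks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import signal as _signal
from scipy import stats

from .reference import GRADIENT_NACL_RANGE


class GradientRangeWarning(UserWarning):
    """A converted value fell outside the programmed gradient."""


@dataclass(frozen=True)
class GradientCalibration:
    """Linear conductivity <-> [NaCl] map on the gradient."""

    slope: float       # (mS/cm) per M
    intercept: float   # mS/cm
    r_squared: float = float("nan")

    def __post_init__(self) -> None:
        if not self.slope > 0:
            raise ValueError(
                f"calibration slope must be positive, got {self.slope}; "
                "check for swapped axes")


@dataclass(frozen=True)
class ElutionProfile:
    """A chromatogram: volume, conductivity trace and A280 absorbance."""

    volume: np.ndarray        # mL, strictly increasing
    conductivity: np.ndarray  # mS/cm
    a280: np.ndarray          # absorbance
    gradient_range: tuple[float, float] = GRADIENT_NACL_RANGE
    protein: str = ""

    def __post_init__(self) -> None:
        v = np.asarray(self.volume, dtype=float)
        c = np.asarray(self.conductivity, dtype=float)
        a = np.asarray(self.a280, dtype=float)
        for name, arr in (("volume", v), ("conductivity", c), ("a280", a)):
            if arr.ndim != 1 or arr.shape != v.shape:
                raise ValueError(f"{name} must match the volume grid")
            if not np.isfinite(arr).all():
                raise ValueError(f"non-finite values in {name}")
        if np.any(np.diff(v) <= 0):
            raise ValueError("volume must be strictly increasing")
        object.__setattr__(self, "volume", v)
        object.__setattr__(self, "conductivity", c)
        object.__setattr__(self, "a280", a)


def fit_calibration(pairs: Sequence[tuple[float, float]]
                    ) -> GradientCalibration:
    """Least-squares calibration from (conductivity mS/cm, [NaCl] M) pairs."""
    pairs = list(pairs)
    if len(pairs) < 2:
        raise ValueError("need at least two calibration pairs")
    cond = np.array([p[0] for p in pairs], dtype=float)
    molar = np.array([p[1] for p in pairs], dtype=float)
    if np.allclose(molar, molar[0]):
        raise ValueError("degenerate calibration: all molarities equal")
    res = stats.linregress(molar, cond)
    return GradientCalibration(slope=float(res.slope),
                               intercept=float(res.intercept),
                               r_squared=float(res.rvalue ** 2))


def calibration_from_profile(profile: ElutionProfile) -> GradientCalibration:
    """Calibration from a profile's own gradient trace.

    The recorded conductivity is regressed on the programmed linear
    [NaCl] ramp across the run volume.
    """
    lo, hi = profile.gradient_range
    v = profile.volume
    molar = lo + (hi - lo) * (v - v[0]) / (v[-1] - v[0])
    return fit_calibration(list(zip(profile.conductivity, molar)))


def conductivity_to_nacl(c: float, cal: GradientCalibration) -> float:
    """Invert the calibration; warns when outside the gradient range."""
    m = (c - cal.intercept) / cal.slope
    lo, hi = GRADIENT_NACL_RANGE
    if not lo - 1e-9 <= m <= hi + 1e-9:
        warnings.warn(
            f"converted [NaCl] {m:.3f} M outside the {lo}-{hi} M gradient",
            GradientRangeWarning, stacklevel=2)
    return float(m)


def nacl_to_conductivity(m: float, cal: GradientCalibration) -> float:
    return float(cal.slope * m + cal.intercept)


def elution_peak(profile: ElutionProfile,
                 cal: GradientCalibration | None = None
                 ) -> tuple[float, float]:
    """(peak conductivity mS/cm, peak [NaCl] M) of the main elution peak.

    The discrete A280 maximum must be interior; its position is refined by
    parabolic interpolation in the volume coordinate and read off the
    conductivity trace. When several well-separated peaks exist the global
    maximum is reported with a warning. ``cal`` defaults to the profile's
    own gradient-trace calibration.
    """
    a = profile.a280
    if np.ptp(a) <= 0:
        raise ValueError("flat absorbance trace: no elution peak")
    i = int(np.argmax(a))
    if i == 0 or i == len(a) - 1:
        raise ValueError("absorbance maximum at profile boundary; no interior peak")
    prominence = 0.2 * np.ptp(a)
    peaks, _ = _signal.find_peaks(a, prominence=prominence)
    if len(peaks) > 1:
        warnings.warn(f"{len(peaks)} separated peaks detected; reporting the "
                      "global maximum", UserWarning, stacklevel=2)
    # 3-point parabolic refinement in volume
    v0, v1, v2 = profile.volume[i - 1:i + 2]
    y0, y1, y2 = a[i - 1:i + 2]
    denom = y0 - 2 * y1 + y2
    if denom == 0:
        v_peak = float(v1)
    else:
        v_peak = float(v1 + 0.5 * (y0 - y2) / denom * (v2 - v0) / 2)
    cond_peak = float(np.interp(v_peak, profile.volume, profile.conductivity))
    if cal is None:
        cal = calibration_from_profile(profile)
    return cond_peak, conductivity_to_nacl(cond_peak, cal)


def additivity_report(single_shifts: dict[str, float],
                      combined_shift: float, combo: str) -> dict[str, float]:
    """Diagnostic for additivity of elution shifts.

    Compares the sum of single-mutation [NaCl] shifts with the measured
    shift of the combination mutant; reported, never enforced.
    """
    expected = sum(single_shifts[letter] for letter in combo)
    return {"expected_sum_M": expected, "observed_M": combined_shift,
            "difference_M": combined_shift - expected}


def read_elution_csv(path: "str | Path") -> ElutionProfile:
    """Read ``volume_mL,conductivity_mS_cm,a280`` CSV."""
    df = pd.read_csv(path)
    required = {"volume_mL", "conductivity_mS_cm", "a280"}
    if not required.issubset(df.columns):
        raise ValueError(f"elution CSV must have columns {sorted(required)}")
    df = df.sort_values("volume_mL")
    return ElutionProfile(df["volume_mL"].to_numpy(),
                          df["conductivity_mS_cm"].to_numpy(),
                          df["a280"].to_numpy())


def write_elution_csv(profile: ElutionProfile, path: "str | Path") -> None:
    pd.DataFrame({"volume_mL": profile.volume,
                  "conductivity_mS_cm": profile.conductivity,
                  "a280": profile.a280}).to_csv(path, index=False)


def elution_table(peaks: dict[str, tuple[float, float]]) -> pd.DataFrame:
    """Per-variant ``variant,peak_mS_cm,peak_NaCl_M`` summary."""
    return pd.DataFrame(
        [{"variant": k, "peak_mS_cm": c, "peak_NaCl_M": m}
         for k, (c, m) in peaks.items()])
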