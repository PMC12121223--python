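"""Two-state thermal denaturation analysis for CD and fluorescence melts.

Model
-----
A protein melting curve is treated as a two-state (native <-> unfolded)
equilibrium with a van't Hoff temperature dependence and zero heat-capacity
increment:

    K(T)  = exp[(dH / R) * (1/Tm_K - 1/T_K)]
    f_U(T) = K / (1 + K)
    y(T)  = (1 - f_U) * (bn0 + bn1*T) + f_U * (bd0 + bd1*T)

with absolute temperatures inside K only, dH the van't Hoff enthalpy at the
midpoint (kJ/mol), and linear native/denatured baselines in degC. The fit
reports Tm, dH and the four baseline parameters with standard errors from
the least-squares covariance; a smoothed-derivative peak gives an
independent, model-light Tm estimate in the tradition of peak-fitting
software. Unfolding irreversibility at fixed scan rate is ignored
(equilibrium assumption).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import lmfit
import numpy as np
import pandas as pd

R_GAS = 8.314462618e-3  # kJ/(mol*K)
CELSIUS_OFFSET = 273.15

CHANNELS = ("CD_228nm", "FL_353nm")


@dataclass(frozen=True)
class MeltingCurve:
    """A temperature scan of an optical unfolding signal."""

    temperature: np.ndarray  # degC, strictly increasing
    signal: np.ndarray
    channel: str = "CD_228nm"
    protein: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.temperature, dtype=float)
        s = np.asarray(self.signal, dtype=float)
        object.__setattr__(self, "temperature", t)
        object.__setattr__(self, "signal", s)
        if t.ndim != 1 or t.shape != s.shape:
            raise ValueError("temperature and signal must be matching 1-d arrays")
        if len(t) < 2 or np.any(np.diff(t) <= 0):
            raise ValueError("temperatures must be strictly increasing")


@dataclass(frozen=True)
class TwoStateFit:
    """Fitted two-state parameters with standard errors."""

    tm: float            # degC
    dH: float            # kJ/mol, van't Hoff at Tm
    native_intercept: float
    native_slope: float
    denatured_intercept: float
    denatured_slope: float
    stderr: dict = field(default_factory=dict)
    residual_sd: float = float("nan")
    channel: str = "CD_228nm"
    tm_derivative: float = float("nan")  # cross-check estimate

    @property
    def tm_se(self) -> float:
        return self.stderr.get("tm", float("nan"))


def fraction_unfolded(T, tm: float, dH: float):
    """f_U(T) under the two-state van't Hoff model (temperatures in degC)."""
    T_K = np.asarray(T, dtype=float) + CELSIUS_OFFSET
    tm_K = tm + CELSIUS_OFFSET
    K = np.exp((dH / R_GAS) * (1.0 / tm_K - 1.0 / T_K))
    return K / (1.0 + K)


def two_state_signal(T, tm: float, dH: float,
                     native_intercept: float, native_slope: float,
                     denatured_intercept: float, denatured_slope: float):
    """Forward melting-curve model: baselines mixed by f_U(T)."""
    T = np.asarray(T, dtype=float)
    fu = fraction_unfolded(T, tm, dH)
    native = native_intercept + native_slope * T
    denat = denatured_intercept + denatured_slope * T
    return (1.0 - fu) * native + fu * denat


class MeltFitError(RuntimeError):
    """Raised when a melt cannot be fitted reliably."""


def tm_from_derivative(curve: MeltingCurve, window: int = 5) -> float:
    """Tm from the extremum of the smoothed melt derivative.

    The signal is smoothed with a centered moving average (default 5
    points), differentiated by finite differences, and the interior
    extremum of the derivative refined by 3-point parabolic interpolation
    (exact for a symmetric peak). Raises :class:`MeltFitError` when no
    clear interior transition exists (e.g. a monotone linear trace).
    """
    t, y = curve.temperature, curve.signal
    if len(t) < 10:
        raise MeltFitError("need at least 10 points for a derivative estimate")
    if window > 1:
        kernel = np.ones(window) / window
        y = np.convolve(y, kernel, mode="same")
        # trim convolution edge effects
        m = window // 2
        t, y = t[m:len(t) - m], y[m:len(y) - m]
    d = np.gradient(y, t)
    dev = np.abs(d - np.median(d))
    i = int(np.argmax(dev))
    if i == 0 or i == len(d) - 1:
        raise MeltFitError("derivative extremum at scan boundary; no transition")
    scale = (np.max(curve.signal) - np.min(curve.signal)) / (t[-1] - t[0])
    if dev[i] < 2.0 * np.median(dev) or dev[i] < 1e-12 * max(scale, 1.0):
        raise MeltFitError("no clear unfolding transition in the scan")
    # parabolic refinement on the derivative magnitude
    y0, y1, y2 = dev[i - 1], dev[i], dev[i + 1]
    denom = y0 - 2 * y1 + y2
    shift = 0.0 if denom == 0 else 0.5 * (y0 - y2) / denom
    shift = float(np.clip(shift, -1.0, 1.0))
    if shift >= 0:
        return float(t[i] + shift * (t[min(i + 1, len(t) - 1)] - t[i]))
    return float(t[i] + shift * (t[i] - t[i - 1]))


def _initial_guess(curve: MeltingCurve) -> dict:
    t, y = curve.temperature, curve.signal
    tm0 = tm_from_derivative(curve)
    n_edge = max(3, int(0.2 * len(t)))
    bn = np.polyfit(t[:n_edge], y[:n_edge], 1)
    bd = np.polyfit(t[-n_edge:], y[-n_edge:], 1)
    # dH from the 25-75% crossing width: ln9 * R * Tm^2 / width is the
    # 10-90% relation; the 25-75% width uses ln(3)-ln(1/3) = 2 ln 3
    native = np.polyval(bn, t)
    denat = np.polyval(bd, t)
    span = denat - native
    with np.errstate(divide="ignore", invalid="ignore"):
        fu = np.clip((y - native) / np.where(span == 0, np.nan, span), 0, 1)
    tm_K = tm0 + CELSIUS_OFFSET
    inside = np.isfinite(fu)
    try:
        t25 = t[inside][np.argmax(fu[inside] >= 0.25)]
        t75 = t[inside][np.argmax(fu[inside] >= 0.75)]
        width = max(t75 - t25, 0.5)
        dH0 = 2 * np.log(3) * R_GAS * tm_K ** 2 / width
    except (ValueError, IndexError):
        dH0 = 300.0
    return {"tm": tm0, "dH": float(np.clip(dH0, 20, 2000)),
            "native_intercept": bn[1], "native_slope": bn[0],
            "denatured_intercept": bd[1], "denatured_slope": bd[0]}


def fit_two_state(curve: MeltingCurve, init: dict | None = None,
                  weights: np.ndarray | None = None) -> TwoStateFit:
    """Least-squares fit of the two-state melt model (6 parameters).

    Initialization comes from the derivative peak (Tm), line fits on the
    outer 20% of points (baselines) and the transition width (dH); any
    entry can be overridden via ``init``. The scan must bracket the
    transition with at least 5 points on each side of the midpoint.
    Raises :class:`MeltFitError` on non-convergence or a midpoint pinned at
    the scan boundary.
    """
    t, y = curve.temperature, curve.signal
    if len(t) < 20:
        raise MeltFitError("need >= 20 points spanning the transition")
    guess = _initial_guess(curve)
    if init:
        guess.update(init)

    model = lmfit.Model(two_state_signal, independent_vars=["T"])
    params = model.make_params(**guess)
    params["dH"].set(min=1e-3)
    params["tm"].set(min=float(t[0]), max=float(t[-1]))
    result = model.fit(y, params, T=t,
                       weights=weights if weights is not None else None)
    if not result.success:
        raise MeltFitError(f"two-state fit did not converge: {result.message}")
    tm_hat = float(result.params["tm"].value)
    span = float(t[-1] - t[0])
    if min(tm_hat - t[0], t[-1] - tm_hat) < 1e-6 * span:
        raise MeltFitError(
            f"fitted midpoint {tm_hat:.2f} degC sits at the scan boundary; "
            f"residual sd {np.std(result.residual):.3g}")
    n_before = int(np.sum(t < tm_hat))
    n_after = int(np.sum(t > tm_hat))
    if min(n_before, n_after) < 5:
        raise MeltFitError(
            f"only {min(n_before, n_after)} points on one side of the "
            "midpoint; scan does not bracket the transition")
    stderr = {name: (float(p.stderr) if p.stderr is not None else float("nan"))
              for name, p in result.params.items()}
    return TwoStateFit(
        tm=tm_hat,
        dH=float(result.params["dH"].value),
        native_intercept=float(result.params["native_intercept"].value),
        native_slope=float(result.params["native_slope"].value),
        denatured_intercept=float(result.params["denatured_intercept"].value),
        denatured_slope=float(result.params["denatured_slope"].value),
        stderr=stderr,
        residual_sd=float(np.std(result.residual, ddof=1)),
        channel=curve.channel,
        tm_derivative=guess["tm"] if init is None or "tm" not in init
        else tm_from_derivative(curve),
    )


def delta_tm(fit_a: TwoStateFit, fit_b: TwoStateFit) -> tuple[float, float]:
    """Midpoint shift ``tm_b - tm_a`` with quadrature-propagated error.

    Both fits must come from the same optical channel.
    """
    if fit_a.channel != fit_b.channel:
        raise ValueError(
            f"channel mismatch: {fit_a.channel} vs {fit_b.channel}")
    d = fit_b.tm - fit_a.tm
    se = float(np.sqrt(np.nansum([fit_a.tm_se ** 2, fit_b.tm_se ** 2])))
    return d, se


def read_melting_csv(path: "str | Path") -> list[MeltingCurve]:
    """Read ``temp_C,signal,channel`` CSV, one curve per channel."""
    df = pd.read_csv(path)
    required = {"temp_C", "signal", "channel"}
    if not required.issubset(df.columns):
        raise ValueError(f"melting CSV must have columns {sorted(required)}")
    curves = []
    for channel, grp in df.groupby("channel", sort=False):
        grp = grp.sort_values("temp_C")
        curves.append(MeltingCurve(grp["temp_C"].to_numpy(),
                                   grp["signal"].to_numpy(), str(channel)))
    return curves


def write_melting_csv(curves: "list[MeltingCurve] | MeltingCurve",
                      path: "str | Path") -> None:
    if isinstance(curves, MeltingCurve):
        curves = [curves]
    frames = [pd.DataFrame({"temp_C": c.temperature, "signal": c.signal,
                            "channel": c.channel}) for c in curves]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def stability_table(fits: dict[str, dict[str, TwoStateFit]],
                    reference: str) -> pd.DataFrame:
    """Per-variant Tm summary with shifts against a reference variant.

    ``fits`` maps variant -> channel -> fit; channels are reported side by
    side the way melting-temperature tables are usually printed.
    """
    rows = []
    for variant, by_channel in fits.items():
        row: dict[str, float | str] = {"variant": variant}
        for channel, fit in by_channel.items():
            ref_fit = fits[reference][channel]
            shift, shift_se = delta_tm(ref_fit, fit)
            key = "cd" if channel.startswith("CD") else "fl"
            row[f"tm_{key}"] = fit.tm
            row[f"se_{key}"] = fit.tm_se
            row[f"dT_{key}"] = shift
        rows.append(row)
    return pd.DataFrame(rows)
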