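"""Biolayer-interferometry sensorgram models and global kinetic fitting.

Model
-----
Binding of an analyte at concentration C (uM) to an immobilized ligand is
described by one or two independent 1:1 pseudo-first-order site
populations ("heterogeneous ligand" when two). Per site i:

    association:  R_i(t) = Rmax_i * C/(C + Kd_i) * (1 - exp(-(kon_i*C + koff_i)*t))
    dissociation: R_i(t) = R_i(t_assoc) * exp(-koff_i*(t - t_assoc))

with kon in 1/(uM*s), koff in 1/s, Kd_i = koff_i/kon_i in uM. Rates and
Rmax are shared across analyte concentrations in the global fit; the
reported (kon, koff, K_D) triple comes from the dominant site (larger
Rmax). Mass transport and analyte depletion are neglected, matching the
assumptions of vendor fitting software. Input traces are assumed
reference-subtracted; :func:`subtract_reference` handles paired traces.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import lmfit
import numpy as np
import pandas as pd


@dataclass(frozen=True)
class Sensorgram:
    """One reference-subtracted BLI trace at a single analyte concentration."""

    time: np.ndarray        # s, strictly increasing, 0 at association start
    response: np.ndarray    # sensor units
    concentration: float    # uM
    t_assoc: float          # s, association phase length
    ligand: str = ""
    analyte: str = ""

    def __post_init__(self) -> None:
        t = np.asarray(self.time, dtype=float)
        r = np.asarray(self.response, dtype=float)
        object.__setattr__(self, "time", t)
        object.__setattr__(self, "response", r)
        if t.ndim != 1 or t.shape != r.shape:
            raise ValueError("time and response must be matching 1-d arrays")
        if np.any(np.diff(t) <= 0):
            raise ValueError("time must be strictly increasing")
        if self.concentration <= 0:
            raise ValueError("analyte concentration must be positive")
        if not 0 < self.t_assoc <= t[-1]:
            raise ValueError("t_assoc must fall inside the time range")

    @property
    def association_mask(self) -> np.ndarray:
        return self.time <= self.t_assoc

    @property
    def phases(self) -> np.ndarray:
        return np.where(self.association_mask, "assoc", "dissoc")


@dataclass(frozen=True)
class KineticsFit:
    """Globally fitted rate constants; one row per site."""

    kon: tuple[float, ...]       # 1/(uM*s)
    koff: tuple[float, ...]      # 1/s
    rmax: tuple[float, ...]      # sensor units
    stderr: dict = field(default_factory=dict)
    residual_sd: float = float("nan")

    @property
    def n_sites(self) -> int:
        return len(self.kon)

    @property
    def reported_site(self) -> int:
        """Index of the dominant (largest-Rmax) site."""
        return int(np.argmax(self.rmax))

    @property
    def kd_reported(self) -> float:
        i = self.reported_site
        return kd_from_rates(self.kon[i], self.koff[i])

    @property
    def kd(self) -> tuple[float, ...]:
        return tuple(kd_from_rates(a, d) for a, d in zip(self.kon, self.koff))


class KineticsFitError(RuntimeError):
    """Raised when a sensorgram fit fails or collapses."""


def _site_response(t: np.ndarray, t_assoc: float, C: float,
                   kon: float, koff: float, rmax: float) -> np.ndarray:
    kd = koff / kon
    req = rmax * C / (C + kd)
    kobs = kon * C + koff
    assoc = req * (1.0 - np.exp(-kobs * np.minimum(t, t_assoc)))
    r_end = req * (1.0 - np.exp(-kobs * t_assoc))
    dissoc = r_end * np.exp(-koff * np.maximum(t - t_assoc, 0.0))
    return np.where(t <= t_assoc, assoc, dissoc)


def model_response(t, phase: str, params: "KineticsFit | dict", C: float,
                   t_assoc: float | None = None):
    """Evaluate the (multi-site) binding model for one phase.

    ``phase`` is ``"association"`` (t measured from injection start) or
    ``"dissociation"`` (t measured from dissociation start, requiring
    ``t_assoc`` to know where association ended).
    """
    t = np.asarray(t, dtype=float)
    if isinstance(params, dict):
        kon, koff, rmax = (np.atleast_1d(params[k]) for k in ("kon", "koff", "rmax"))
    else:
        kon, koff, rmax = params.kon, params.koff, params.rmax
    if any(v <= 0 for v in (*kon, *koff)) or C <= 0:
        raise ValueError("rates and concentration must be positive")
    if phase == "association":
        total = np.zeros_like(t)
        for a, d, r in zip(kon, koff, rmax):
            req = r * C / (C + d / a)
            total = total + req * (1.0 - np.exp(-(a * C + d) * t))
        return total
    if phase == "dissociation":
        if t_assoc is None:
            raise ValueError("dissociation phase needs t_assoc")
        total = np.zeros_like(t)
        for a, d, r in zip(kon, koff, rmax):
            req = r * C / (C + d / a)
            r_end = req * (1.0 - np.exp(-(a * C + d) * t_assoc))
            total = total + r_end * np.exp(-d * t)
        return total
    raise ValueError(f"unknown phase {phase!r}")


def kd_from_rates(kon: float, koff: float) -> float:
    """Equilibrium dissociation constant K_D = koff/kon (uM)."""
    if kon <= 0 or koff <= 0:
        raise ValueError("rates must be positive")
    return koff / kon


def fold_change(kd_ref: float, kd_new: float) -> float:
    """Affinity gain of a new variant over a reference: Kd_ref / Kd_new."""
    if kd_ref <= 0 or kd_new <= 0:
        raise ValueError("dissociation constants must be positive")
    return kd_ref / kd_new


def _initial_rates(sensorgrams: Sequence[Sensorgram]) -> tuple[float, float, float]:
    """(kon, koff, rmax) starting values from phase shapes.

    koff: log-linear regression on the dissociation tail of the
    highest-concentration trace. kon: slope of k_obs (from time-to-63% of
    the association plateau) against concentration.
    """
    top = max(sensorgrams, key=lambda s: s.concentration)
    mask = ~top.association_mask
    td, rd = top.time[mask] - top.t_assoc, top.response[mask]
    pos = rd > max(rd.max(), 1e-12) * 1e-3
    if pos.sum() >= 2:
        slope = np.polyfit(td[pos], np.log(rd[pos]), 1)[0]
        koff0 = max(-slope, 1e-4)
    else:
        koff0 = 0.1
    kobs, concs = [], []
    for s in sensorgrams:
        m = s.association_mask
        ta, ra = s.time[m], s.response[m]
        plateau = ra[-1]
        if plateau <= 0:
            continue
        i = int(np.argmax(ra >= (1 - 1 / np.e) * plateau))
        if ta[i] > 0:
            kobs.append(1.0 / ta[i])
            concs.append(s.concentration)
    if len(kobs) >= 2:
        kon0 = max(np.polyfit(concs, kobs, 1)[0], 1e-4)
    elif kobs:
        kon0 = max((kobs[0] - koff0) / concs[0], 1e-4)
    else:
        kon0 = 1.0
    kd0 = koff0 / kon0
    top_plateau = top.response[top.association_mask][-1]
    rmax0 = max(top_plateau * (top.concentration + kd0) / top.concentration, 1e-6)
    return kon0, koff0, rmax0


def global_fit(sensorgrams: Sequence[Sensorgram], n_sites: int = 1,
               init: dict | None = None) -> KineticsFit:
    """Global least-squares fit across concentrations and both phases.

    Rates and per-site Rmax are shared by all traces. With ``n_sites=2``
    the starting point splits Rmax 60/40 and spreads the rates by a factor
    of 3 either side of the single-site guess. Raises
    :class:`KineticsFitError` on non-convergence or when a rate collapses
    onto its positivity bound.
    """
    if len(sensorgrams) < 1:
        raise ValueError("need at least one sensorgram")
    if n_sites not in (1, 2):
        raise ValueError("n_sites must be 1 or 2")
    kon0, koff0, rmax0 = _initial_rates(sensorgrams)
    if init:
        kon0 = init.get("kon", kon0)
        koff0 = init.get("koff", koff0)
        rmax0 = init.get("rmax", rmax0)

    params = lmfit.Parameters()
    if n_sites == 1:
        starts = [(kon0, koff0, rmax0)]
    else:
        starts = [(kon0 * 3, koff0 / 3, rmax0 * 0.6),
                  (kon0 / 3, koff0 * 3, rmax0 * 0.4)]
    for i, (a, d, r) in enumerate(starts, start=1):
        params.add(f"kon{i}", value=a, min=1e-8)
        params.add(f"koff{i}", value=d, min=1e-8)
        params.add(f"rmax{i}", value=r, min=1e-8)

    def residual(p: lmfit.Parameters) -> np.ndarray:
        out = []
        for s in sensorgrams:
            model = np.zeros_like(s.time)
            for i in range(1, n_sites + 1):
                model += _site_response(
                    s.time, s.t_assoc, s.concentration,
                    p[f"kon{i}"].value, p[f"koff{i}"].value, p[f"rmax{i}"].value)
            out.append(model - s.response)
        return np.concatenate(out)

    result = lmfit.minimize(residual, params, method="leastsq")
    if not result.success:
        raise KineticsFitError(f"global fit did not converge: {result.message}")
    vals = {k: float(result.params[k].value) for k in result.params}
    for name, v in vals.items():
        if name.startswith(("kon", "koff")) and v <= 2e-8:
            raise KineticsFitError(
                f"parameter {name} collapsed onto its lower bound; "
                "the data do not constrain this site")
    order = sorted(range(1, n_sites + 1),
                   key=lambda i: -vals[f"rmax{i}"])  # dominant site first
    stderr = {}
    for rank, i in enumerate(order, start=1):
        for base in ("kon", "koff", "rmax"):
            p = result.params[f"{base}{i}"]
            stderr[f"{base}{rank}"] = (float(p.stderr)
                                       if p.stderr is not None else float("nan"))
    return KineticsFit(
        kon=tuple(vals[f"kon{i}"] for i in order),
        koff=tuple(vals[f"koff{i}"] for i in order),
        rmax=tuple(vals[f"rmax{i}"] for i in order),
        stderr=stderr,
        residual_sd=float(np.std(result.residual, ddof=1)),
    )


def binding_screen(sensorgrams: Sequence[Sensorgram], threshold: float
                   ) -> dict[str, tuple[bool, float]]:
    """Qualitative bound / not-bound call per ligand.

    A ligand is called bound when the maximum association-phase response of
    any of its traces exceeds ``threshold``. Returns
    ``ligand -> (bound, max_response)``.
    """
    out: dict[str, tuple[bool, float]] = {}
    for s in sensorgrams:
        peak = float(s.response[s.association_mask].max(initial=0.0))
        prev = out.get(s.ligand, (False, -np.inf))[1]
        best = max(peak, prev)
        out[s.ligand] = (best > threshold, best)
    return out


def subtract_reference(trace: Sensorgram, reference: Sensorgram) -> Sensorgram:
    """Subtract a paired reference-sensor trace sampled on the same grid."""
    if trace.time.shape != reference.time.shape or \
            not np.allclose(trace.time, reference.time):
        raise ValueError("trace and reference must share a time grid")
    return Sensorgram(trace.time, trace.response - reference.response,
                      trace.concentration, trace.t_assoc,
                      trace.ligand, trace.analyte)


def read_sensorgram_csv(path: "str | Path") -> list[Sensorgram]:
    """Read ``time_s,response,conc_uM,phase`` CSV, one trace per concentration."""
    df = pd.read_csv(path)
    required = {"time_s", "response", "conc_uM", "phase"}
    if not required.issubset(df.columns):
        raise ValueError(f"sensorgram CSV must have columns {sorted(required)}")
    ligand = str(df["ligand"].iloc[0]) if "ligand" in df.columns else ""
    traces = []
    for conc, grp in df.groupby("conc_uM", sort=True):
        grp = grp.sort_values("time_s")
        assoc = grp[grp["phase"] == "assoc"]
        if assoc.empty:
            raise ValueError(f"trace at {conc} uM has no association phase")
        t_assoc = float(assoc["time_s"].max())
        traces.append(Sensorgram(grp["time_s"].to_numpy(),
                                 grp["response"].to_numpy(),
                                 float(conc), t_assoc, ligand=ligand))
    return traces


def write_sensorgram_csv(sensorgrams: Sequence[Sensorgram],
                         path: "str | Path") -> None:
    frames = []
    for s in sensorgrams:
        frames.append(pd.DataFrame({
            "time_s": s.time, "response": s.response,
            "conc_uM": s.concentration, "phase": s.phases,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def kinetics_table(fits: dict[str, KineticsFit], reference: str
                   ) -> pd.DataFrame:
    """Per-variant kinetics summary with fold-change against a reference."""
    kd_ref = fits[reference].kd_reported
    rows = []
    for variant, fit in fits.items():
        i = fit.reported_site
        kon, koff = fit.kon[i], fit.koff[i]
        kon_se = fit.stderr.get(f"kon{i + 1}", float("nan"))
        koff_se = fit.stderr.get(f"koff{i + 1}", float("nan"))
        kd = fit.kd_reported
        kd_se = kd * float(np.hypot(kon_se / kon, koff_se / koff))
        rows.append({
            "variant": variant,
            "kon": kon, "kon_se": kon_se,
            "koff": koff, "koff_se": koff_se,
            "kd": kd, "kd_se": kd_se,
            "fold_vs_ref": fold_change(kd_ref, kd),
        })
    return pd.DataFrame(rows)
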