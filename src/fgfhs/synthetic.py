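"""Synthetic instrument and structure data with known ground truth.

Every input the pipeline consumes can be generated here: toy ligand-bound
structures with controllable residue-ligand distances and planted clashes,
toy alignments with planted basic-residue support, BLI sensorgrams, thermal
melts and heparin-column elution profiles. Defaults mirror the acquisition
settings of the experiments being emulated: 200/400/800 nM analyte with
450 s association + 450 s dissociation at 2 Hz for BLI; 20-90 degC scans
in 0.5 degC steps for melts; a linear 0.5-2 M NaCl gradient for elution.
Noise is Gaussian and homoscedastic, defaulting to 1% of the dynamic
range; all randomness flows through explicit seeds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from . import reference
from .alignment import Alignment, BASIC_RESIDUES
from .chromatography import ElutionProfile, GradientCalibration
from .kinetics import Sensorgram, _site_response
from .structure import Atom, Structure
from .thermostability import MeltingCurve, two_state_signal

#: Default relative noise: 1% of the signal's dynamic range.
DEFAULT_NOISE_FRACTION = 0.01


@dataclass(frozen=True)
class SyntheticSpec:
    """Shared knobs of the simulators: seed, noise level, grid step."""

    seed: int = 0
    noise_sd: float | None = None  # signal units; None -> 1% of range
    step: float | None = None      # s (sensorgrams) or degC (melts)

    def __post_init__(self) -> None:
        if self.noise_sd is not None and self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        if self.step is not None and self.step <= 0:
            raise ValueError("sampling step must be positive")

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)

    def resolve_noise(self, dynamic_range: float) -> float:
        if self.noise_sd is not None:
            return self.noise_sd
        return DEFAULT_NOISE_FRACTION * dynamic_range


# ---------------------------------------------------------------------------
# toy structures

_RESIDUE_SPACING = 3.8  # A between consecutive CA atoms
_LIGAND_NAME = "LIG"
_OBSTACLE_NAME = "OBS"
_CLASH_OBSTACLE_OFFSET = 3.0  # A beyond CB along the side-chain direction


def make_toy_complex(n_residues: int, ligand_offset: float,
                     clash_positions: tuple[int, ...] = (),
                     seed: int = 0) -> Structure:
    """A poly-alanine chain with a pseudo-ligand at a known distance.

    The backbone runs along x with 3.8 A residue spacing; CB atoms point
    along +y, so idealized side-chain extension proceeds in +y. A rigid
    5-atom ligand (residue ``LIG``) lies above the chain's five central
    residues at height ``ligand_offset`` along +z: each of those residues
    has its minimum heavy-atom ligand distance exactly ``ligand_offset``
    (via CA), and flanking residues are progressively farther.

    Residues listed in ``clash_positions`` (1-based) get a fixed obstacle
    heteroatom (residue ``OBS``) placed on the side-chain extension path,
    3 A beyond CB: the wild-type alanine does not clash with it, but any
    extended substitution does. The geometry is deterministic; ``seed`` is
    accepted for interface symmetry with the other generators.
    """
    if n_residues < 3:
        raise ValueError("need at least 3 residues")
    if ligand_offset <= 0:
        raise ValueError("ligand_offset must be positive")
    for p in clash_positions:
        if not 1 <= p <= n_residues:
            raise ValueError(f"clash position {p} outside 1..{n_residues}")

    atoms: list[Atom] = []
    for i in range(1, n_residues + 1):
        x = i * _RESIDUE_SPACING
        for name, element, (dx, dy, dz) in (
                ("N", "N", (-0.8, -1.1, 0.0)),
                ("CA", "C", (0.0, 0.0, 0.0)),
                ("C", "C", (0.8, -1.1, 0.0)),
                ("O", "O", (1.9, -1.3, 0.0)),
                ("CB", "C", (0.0, 1.53, 0.0))):
            atoms.append(Atom("A", i, "", "ALA", name, element,
                              x + dx, dy, dz))

    mid = (n_residues + 1) // 2
    lig_center = mid * _RESIDUE_SPACING
    for k in range(5):
        x = lig_center + (k - 2) * _RESIDUE_SPACING
        atoms.append(Atom("L", 900 + k, "", _LIGAND_NAME, f"C{k + 1}", "C",
                          x, 0.0, ligand_offset, is_ligand=True))

    for j, p in enumerate(sorted(set(clash_positions))):
        x = p * _RESIDUE_SPACING
        atoms.append(Atom("O", 800 + j, "", _OBSTACLE_NAME, "O1", "O",
                          x, 1.53 + _CLASH_OBSTACLE_OFFSET, 0.0))
    return Structure(tuple(atoms))


def toy_ligand_residues(n_residues: int) -> tuple[int, ...]:
    """The residues of a toy complex sitting directly under the ligand."""
    mid = (n_residues + 1) // 2
    return tuple(p for p in range(mid - 2, mid + 3) if 1 <= p <= n_residues)


# ---------------------------------------------------------------------------
# sensorgrams

def simulate_sensorgram(kon: float, koff: float, rmax: float,
                        concentrations: tuple[float, ...] =
                        reference.BLI_CONCENTRATIONS_UM,
                        t_assoc: float = reference.BLI_T_ASSOC_S,
                        t_dissoc: float = reference.BLI_T_DISSOC_S,
                        spec: SyntheticSpec = SyntheticSpec(),
                        ligand: str = "", analyte: str = ""
                        ) -> list[Sensorgram]:
    """Single-site sensorgrams at several analyte concentrations.

    R(t) follows the pseudo-first-order 1:1 model used by
    :mod:`fgfhs.kinetics`; Gaussian noise of sd ``spec.noise_sd`` (default
    1% of Rmax) is added pointwise. Sampling is 2 Hz unless ``spec.step``
    overrides it.
    """
    if kon <= 0 or koff <= 0 or rmax <= 0:
        raise ValueError("kon, koff and rmax must be positive")
    if not concentrations:
        raise ValueError("need at least one analyte concentration")
    if any(c <= 0 for c in concentrations):
        raise ValueError("concentrations must be positive")
    step = spec.step if spec.step is not None else 0.5
    rng = spec.rng()
    sd = spec.resolve_noise(rmax)
    t = np.arange(0.0, t_assoc + t_dissoc + step / 2, step)
    out = []
    for conc in concentrations:
        r = _site_response(t, t_assoc, conc, kon, koff, rmax)
        if sd > 0:
            r = r + rng.normal(0.0, sd, size=r.shape)
        out.append(Sensorgram(t, r, conc, t_assoc, ligand=ligand,
                              analyte=analyte))
    return out


# ---------------------------------------------------------------------------
# melting curves

def simulate_melting_curve(tm: float, dH: float,
                           baselines: tuple[float, float, float, float]
                           | None = None,
                           direction: str = "increasing",
                           channel: str = "FL_353nm",
                           spec: SyntheticSpec = SyntheticSpec()
                           ) -> MeltingCurve:
    """A two-state melt on the 20-90 degC scan window.

    ``baselines`` is (native intercept, native slope, denatured intercept,
    denatured slope); when omitted, a generic pair is chosen so the signal
    rises (``direction="increasing"``, e.g. Trp fluorescence at 353 nm) or
    falls (``"decreasing"``, e.g. ellipticity magnitude) across the
    transition. Noise defaults to 1% of the baseline separation at Tm.
    """
    lo, hi = reference.MELT_T_MIN, reference.MELT_T_MAX
    if not lo <= tm <= hi:
        raise ValueError(f"tm {tm} outside the {lo}-{hi} degC scan window")
    if dH <= 0:
        raise ValueError("dH must be positive")
    if baselines is None:
        if direction == "increasing":
            baselines = (0.05, 0.0005, 0.95, 0.0005)
        elif direction == "decreasing":
            baselines = (0.95, -0.0005, 0.05, -0.0005)
        else:
            raise ValueError("direction must be 'increasing' or 'decreasing'")
    step = spec.step if spec.step is not None else 0.5
    t = np.arange(lo, hi + step / 2, step)
    y = two_state_signal(t, tm, dH, *baselines)
    bn0, bn1, bd0, bd1 = baselines
    span = abs((bd0 + bd1 * tm) - (bn0 + bn1 * tm))
    sd = spec.resolve_noise(span)
    if sd > 0:
        y = y + spec.rng().normal(0.0, sd, size=y.shape)
    return MeltingCurve(t, y, channel=channel)


# ---------------------------------------------------------------------------
# toy alignments

_NON_BASIC = "ACDEFGHILMNPQSTVWY"  # 20 minus K and R


def make_toy_alignment(target_row: str, support_map: dict[int, int],
                       n_rows: int, target_id: str = "target",
                       seed: int = 0) -> Alignment:
    """An alignment with exact planted basic-residue support per column.

    ``support_map`` maps 0-based column -> number of K/R residues among
    the ``n_rows - 1`` non-target rows; every unlisted column gets zero.
    Non-basic cells are drawn uniformly from the 18 non-basic residues.
    """
    if n_rows < 2:
        raise ValueError("need at least 2 rows")
    width = len(target_row)
    for col, count in support_map.items():
        if not 0 <= col < width:
            raise ValueError(f"support column {col} outside 0..{width - 1}")
        if not 0 <= count <= n_rows - 1:
            raise ValueError(
                f"column {col}: support {count} impossible with "
                f"{n_rows - 1} non-target rows")
    rng = np.random.default_rng(seed)
    others = np.empty((n_rows - 1, width), dtype="<U1")
    non_basic = np.array(list(_NON_BASIC))
    basic = np.array(sorted(BASIC_RESIDUES))
    for j in range(width):
        count = support_map.get(j, 0)
        col = rng.choice(non_basic, size=n_rows - 1)
        if count:
            rows = rng.choice(n_rows - 1, size=count, replace=False)
            col[rows] = rng.choice(basic, size=count)
        others[:, j] = col
    ids = (target_id,) + tuple(f"row{i + 1}" for i in range(n_rows - 1))
    rows = (target_row.upper(),) + tuple("".join(r) for r in others)
    return Alignment(ids, rows)


# ---------------------------------------------------------------------------
# elution profiles

def simulate_elution(calibration: GradientCalibration, peak_nacl: float,
                     spec: SyntheticSpec = SyntheticSpec(),
                     total_volume: float = 30.0,
                     peak_width: float = 0.8,
                     peak_height: float = 100.0) -> ElutionProfile:
    """A chromatogram with a Gaussian peak at a known elution molarity.

    The gradient trace is linear from 0.5 to 2 M NaCl over
    ``total_volume`` mL, converted to conductivity by ``calibration``;
    the A280 peak (sd ``peak_width`` mL) is centered where the gradient
    crosses ``peak_nacl``. Noise defaults to 1% of the peak height.
    """
    lo, hi = reference.GRADIENT_NACL_RANGE
    if not lo <= peak_nacl <= hi:
        raise ValueError(f"peak_nacl {peak_nacl} outside the {lo}-{hi} M gradient")
    step = spec.step if spec.step is not None else 0.05
    v = np.arange(0.0, total_volume + step / 2, step)
    molar = lo + (hi - lo) * v / total_volume
    cond = calibration.slope * molar + calibration.intercept
    v_peak = total_volume * (peak_nacl - lo) / (hi - lo)
    a = peak_height * np.exp(-0.5 * ((v - v_peak) / peak_width) ** 2)
    sd = spec.resolve_noise(peak_height)
    if sd > 0:
        a = a + spec.rng().normal(0.0, sd, size=a.shape)
    return ElutionProfile(v, cond, a)
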