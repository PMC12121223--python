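"""Packaged reference data for the FGF1 heparan-sulfate biosensor panel.

Holds the human FGF1 sequence in its three numbering frames, the named
mutation sets that define the engineered variant panel, and the published
characterization tables (melting temperatures, BLI kinetics, heparin-column
elution points) used as presets by the simulators, examples and the CLI.
"""

from __future__ import annotations

from types import MappingProxyType

#: Human FGF1 precursor (UniProt P05230, 155 aa), transcribed in-repo.
#: Cross-checked against the documented anchor residues of the
#: Gimenez-Gallego (1-140) frame: C16, S17, Q40, S47, L72, C83, H93, Y94,
#: N95, W107 (the single tryptophan), N114, S116 and C117 all match.
FGF1_FULL_LENGTH = (
    "MAEGEITTFTALTEKFNLPPGNYKKPKLLYCSNGGHFLRILPDGTVDGTRDRSDQHIQLQ"
    "LSAESVGEVYIKSTETGQYLAMDTDGLLYGSQTPNEECLFLERLEENHYNTYISKKHAEK"
    "NWFVGLKKNGSCKRGPRTHYGQKAILFLPLPVSSD"
)

#: Truncated 140-residue form (full-length residues 16-155); positions in
#: this string, 1-based, are Gimenez-Gallego numbers.
FGF1_GG = FGF1_FULL_LENGTH[15:]

#: Expression construct: Met-Ala leader + full-length residues 21-154.
FGF1_CONSTRUCT = "MA" + FGF1_FULL_LENGTH[20:154]

#: HS/HSPG-affinity point mutations, by their single-letter design label.
#: Positions are Gimenez-Gallego numbers.
HS_SITE_MUTATIONS = MappingProxyType({
    "A": "N114R",
    "B": "S116R",
    "C": "S17K",
    "D": "L72R",
})

#: FGFR-binding disruption set shared by every panel variant.
FGFR_MUTATIONS = ("Y94A", "N95A")

#: Stabilizing set shared by every panel variant (raises wild-type Tm by
#: over 20 degC).
STABILITY_MUTATIONS = ("C16S", "Q40P", "S47I", "C83S", "H93G", "C117S")

#: The 13 panel members: the FGFR-dead stabilized scaffold plus every
#: produced combination of the A-D affinity mutations.
PANEL_COMBINATIONS = (
    "", "A", "B", "C", "D", "AB", "BC", "BD", "CD", "ABC", "ABD", "BCD", "ABCD",
)


def variant_name(combo: str) -> str:
    """Panel naming convention: '' -> FGF1_HS, 'BCD' -> FGF1_HS_BCD."""
    return "FGF1_HS" + (f"_{combo}" if combo else "")


#: Published melting temperatures (degC) from CD (228 nm ellipticity) and
#: intrinsic Trp107 fluorescence (353 nm) melts:
#: variant -> (tm_cd, se_cd, dtm_cd, tm_fl, se_fl, dtm_fl).
PUBLISHED_TM = MappingProxyType({
    "FGF1_HS":     (60.82, 1.09, 0.00, 60.69, 0.02, 0.00),
    "FGF1_HS_B":   (61.35, 0.07, 0.53, 62.92, 0.04, 2.23),
    "FGF1_HS_C":   (61.10, 0.09, 0.28, 61.70, 0.02, 1.00),
    "FGF1_HS_D":   (65.84, 0.09, 5.02, 64.64, 0.02, 3.95),
    "FGF1_HS_BC":  (61.95, 0.14, 1.13, 64.53, 0.02, 3.83),
    "FGF1_HS_BD":  (65.92, 0.03, 5.10, 64.44, 0.06, 3.75),
    "FGF1_HS_CD":  (66.21, 0.03, 5.39, 64.81, 0.02, 4.12),
    "FGF1_HS_BCD": (66.15, 0.03, 5.33, 66.32, 0.02, 5.63),
})

#: Published glypican-4 BLI kinetics:
#: variant -> (kon 1/(uM*s), kon_se, koff 1/s, koff_se, kd uM, kd_se).
PUBLISHED_KINETICS = MappingProxyType({
    "FGF1_HS":     (0.19, 0.04, 1.43, 0.19, 7.37, 1.71),
    "FGF1_HS_B":   (0.24, 0.01, 0.64, 0.03, 2.64, 0.21),
    "FGF1_HS_C":   (0.27, 0.01, 0.61, 0.02, 2.27, 0.13),
    "FGF1_HS_D":   (0.33, 0.02, 0.34, 0.02, 1.01, 0.10),
    "FGF1_HS_BC":  (6.83, 1.65, 0.52, 0.12, 0.08, 0.03),
    "FGF1_HS_BD":  (0.71, 0.02, 0.30, 0.01, 0.42, 0.02),
    "FGF1_HS_CD":  (0.29, 0.01, 0.24, 0.01, 0.81, 0.03),
    "FGF1_HS_BCD": (0.42, 0.01, 0.15, 0.00, 0.35, 0.01),
})

#: Published heparin-column elution points on the 0.5-2 M NaCl gradient:
#: variant -> (peak conductivity mS/cm, peak [NaCl] M).
PUBLISHED_ELUTION = MappingProxyType({
    "FGF1_HS":     (120.19, 1.37),
    "FGF1_HS_B":   (125.86, 1.46),
    "FGF1_HS_C":   (126.34, 1.47),
    "FGF1_HS_D":   (125.89, 1.46),
    "FGF1_HS_BC":  (129.27, 1.52),
    "FGF1_HS_BD":  (131.43, 1.55),
    "FGF1_HS_CD":  (131.06, 1.55),
    "FGF1_HS_BCD": (134.27, 1.60),
})

#: BLI acquisition settings used for the panel: analyte concentrations in
#: uM and phase durations in s.
BLI_CONCENTRATIONS_UM = (0.2, 0.4, 0.8)
BLI_T_ASSOC_S = 450.0
BLI_T_DISSOC_S = 450.0

#: Thermal scan window, degC.
MELT_T_MIN = 20.0
MELT_T_MAX = 90.0

#: Heparin-column gradient endpoints, M NaCl.
GRADIENT_NACL_RANGE = (0.5, 2.0)
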