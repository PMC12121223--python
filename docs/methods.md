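# Methods

This note documents the models, rules and numerical choices behind the
`fgfhs` pipeline: how candidate heparan-sulfate (HS) affinity mutations are
designed from an alignment and a ligand-bound structure, how the variant
panel is defined, and how the three characterization assays — thermal
melts, biolayer-interferometry (BLI) kinetics and heparin-column elution —
are modelled and fitted. It also states what the synthetic-data generators
emulate and what they deliberately do not.

## Scaffold, numbering and the variant panel

All mutation positions use the Gimenez-Gallego convention: positions 1–140
of the classic 140-residue FGF1 form, which corresponds to residues 16–155
of the 155-residue precursor (UniProt P05230). The expressed construct is a
Met-Ala leader followed by precursor residues 21–154 (136 residues); its
first FGF1 residue (construct position 3) is therefore Gimenez-Gallego
position 6, and Gimenez-Gallego 1–5, like the leader itself, have no
counterpart in the other frame. Conversions are exact bijections on their
covered ranges and raise on unmapped positions rather than shifting
silently — an intentional guard against off-by-offset mutagenesis errors.
The packaged precursor sequence was cross-checked at thirteen anchor
residues (the three free cysteines C16/C83/C117, the single tryptophan
W107, and all twelve mutated sites).

The panel consists of 13 variants. Each carries two fixed sets on the FGF1
scaffold: Y94A + N95A, which abolish FGFR engagement, and the stabilizing
sextet C16S, Q40P, S47I, C83S, H93G, C117S. On top of these, every produced
combination of the four HS-affinity mutations A = N114R, B = S116R,
C = S17K, D = L72R defines a named variant (FGF1_HS carries none;
FGF1_HS_BCD carries B, C and D; all twelve combinations plus the scaffold).
`apply_mutations` verifies the wild-type residue at every site before any
edit, so a wrong numbering frame fails loudly.

## Mutation design rules

Candidate sites must satisfy three filters, evaluated in order:

1. **Basic support in the paralog alignment.** A column qualifies when the
   target row holds a non-basic, non-gap residue and at least
   `min_support = 3` of the other rows carry K or R. Histidine is not
   counted as basic. The target's own residue never counts, and gaps in
   other rows contribute nothing while the absolute threshold stays at 3.
   Columns where the target is gapped are never candidates.
2. **Ligand vicinity.** The site's minimum heavy-atom distance to the bound
   glycosaminoglycan must not exceed `vicinity_cutoff = 8.0` Å — roughly a
   salt bridge plus the reach of an extended basic side chain. The cutoff
   is a tunable argument/CLI flag, since "near the ligand" is inherently a
   judgment call.
3. **No steric clash after substitution.** The site is mutated in silico to
   arginine (preferred) or lysine and screened: a clash is any heavy
   side-chain atom closer than `clash_cutoff = 2.4` Å (center-to-center) to
   a heavy atom of the ligand or of a non-adjacent residue; the backbone of
   the two sequence neighbours is excluded, their side chains are not.

Side chains are modelled as idealized straight chains: the new residue's
heavy atoms beyond CB are placed collinearly along the CA→CB direction at
1.53 Å per atom (branched side chains are flattened). This is a
single-conformation surrogate for rotamer search — conservative in the
sense that a contact relievable by a rotamer flip may still be flagged; the
cutoff is tunable to compensate, and rotamer exploration is out of scope.
Mutations from glycine synthesize CB at the idealized tetrahedral position;
mutations to glycine truncate to the backbone.

Surviving sites are ranked by (ligand distance ascending, basic support
descending). The ranking key is a pragmatic choice — closer sites are more
likely to form contacts, support breaks ties — and no claim is made that it
reproduces any particular historical ordering; when both K and R pass at a
site, arginine is preferred (deterministic tie-break, reflecting the
prevalence of arginine among validated HS-affinity mutations). Alignment
columns map to structure residues through the ungapped target sequence
index and a numbering frame; structures with insertion codes are rejected
rather than guessed at.

Conservation shading for alignment figures follows the usual two-tier rule:
a column is identically conserved when one residue occurs at least three
times, class-conserved when no residue repeats three times but three
not-all-identical residues share one physicochemical class. The class
partition (positive {K,R,H}, negative {D,E}, polar {S,T,N,Q,C,Y,W},
nonpolar {A,V,L,I,M,F,P,G}) is a standard one and is configurable.

## Two-state thermal denaturation

Melts (CD ellipticity at 228 nm, or Trp107 fluorescence at 353 nm) are
fitted with the two-state van't Hoff model with ΔCp = 0:

    K(T) = exp[(ΔH/R)(1/T_m − 1/T)]   (absolute temperatures)
    f_U  = K/(1+K)
    y(T) = (1−f_U)(b_n0 + b_n1·T) + f_U(b_d0 + b_d1·T)

Six parameters (T_m, ΔH, four baseline coefficients) are fitted by
unweighted least squares (lmfit/Levenberg–Marquardt), with standard errors
from the covariance. ΔCp is fixed at zero because it is unidentifiable from
a single melt; the van't Hoff ΔH is therefore the midpoint-slope enthalpy
only. Unfolding irreversibility at fixed scan rate is ignored (equilibrium
assumption). Initialization: T_m from the smoothed-derivative peak,
baselines from line fits on the outer 20% of points, ΔH from the 25–75%
transition width. Fits whose midpoint lands at a scan boundary, or scans
with fewer than five points on either side of the midpoint, raise a
diagnostic error instead of returning a silently bad fit.

A second, model-light estimator reports the extremum of the smoothed
finite-difference derivative (5-point moving average, configurable) refined
by 3-point parabolic interpolation, in the tradition of peak-fitting
software. For a genuinely symmetric derivative peak it returns the exact
center; note that the van't Hoff transition itself is slightly asymmetric
in T (the exponent is linear in 1/T), so on noiseless two-state data the
derivative estimate sits a fraction of a grid step below the fitted T_m —
the two are cross-checks, with the full fit being the reported value.
Midpoint shifts between variants are differences of fitted T_m with
standard errors combined in quadrature, and require matching channels.

## BLI kinetics

Sensorgrams follow the pseudo-first-order 1:1 model, per site i:

    association:  R_i(t) = Rmax_i · C/(C+K_D,i) · (1 − e^{−(kon_i·C+koff_i)t})
    dissociation: R_i(t) = R_i(t_assoc) · e^{−koff_i (t−t_assoc)}

with kon in 1/(µM·s), koff in 1/s, K_D = koff/kon in µM. Concentrations are
µM throughout; nM inputs are converted at the I/O boundary. The
"heterogeneous ligand" variant is the sum of two independent sites. The
global fit shares rates and per-site Rmax across all concentrations and
both phases; when two sites are fitted, the dominant (larger-Rmax) site
supplies the single reported (kon, koff, K_D) triple, with both sites
retained in the full result. Initialization: koff from a log-linear fit of
the dissociation tail of the highest concentration, kon from the regression
of apparent rates (time to 63% of plateau) on concentration; both
overridable. Positivity is enforced by bounds, and a rate collapsing onto
its bound raises a diagnostic error. Mass-transport limitation and analyte
depletion are neglected, matching the assumptions of vendor fitting
software; input traces are assumed reference-subtracted (a helper subtracts
paired traces). A qualitative screen calls a ligand "bound" when the
maximum association response exceeds a threshold — the analysis used for
receptor-binding knockouts, where the readout is presence/absence rather
than a rate.

## Heparin-column elution

On a linear 0.5–2 M NaCl gradient, conductivity is proportional to [NaCl];
the calibration `conductivity = slope·M + intercept` is always fitted from
data — either tabulated (conductivity, molarity) pairs or a profile's own
gradient trace — never hard-coded, because the buffer's baseline
conductivity is instrument- and buffer-dependent. Elution peaks are located
at the discrete A280 maximum refined by 3-point parabolic interpolation
(the chromatography-software convention for near-symmetric peaks;
peak-maximum rather than centroid is assumed for tabulated values).
Monotone or flat traces raise; multiple well-separated peaks produce a
warning and the global maximum. Because the calibration map is strictly
monotone, ranking variants by peak conductivity and by converted molarity
is the same ranking. Additivity of single-mutation shifts is reported as a
diagnostic only, never enforced.

## Synthetic data

The generators produce every input with known ground truth, under explicit
seeds (no hidden global state; identical spec ⇒ bit-identical output):

- **Sensorgrams**: the forward model above, sampled at 2 Hz over 450 s
  association + 450 s dissociation at 0.2/0.4/0.8 µM — the acquisition
  settings of the experiments being emulated.
- **Melts**: the two-state model on a 20–90 °C window at 0.5 °C steps
  (the instruments scan continuously at 1 °C/min; grid density is a free
  choice).
- **Chromatograms**: a linear 0.5→2 M gradient over 30 mL with a Gaussian
  peak (σ = 0.8 mL) centered at the requested molarity.
- **Toy complexes**: a poly-alanine chain on a regular backbone with a
  rigid 5-atom pseudo-ligand at an exactly known minimum distance from the
  central residues, and optional obstacle atoms placed on the side-chain
  extension path so a designated position clashes only after substitution.
  Ligand chemistry is irrelevant to the geometric filters under test.
- **Toy alignments**: columns with exactly planted K/R support counts among
  non-target rows, all other cells drawn from non-basic residues.

Noise is Gaussian, homoscedastic, defaulting to 1% of the dynamic range — a
conservative figure for modern BLI/CD instruments; real instrument noise
(drift, heteroscedasticity, baseline steps, air spikes) is richer. Passing
the recovery tests therefore demonstrates correctness of the models and
estimators under the stated noise model, not robustness to every instrument
artifact. The toy structures likewise exercise the geometric filters, not
protein-like packing; the design demo on real FGF paralog data requires an
externally obtained alignment and heparin-bearing structure and is not part
of the test suite.

## Problem sizes and tolerances

Noiseless simulate→fit round trips are required to recover generating
parameters to ≤1e-6 relative error. Stochastic recovery checks use 50
replicate melts (mean T_m bias < 0.1 °C at 1% noise) and 25 replicate
sensorgram sets (median kon within 5%), sizes at which the estimators'
bias is clearly resolved while the whole suite stays fast. Brute-force
all-pairs oracles for distances and clash detection run on structures of at
most a few hundred atoms and must agree exactly (1e-9 Å). The acceptance
script reruns each stage once at these same settings with seed-derived
noise realizations.

## Known limitations

- No rotamer search, energy model or electrostatics in the design step; the
  clash screen can flag relievable contacts (tunable cutoff).
- ΔCp = 0 and equilibrium two-state only; no multi-state or scan-rate
  dependent unfolding, no chemical denaturation.
- No mass-transport or conformational-change BLI models; no parsing of
  proprietary instrument exports (generic CSV schemas only).
- No column-thermodynamics model for elution; peak-maximum convention.
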