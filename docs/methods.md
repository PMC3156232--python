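# Methods

## Property engine

GRAVY is the arithmetic mean of per-residue hydropathy. The default scale
is Kyte–Doolittle; Fauchère–Pliška (side-chain octanol transfer free
energies) and the Eisenberg normalized consensus are shipped as named
alternatives because published GRAVY figures for this class of libraries
do not always state their scale or normalization, and the two common
scales disagree (notably tryptophan: −0.9 under Kyte–Doolittle, +2.25
under Fauchère–Pliška). We make no attempt to match any particular
printed GRAVY number; the scale is an explicit argument everywhere.

Two charge conventions:

* **Formal** (used for library design labels): K/R = +1, D/E = −1,
  everything else 0, histidine counted neutral at pH 7, termini excluded.
  This integer bookkeeping reproduces the standard corner annotations of
  the pilot grid (+4 at the cationic/hydrophobic corner, −2 at E6, 0 at
  E4).
* **Henderson–Hasselbalch**: each ionizable group contributes
  ±1/(1+10^{±(pH−pKa)}); side-chain pKas default to the EMBOSS set
  (C 8.5, D 3.9, E 4.1, H 6.5, K 10.8, R 12.5, Y 10.1) with free termini
  at 8.6/3.6, both pluggable. The charge is strictly decreasing in pH, so
  the pI is the unique zero crossing, located by bisection on [0, 14]
  with tolerance 1e−4 pH units (max 100 iterations). If the charge never
  changes sign on the physical range (e.g. acids only with termini
  excluded), the nearer bracket endpoint is returned; a sequence with no
  ionizable groups raises an error. The test suite checks bisection
  against an exhaustive vectorized pH-grid scan.

## Pilot matrix design

The pilot library is a 6×6 grid of 9-mers on the fixed periodicity
template HHPPHHPPH (hydrophobic slots 1, 2, 5, 6, 9; charged slots
3, 4, 7, 8). A *residue ladder* supplies six 5-residue hydrophobic levels
(rows, mean hydropathy strictly decreasing) and six 4-residue charge
levels (columns, formal charge decreasing +4, +3, +2, 0, −1, −2). Only
two member sequences of the original pilot grid are published verbatim
(E4 = AMKDAMERM, E6 = AMQDAMNEM); the remaining 34 are unrecoverable, so
the shipped ladder (`data/pilot_ladder.yaml`, version pilot-v1) is one
canonical assignment satisfying the published constraints: composition
pools (W/F/L/I-rich down to A/V/M-rich; K/R/H-rich across to D/E-rich),
both monotone gradients under the default scale, the two sequence
anchors, and the corner charges. Because tryptophan is hydrophilic on the
Kyte–Doolittle scale, the aromatic-rich top rows use it sparingly to keep
the row gradient monotone. Tests therefore assert properties (gradients,
anchors, cardinality), never non-anchor sequences. Generation is fully
deterministic: same ladder, byte-identical FASTA.

Rows are labeled A–F, columns 1–6 (1-based).

## Refinement

**In-Plane.** Four corner peptides define bilinear (GRAVY, pI) targets on
a 4×4 grid: GRAVY varies down the rows, pI across the columns, with steps
of (corner difference)/3 — strictly smaller than the pilot's steps. Each
cell is realized on the pilot template by greedy residue substitution
starting from the nearest corner: positions scanned left to right,
candidate residues from the ladder pools in lexicographic order, first
improvement of the normalized objective
|ΔGRAVY|/range + |ΔpI|/range accepted; passes repeat until a fixed point
(max 30). This is deterministic and keeps realized row-mean GRAVY
monotone down rows and pI monotone along columns for the default corners;
a target further than 0.35 GRAVY units from the realized value (outside
the pool's reach) is effectively clamped and logged. The pI axis is
realized more coarsely than the GRAVY axis because the polar pool offers
only seven distinct pKa patterns.

**Orthogonal.** The In-Plane diagonal (4 peptides) becomes the columns of
a 4×4 grid whose rows carry four periodicity masks: block (HHHHHPPPP),
3:3 alternation (HHHPPPHHH), the pilot mask (HHPPHHPPH), and strict
alternation (HPHPHPHPH). For odd length 9 the per-mask H/P counts are a
design choice: 5H/4P for block, pilot, and alternating; 6H/3P for 3:3.
Repacking splits a sequence into hydrophobic-class and polar-class
residues by the source mask and lays them onto the target mask preserving
within-class order; when class sizes differ, the excess residues are
reassigned by hydropathy rank (most hydrophobic polar-class residues
promoted first, least hydrophobic hydrophobic-class residues demoted
first, ties broken by position). Composition is always preserved
(anagram property), and repacking is invertible when class sizes match.
Row C (the pilot mask) reproduces the input diagonal verbatim.

## Isotherm analysis

Absorbance is assumed strictly proportional to free peptide in the
supernatant, the implicit assumption behind C_bound = C₀(1 − A_f/A_i).
Negative computed binding (possible under measurement noise at low
depletion) is clamped to zero with a logged warning. Surface area treats
cells as discrete spheres: area = count·π·d². Bound surface density is
C_bound·V/area, with the assay volume an explicit required input.

`fit_langmuir` is nonlinear least squares (scipy) initialized from the
double-reciprocal linearization 1/(P/A) = 1/N + 1/(K_a·N·C_eq). The
default weighting is heteroscedastic with σ ∝ C_eq: under the depletion
readout, multiplicative absorbance noise enters the bound density with a
standard deviation proportional to the free concentration, and weighting
accordingly roughly halves the parameter error at 5% noise relative to
ordinary least squares. Uniform weighting is available. Standard errors
come from the parameter covariance; `r` is the correlation of observed
vs fitted densities.

`classify_isotherm` compares the Langmuir fit (ordinary least squares,
for likelihood comparability) against a line through the origin by
small-sample-corrected AIC and returns "other" when the winner's r² is
below 0.8. Two-site and cooperative models are out of scope and fall
into "other".

## Simulators

**Pulldown.** Mass balance C₀V = C_eq·V + A·K_a·N·C_eq/(1+K_a·C_eq)
rearranges to the quadratic
K_a·V·C_eq² + (V + K_a·N·A − K_a·C₀·V)·C_eq − C₀·V = 0, whose unique
non-negative root is taken in closed form (residual < 1e−12·C₀ by test).
Emitted absorbances are A_i = 1 and A_f = (C_eq/C₀)(1+ε) with
multiplicative Gaussian ε — the noise model is a choice, documented here,
and pluggable by post-processing samples. Initial concentrations must be
positive (the ratio readout is undefined at C₀ = 0); the default grids
run 10 points from 1 µM, to 100 µM for ordinary assays and 500 µM when
the capacity is high enough that saturation is only approached there.
The benchmark geometry is 7.5×10⁶ cells of 1.0 µm diameter in 100 µL.
The stochastic recovery benchmark (5% noise, 200 replicates) uses
K_a = 5.6×10⁴ L/mol with N = 7×10⁻⁴ mol/m² — affinity and capacity each
at the level actually measured for refined binders in this assay class —
because parameter recovery from a depletion readout is only well-posed
when an appreciable fraction of peptide binds; with a 100-fold smaller
capacity the depletion signal at 100 µM falls near the noise floor and
no fitting method recovers K_a reliably.

**Fingerprint.** A surface archetype (charge affinity with sign, a
non-negative hydrophobic affinity, baseline ratio ≥ 1, log-noise sd)
produces per-peptide log-scores
S = w_q·max(0, −q·charge_affinity) + w_h·max(0, GRAVY)·hydro_affinity
with q the formal charge and GRAVY under Fauchère–Pliška — chosen for
this forward model because it is a transfer free energy, positive for
hydrophobic residues, so the hydrophobic reward grades across the whole
library (under Kyte–Doolittle nearly every library member has negative
GRAVY and the term would vanish). Ratios are baseline·e^{S+ε}. This
score is deliberately simple and monotone; it is test plumbing, not a
claim about real surface chemistry — real profiles reflect specific
wall components (e.g. exopolysaccharides) that no two-parameter
archetype captures, so passing the classification benchmark shows the
fingerprint machinery works, not that real strains are separable. The
four default archetypes (anionic, cationic, hydrophobic, amphiphilic
surfaces) were chosen once for separability at log-noise 0.1 and are
frozen; the seeded benchmark (4 archetypes × 50 draws) is reproducible
exactly run to run.

**Images.** Disks at one intensity level on a flat background with
optional Gaussian pixel noise, plus exact class masks. No PSF or
illumination modeling; region selection in real experiments is manual,
and this package deliberately takes masks or intensity lists as input
rather than implementing segmentation.

## Fingerprint analysis conventions

Ratios are multiplicative in exposure and gain, so similarity operates on
log-ratios; the default is Spearman rank correlation (invariant to any
monotone per-experiment response), with cosine available. Classification
is nearest-reference with the margin best-minus-second; exact ties break
by label order with a warning. No published numeric identification rule
exists for peptide-library fingerprints; this classifier is a stated
convention of the package. Pools partition the library row-major
(4 pools of 9, subpools of 3 by default); deconvolution validates call
consistency across levels and returns every position on an all-positive
path, so a positive subpool without individual calls contributes all its
members as candidates.

## Problem sizes and determinism

Default test and acceptance workloads are desk-scale by construction:
36-peptide designs, 10-concentration isotherms, 200-replicate noise
studies, 200-draw classification benchmarks. Every stochastic component
takes an explicit seed (numpy `default_rng`) and all generators are
bit-reproducible given (parameters, seed).

## Known limitations

* The ladder realizes one canonical pilot library; other assignments
  satisfy the same constraints, and non-anchor sequences are not claimed
  to match any previously synthesized library.
* The greedy In-Plane search optimizes cells independently; it guarantees
  determinism and, empirically for the default pools, monotone realized
  axes, but not global optimality of |realized − target|.
* Langmuir fitting assumes single-site equilibrium binding; multistep
  isotherms are only flagged ("other"), never modeled.
* The fingerprint forward model ignores steric, sequence-order, and
  specific-receptor effects by design.
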