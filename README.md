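# pepmatrix

Sparse-matrix peptide library design, refinement, and quantitative analysis
of surface-binding screens.

## The problem

Biological surfaces — bacterial cell walls, yeast and mammalian cell
membranes, mineralized tissues — present bulk physicochemical signatures
dominated by charge and hydrophobicity. Rather than screening enormous
random peptide libraries against such surfaces, a *sparse matrix* samples
the two-dimensional hydrophobicity × charge space of short amphipathic
peptides at wide intervals: a 6×6 grid of 36 9-mers is often enough to
find binders against any surface probed. Hits are then refined with a
second small library, either by interpolating the same two properties at
finer steps between the corner hits (**In-Plane** refinement) or by holding
composition fixed and varying the spatial periodicity of hydrophobic vs
hydrophilic residues (**Orthogonal** refinement).

`pepmatrix` is a toolkit for scientists running this workflow: it designs
the libraries, computes the governing physicochemical descriptors, analyzes
the two standard quantitative readouts, and ships forward simulators so the
whole pipeline can be exercised and validated on synthetic data.

## What it computes

**Descriptors.** GRAVY (grand average of hydropathicity, the residue-mean
hydropathy under Kyte–Doolittle, Fauchère–Pliška, or Eisenberg scales),
formal net charge at a given pH (K/R = +1, D/E = −1, H and termini 0), a
Henderson–Hasselbalch titration charge, and the isoelectric point pI found
by bisection of the monotone charge–pH curve.

**Binding isotherms.** A pulldown assay measures labeled-peptide absorbance
before (A_i) and after (A_f) exposure to cells; the bound concentration is
C_bound = C₀(1 − A_f/A_i). With cells modeled as discrete spheres
(area = count·π·d²), bound moles per m² against the free concentration
C_eq follows the Langmuir isotherm

    P/A = K_a·N·C_eq / (1 + K_a·C_eq)

with association constant K_a (L/mol) and monolayer capacity N (mol/m²),
fitted by weighted nonlinear least squares with a double-reciprocal start.
Isotherms are classified as Langmuir, linear (nonspecific), or other.

**Fingerprints.** Per-peptide fluorescence is quantified as the ratio of
cell-region to background intensity; the grid of ratios is an organism's
binding profile. Profiles are compared by rank correlation of log-ratios
and unknowns classified against references. Hierarchical pooled screening
(4 pools of 9 → subpools of 3 → singles) resolves one hit in 10 assays.

## Worked example

Generate the pilot library and inspect the two tooth-binding anchors:

```
$ pepmatrix design --out pilot.fasta --summary pilot.tsv
wrote 36 peptides to pilot.fasta

$ pepmatrix props AMKDAMERM AMQDAMNEM
[
  {
    "id": "AMKDAMERM",
    "sequence": "AMKDAMERM",
    "gravy": -0.6777777777777777,
    "net_charge": 0,
    "pI": 6.494327545166016
  },
  {
    "id": "AMQDAMNEM",
    "sequence": "AMQDAMNEM",
    "gravy": -0.5222222222222221,
    "net_charge": -2,
    "pI": 3.550067901611328
  }
]
```

AMKDAMERM (grid cell E4) is uncharged at pH 7 and AMQDAMNEM (E6) carries
−2 — the two peptides share hydrophobic content but differ in charge,
which is why they discriminate between enamel-like and dentin-like
surfaces. Simulate a depletion assay for a surface with
K_a = 5.6×10⁴ L/mol and N = 0.31×10⁻⁴ mol/m² and refit it:

```
$ pepmatrix simulate pulldown --ka 5.6e4 --n 0.31e-4 --out assay.csv
$ pepmatrix isotherm assay.csv
{
  "sim": {
    "Ka": 56000.00000000036,
    "N": 3.0999999999999934e-05,
    "se_Ka": 8.380812471980073e-11,
    "se_N": 3.456279618614203e-20,
    "r": 1.0,
    "model": "langmuir"
  }
}
```

The fitter recovers the generating parameters to machine precision on
noiseless data; under 5% absorbance noise the median relative error stays
below 15% (see the test suite).

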