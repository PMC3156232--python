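"""Physicochemical property engine for short peptides.

Computes the grand average of hydropathicity (GRAVY), net charge at a given
pH (formal or Henderson–Hasselbalch), and the isoelectric point (pI).

GRAVY is the arithmetic mean of per-residue hydropathy values under a chosen
scale.  Three scales are shipped: Kyte–Doolittle (the default),
Fauchère–Pliška side-chain transfer free energies, and the Eisenberg
normalized consensus scale.

Two charge conventions are supported:

``formal``
    Integer bookkeeping at physiological pH: Lys/Arg +1, Asp/Glu −1,
    His and the termini 0.  This is the convention used to label peptide
    library corners ("charge = +4 at pH 7.0").

``henderson_hasselbalch``
    Continuous titration model.  Each ionizable group contributes its
    Henderson–Hasselbalch fractional charge; the pI is the unique pH at
    which the total crosses zero (the charge is strictly decreasing in pH).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np

from .errors import AlphabetError, PHRangeError, UndefinedPIError

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
_AA_SET = frozenset(AMINO_ACIDS)


@dataclass(frozen=True)
class PeptideSequence:
    """A peptide with an optional grid position inside a matrix library.

    ``row``/``col`` are the matrix coordinates (row letter, 1-based column)
    when the peptide is a member of a :class:`~pepmatrix.design.MatrixLibrary`.
    """

    id: str
    sequence: str
    row: str | None = None
    col: int | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise AlphabetError("sequence must be non-empty")
        for i, ch in enumerate(self.sequence, start=1):
            if ch not in _AA_SET:
                raise AlphabetError(
                    f"invalid residue {ch!r} at position {i} in sequence "
                    f"{self.id!r} (expected one of {AMINO_ACIDS})"
                )
        if self.col is not None and self.col < 1:
            raise ValueError("column index must be >= 1")

    def __len__(self) -> int:
        return len(self.sequence)

    @property
    def grid_position(self) -> tuple[str, int] | None:
        if self.row is None or self.col is None:
            return None
        return (self.row, self.col)


def as_peptide(seq: "PeptideSequence | str", id: str = "") -> PeptideSequence:
    """Coerce a plain string to a validated :class:`PeptideSequence`."""
    if isinstance(seq, PeptideSequence):
        return seq
    return PeptideSequence(id=id or seq, sequence=seq)


@dataclass(frozen=True)
class HydropathyScale:
    """A named per-residue hydropathy scale (all 20 residues, finite values)."""

    name: str
    values: dict[str, float]

    def __post_init__(self) -> None:
        missing = _AA_SET - set(self.values)
        extra = set(self.values) - _AA_SET
        if missing or extra:
            raise ValueError(
                f"scale {self.name!r} must cover exactly the 20 standard "
                f"residues (missing {sorted(missing)}, extra {sorted(extra)})"
            )
        if not all(math.isfinite(v) for v in self.values.values()):
            raise ValueError(f"scale {self.name!r} has non-finite values")

    def __getitem__(self, residue: str) -> float:
        return self.values[residue]


KYTE_DOOLITTLE = HydropathyScale(
    "kyte-doolittle",
    {
        "A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5,
        "Q": -3.5, "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5,
        "L": 3.8, "K": -3.9, "M": 1.9, "F": 2.8, "P": -1.6,
        "S": -0.8, "T": -0.7, "W": -0.9, "Y": -1.3, "V": 4.2,
    },
)

FAUCHERE_PLISKA = HydropathyScale(
    "fauchere-pliska",
    {
        "A": 0.31, "R": -1.01, "N": -0.60, "D": -0.77, "C": 1.54,
        "Q": -0.22, "E": -0.64, "G": 0.00, "H": 0.13, "I": 1.80,
        "L": 1.70, "K": -0.99, "M": 1.23, "F": 1.79, "P": 0.72,
        "S": -0.04, "T": 0.26, "W": 2.25, "Y": 0.96, "V": 1.22,
    },
)

EISENBERG_CONSENSUS = HydropathyScale(
    "eisenberg-consensus",
    {
        "A": 0.62, "R": -2.53, "N": -0.78, "D": -0.90, "C": 0.29,
        "Q": -0.85, "E": -0.74, "G": 0.48, "H": -0.40, "I": 1.38,
        "L": 1.06, "K": -1.50, "M": 0.64, "F": 1.19, "P": 0.12,
        "S": -0.18, "T": -0.05, "W": 0.81, "Y": 0.26, "V": 1.08,
    },
)

SCALES: dict[str, HydropathyScale] = {
    s.name: s for s in (KYTE_DOOLITTLE, FAUCHERE_PLISKA, EISENBERG_CONSENSUS)
}

# EMBOSS pKa set: side chains plus free termini.
EMBOSS_SIDE_CHAIN_PKAS: dict[str, float] = {
    "C": 8.5, "D": 3.9, "E": 4.1, "H": 6.5, "K": 10.8, "R": 12.5, "Y": 10.1,
}
EMBOSS_TERMINAL_PKAS: tuple[float, float] = (8.6, 3.6)  # (amino, carboxyl)

_BASIC = frozenset("KRH")
_ACIDIC = frozenset("DECY")


@dataclass(frozen=True)
class ChargeModel:
    """Charge convention: formal integers or Henderson–Hasselbalch titration."""

    mode: str = "formal"  # {"formal", "henderson_hasselbalch"}
    side_chain_pkas: dict[str, float] = field(
        default_factory=lambda: dict(EMBOSS_SIDE_CHAIN_PKAS)
    )
    terminal_pkas: tuple[float, float] = EMBOSS_TERMINAL_PKAS
    include_termini: bool = True

    def __post_init__(self) -> None:
        if self.mode not in ("formal", "henderson_hasselbalch"):
            raise ValueError(f"unknown charge mode {self.mode!r}")
        for k, v in self.side_chain_pkas.items():
            if not 0.0 < v < 14.0:
                raise ValueError(f"pKa of {k} out of (0, 14): {v}")
        for v in self.terminal_pkas:
            if not 0.0 < v < 14.0:
                raise ValueError(f"terminal pKa out of (0, 14): {v}")


FORMAL_MODEL = ChargeModel(mode="formal")
HH_MODEL = ChargeModel(mode="henderson_hasselbalch")


def gravy(seq: PeptideSequence | str, scale: HydropathyScale = KYTE_DOOLITTLE) -> float:
    """Grand average of hydropathicity: mean per-residue scale value."""
    pep = as_peptide(seq)
    return sum(scale[ch] for ch in pep.sequence) / len(pep)


def net_charge(
    seq: PeptideSequence | str,
    pH: float = 7.0,
    model: ChargeModel = FORMAL_MODEL,
):
    """Net charge (elementary-charge units) at ``pH`` under ``model``.

    ``pH`` may be a numpy array in Henderson–Hasselbalch mode, in which case
    an array of charges is returned (used by titration-curve scans).
    """
    pep = as_peptide(seq)
    scalar = np.isscalar(pH)
    ph = np.asarray(pH, dtype=float)
    if np.any(ph < 0.0) or np.any(ph > 14.0):
        raise PHRangeError(f"pH must lie in [0, 14], got {pH}")

    if model.mode == "formal":
        s = pep.sequence
        q = (s.count("K") + s.count("R")) - (s.count("D") + s.count("E"))
        return q if scalar else np.full_like(ph, float(q))

    charge = np.zeros_like(ph)
    for ch in pep.sequence:
        pka = model.side_chain_pkas.get(ch)
        if pka is None:
            continue
        if ch in _BASIC:
            charge += 1.0 / (1.0 + 10.0 ** (ph - pka))
        else:
            charge -= 1.0 / (1.0 + 10.0 ** (pka - ph))
    if model.include_termini:
        amino, carboxyl = model.terminal_pkas
        charge += 1.0 / (1.0 + 10.0 ** (ph - amino))
        charge -= 1.0 / (1.0 + 10.0 ** (carboxyl - ph))
    return float(charge) if scalar else charge


def _n_ionizable(pep: PeptideSequence, model: ChargeModel) -> int:
    n = sum(1 for ch in pep.sequence if ch in model.side_chain_pkas)
    if model.include_termini:
        n += 2
    return n


def isoelectric_point(
    seq: PeptideSequence | str,
    model: ChargeModel = HH_MODEL,
    tol: float = 1e-4,
    max_iter: int = 100,
) -> float:
    """pH at which the Henderson–Hasselbalch net charge crosses zero.

    Located by bisection on [0, 14]; uniqueness follows from the charge
    being strictly decreasing in pH.  If the charge never changes sign on
    the physical range (e.g. acidic groups only with termini excluded),
    the nearer bracket endpoint is returned.
    """
    pep = as_peptide(seq)
    if model.mode != "henderson_hasselbalch":
        model = replace(model, mode="henderson_hasselbalch")
    if _n_ionizable(pep, model) == 0:
        raise UndefinedPIError(
            f"sequence {pep.id!r} has no ionizable groups under this model"
        )
    lo, hi = 0.0, 14.0
    f_lo = net_charge(pep, lo, model)
    f_hi = net_charge(pep, hi, model)
    if f_lo <= 0.0:
        return lo
    if f_hi >= 0.0:
        return hi
    for _ in range(max_iter):
        mid = 0.5 * (lo + hi)
        if net_charge(pep, mid, model) > 0.0:
            lo = mid
        else:
            hi = mid
        if hi - lo < tol:
            break
    return 0.5 * (lo + hi)


@dataclass(frozen=True)
class PropertyProfile:
    """GRAVY, net charge, and pI of one peptide under declared conventions."""

    gravy: float
    net_charge: float
    pI: float


def property_profile(
    seq: PeptideSequence | str,
    scale: HydropathyScale = KYTE_DOOLITTLE,
    charge_model: ChargeModel = FORMAL_MODEL,
    pH: float = 7.0,
    pi_model: ChargeModel = HH_MODEL,
) -> PropertyProfile:
    """Convenience bundle of the three standard descriptors."""
    return PropertyProfile(
        gravy=gravy(seq, scale),
        net_charge=net_charge(seq, pH, charge_model),
        pI=isoelectric_point(seq, pi_model),
    )
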