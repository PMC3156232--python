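"""Design of the 6x6 pilot sparse-matrix peptide library.

The pilot library samples the 2-D physicochemical space of potentially
amphipathic 9-mers at wide intervals: hydrophobicity is graded down the
rows (residues at positions 1, 2, 5, 6, 9) and formal charge across the
columns (positions 3, 4, 7, 8).  Each grid cell is the 9-mer obtained by
interleaving one hydrophobic level with one charge level on the fixed
periodicity template HHPPHHPPH.

Sequence anchors: row E combined with charge columns 4 and 6 reproduces
the peptides AMKDAMERM (E4) and AMQDAMNEM (E6); the A1 corner carries
formal charge +4 at pH 7 and the E6 corner −2.
"""

from __future__ import annotations

import importlib.resources
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import yaml

from .errors import DesignError
from .properties import (
    FORMAL_MODEL,
    HH_MODEL,
    KYTE_DOOLITTLE,
    ChargeModel,
    HydropathyScale,
    PeptideSequence,
    gravy,
    isoelectric_point,
    net_charge,
)

HYDROPHOBIC_POSITIONS = (1, 2, 5, 6, 9)
CHARGED_POSITIONS = (3, 4, 7, 8)


@dataclass(frozen=True)
class PeriodicityTemplate:
    """Length-9 mask over {H, P}: hydrophobic vs polar/charged slots."""

    name: str
    mask: str

    def __post_init__(self) -> None:
        if len(self.mask) != 9 or set(self.mask) - {"H", "P"}:
            raise DesignError(f"mask must be 9 characters over {{H,P}}: {self.mask!r}")
        if "H" not in self.mask or "P" not in self.mask:
            raise DesignError("mask needs at least one H and one P slot")

    @property
    def h_positions(self) -> tuple[int, ...]:
        """1-based positions of hydrophobic slots."""
        return tuple(i + 1 for i, c in enumerate(self.mask) if c == "H")

    @property
    def p_positions(self) -> tuple[int, ...]:
        return tuple(i + 1 for i, c in enumerate(self.mask) if c == "P")


#: Periodicity of the pilot matrix: hydrophobic at 1,2,5,6,9, charged at 3,4,7,8.
PILOT_TEMPLATE = PeriodicityTemplate("pilot", "HHPPHHPPH")


@dataclass(frozen=True)
class ResidueLadder:
    """Graded residue assignments for the pilot grid.

    ``hydrophobic_levels``: one 5-residue tuple per row (positions 1,2,5,6,9),
    mean hydropathy non-increasing top to bottom.
    ``charge_levels``: one 4-residue tuple per column (positions 3,4,7,8),
    formal charge non-increasing left to right.
    """

    hydrophobic_levels: tuple[tuple[str, ...], ...]
    charge_levels: tuple[tuple[str, ...], ...]
    name: str = "ladder"

    def __post_init__(self) -> None:
        for level in self.hydrophobic_levels:
            if len(level) != len(HYDROPHOBIC_POSITIONS):
                raise DesignError(f"hydrophobic level {level} must have 5 residues")
        for level in self.charge_levels:
            if len(level) != len(CHARGED_POSITIONS):
                raise DesignError(f"charge level {level} must have 4 residues")

    def validate(self, scale: HydropathyScale = KYTE_DOOLITTLE) -> None:
        """Check the monotone gradients; raise DesignError naming offenders."""
        means = [np.mean([scale[r] for r in lvl]) for lvl in self.hydrophobic_levels]
        for i in range(len(means) - 1):
            if means[i] < means[i + 1] - 1e-12:
                raise DesignError(
                    f"hydrophobic levels {i + 1} and {i + 2} break monotonicity: "
                    f"mean hydropathy {means[i]:.3f} < {means[i + 1]:.3f}"
                )
        charges = [net_charge("".join(lvl), 7.0, FORMAL_MODEL) for lvl in self.charge_levels]
        for i in range(len(charges) - 1):
            if charges[i] < charges[i + 1]:
                raise DesignError(
                    f"charge levels {i + 1} and {i + 2} break monotonicity: "
                    f"formal charge {charges[i]} < {charges[i + 1]}"
                )

    @property
    def hydrophobic_pool(self) -> tuple[str, ...]:
        """Distinct residues available for hydrophobic slots, sorted."""
        return tuple(sorted({r for lvl in self.hydrophobic_levels for r in lvl}))

    @property
    def polar_pool(self) -> tuple[str, ...]:
        return tuple(sorted({r for lvl in self.charge_levels for r in lvl}))


def load_ladder(path=None) -> ResidueLadder:
    """Load a residue ladder from YAML (default: the shipped pilot-v1 config)."""
    if path is None:
        ref = importlib.resources.files("pepmatrix.data") / "pilot_ladder.yaml"
        raw = yaml.safe_load(ref.read_text())
    else:
        with open(path) as fh:
            raw = yaml.safe_load(fh)
    return ResidueLadder(
        hydrophobic_levels=tuple(tuple(lvl) for lvl in raw["hydrophobic_levels"]),
        charge_levels=tuple(tuple(lvl) for lvl in raw["charge_levels"]),
        name=raw.get("name", "ladder"),
    )


DEFAULT_LADDER = load_ladder()


@dataclass(frozen=True)
class MatrixLibrary:
    """A complete rows x cols grid of 9-mer peptides with declared axes."""

    row_labels: tuple[str, ...]
    column_indices: tuple[int, ...]
    grid: dict[tuple[str, int], PeptideSequence]
    template: PeriodicityTemplate | None = PILOT_TEMPLATE
    row_axis: str = "hydrophobicity"
    column_axis: str = "charge"

    def __post_init__(self) -> None:
        expected = {(r, c) for r in self.row_labels for c in self.column_indices}
        got = set(self.grid)
        if got != expected:
            missing = sorted(expected - got)
            extra = sorted(got - expected)
            raise DesignError(
                f"grid incomplete: missing {missing[:6]}, unexpected {extra[:6]}"
            )
        for pos, pep in self.grid.items():
            if len(pep) != 9:
                raise DesignError(f"peptide at {pos} has length {len(pep)}, expected 9")

    def __len__(self) -> int:
        return len(self.grid)

    @property
    def shape(self) -> tuple[int, int]:
        return (len(self.row_labels), len(self.column_indices))

    def __getitem__(self, pos: tuple[str, int]) -> PeptideSequence:
        return self.grid[pos]

    def peptides(self) -> list[PeptideSequence]:
        """Members in row-major order."""
        return [
            self.grid[(r, c)] for r in self.row_labels for c in self.column_indices
        ]

    def positions(self) -> list[tuple[str, int]]:
        return [(r, c) for r in self.row_labels for c in self.column_indices]


def _assemble(
    hydro: tuple[str, ...],
    charged: tuple[str, ...],
    template: PeriodicityTemplate = PILOT_TEMPLATE,
) -> str:
    seq = [""] * 9
    for pos, res in zip(template.h_positions, hydro):
        seq[pos - 1] = res
    for pos, res in zip(template.p_positions, charged):
        seq[pos - 1] = res
    return "".join(seq)


def build_pilot_matrix(
    ladder: ResidueLadder | None = None,
    scale: HydropathyScale = KYTE_DOOLITTLE,
    row_labels: str | None = None,
) -> MatrixLibrary:
    """Build the pilot matrix (rows A.. by hydrophobicity, columns 1.. by charge)."""
    ladder = ladder or DEFAULT_LADDER
    ladder.validate(scale)
    n_rows = len(ladder.hydrophobic_levels)
    n_cols = len(ladder.charge_levels)
    rows = tuple((row_labels or "ABCDEFGHIJKLMNOPQRSTUVWXYZ")[:n_rows])
    cols = tuple(range(1, n_cols + 1))
    grid: dict[tuple[str, int], PeptideSequence] = {}
    for i, r in enumerate(rows):
        for j, c in enumerate(cols):
            seq = _assemble(ladder.hydrophobic_levels[i], ladder.charge_levels[j])
            grid[(r, c)] = PeptideSequence(id=f"{r}{c}", sequence=seq, row=r, col=c)
    seqs = [p.sequence for p in grid.values()]
    if len(set(seqs)) != len(seqs):
        raise DesignError("ladder produces duplicate sequences")
    return MatrixLibrary(row_labels=rows, column_indices=cols, grid=grid)


@dataclass(frozen=True)
class MatrixSummary:
    """Per-peptide property table plus per-row and per-column means."""

    table: pd.DataFrame
    row_means: pd.DataFrame
    col_means: pd.DataFrame


def summarize(
    matrix: MatrixLibrary,
    scale: HydropathyScale = KYTE_DOOLITTLE,
    charge_model: ChargeModel = FORMAL_MODEL,
    pH: float = 7.0,
    pi_model: ChargeModel = HH_MODEL,
) -> MatrixSummary:
    """Property table of a library: position, sequence, GRAVY, charge, pI."""
    records = []
    for pep in matrix.peptides():
        records.append(
            {
                "row": pep.row,
                "col": pep.col,
                "id": pep.id,
                "sequence": pep.sequence,
                "gravy": gravy(pep, scale),
                "net_charge": net_charge(pep, pH, charge_model),
                "pI": isoelectric_point(pep, pi_model),
            }
        )
    table = pd.DataFrame.from_records(records)
    num = ["gravy", "net_charge", "pI"]
    row_means = table.groupby("row", sort=False)[num].mean().reset_index()
    col_means = table.groupby("col", sort=False)[num].mean().reset_index()
    return MatrixSummary(table=table, row_means=row_means, col_means=col_means)
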