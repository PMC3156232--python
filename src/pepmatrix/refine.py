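"""Second-round refinement libraries: In-Plane and Orthogonal matrices.

In-Plane refinement interpolates the two pilot property axes (GRAVY down
the rows, pI across the columns) between four "corner" hit peptides with
step sizes strictly smaller than the pilot's, then realizes each target
cell as a 9-mer on the pilot periodicity by greedy residue substitution
from the ladder pools.

Orthogonal refinement holds composition near the In-Plane diagonal and
varies the periodicity instead: each diagonal peptide is re-laid onto four
hydrophobic/polar masks ranging from a single amino-terminal hydrophobic
block to strict alternation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np

from .design import (
    PILOT_TEMPLATE,
    DEFAULT_LADDER,
    MatrixLibrary,
    PeriodicityTemplate,
    ResidueLadder,
)
from .errors import DesignError
from .properties import (
    HH_MODEL,
    KYTE_DOOLITTLE,
    ChargeModel,
    HydropathyScale,
    PeptideSequence,
    gravy,
    isoelectric_point,
)

logger = logging.getLogger(__name__)

__all__ = [
    "PeriodicityTemplate",
    "RefinementSpec",
    "PropertyTargets",
    "in_plane_targets",
    "bilinear_grid",
    "in_plane_refine",
    "periodicity_templates",
    "repack_sequence",
    "orthogonal_refine",
]


def periodicity_templates() -> tuple[PeriodicityTemplate, ...]:
    """The four masks of the Orthogonal matrix, block first.

    block:       all hydrophobic residues at the amino terminus (HHHHHPPPP)
    three-three: 3:3 alternation (HHHPPPHHH; a 9-mer allots 6 H, 3 P)
    pilot:       the pilot periodicity, H at positions 1,2,5,6,9
    alternating: strict single-residue alternation (HPHPHPHPH)
    """
    return (
        PeriodicityTemplate("block", "HHHHHPPPP"),
        PeriodicityTemplate("three-three", "HHHPPPHHH"),
        PILOT_TEMPLATE,
        PeriodicityTemplate("alternating", "HPHPHPHPH"),
    )


@dataclass(frozen=True)
class PropertyTargets:
    """Per-cell (GRAVY, pI) targets for a refinement grid."""

    gravy: np.ndarray
    pi: np.ndarray

    @property
    def shape(self) -> tuple[int, int]:
        return self.gravy.shape


@dataclass(frozen=True)
class RefinementSpec:
    """Four corner peptides and the shape of the refined grid."""

    corners: tuple[tuple[PeptideSequence, PeptideSequence],
                   tuple[PeptideSequence, PeptideSequence]]
    out_shape: tuple[int, int] = (4, 4)

    def __post_init__(self) -> None:
        if len(self.corners) != 2 or any(len(r) != 2 for r in self.corners):
            raise DesignError("corners must be a 2x2 grid of peptides")
        if min(self.out_shape) < 2:
            raise DesignError("refined grid needs at least 2 rows and 2 columns")


def bilinear_grid(c00, c01, c10, c11, shape):
    rows, cols = shape
    out = np.empty(shape)
    for i in range(rows):
        u = i / (rows - 1)
        for j in range(cols):
            v = j / (cols - 1)
            out[i, j] = (
                (1 - u) * (1 - v) * c00 + (1 - u) * v * c01
                + u * (1 - v) * c10 + u * v * c11
            )
    return out


def in_plane_targets(
    corners,
    out_shape: tuple[int, int] = (4, 4),
    scale: HydropathyScale = KYTE_DOOLITTLE,
    pi_model: ChargeModel = HH_MODEL,
) -> PropertyTargets:
    """Bilinear (GRAVY, pI) targets between the four corner peptides.

    Rows span GRAVY (top row = first corner row), columns span pI.  Step
    sizes along each axis are the corner-to-corner difference divided by
    (cells − 1), hence strictly smaller than the original pilot steps.
    """
    (p00, p01), (p10, p11) = corners
    g = [gravy(p, scale) for p in (p00, p01, p10, p11)]
    q = [isoelectric_point(p, pi_model) for p in (p00, p01, p10, p11)]
    if max(g) - min(g) < 1e-12 and max(q) - min(q) < 1e-12:
        warnings.warn("degenerate corners: all property targets identical")
    return PropertyTargets(
        gravy=bilinear_grid(g[0], g[1], g[2], g[3], out_shape),
        pi=bilinear_grid(q[0], q[1], q[2], q[3], out_shape),
    )


def _objective(seq_chars, g_target, p_target, g_norm, p_norm, scale, pi_model):
    s = "".join(seq_chars)
    g = gravy(s, scale)
    p = isoelectric_point(s, pi_model)
    return abs(g - g_target) / g_norm + abs(p - p_target) / p_norm


def _greedy_fit(
    base: str,
    g_target: float,
    p_target: float,
    g_norm: float,
    p_norm: float,
    template: PeriodicityTemplate,
    hydro_pool,
    polar_pool,
    scale,
    pi_model,
    max_passes: int = 30,
) -> str:
    """Greedy residue substitution: positions left to right, candidates in
    lexicographic order, first improvement accepted; deterministic."""
    chars = list(base)
    best = _objective(chars, g_target, p_target, g_norm, p_norm, scale, pi_model)
    for _ in range(max_passes):
        improved = False
        for pos in range(9):
            pool = hydro_pool if template.mask[pos] == "H" else polar_pool
            for cand in pool:
                if cand == chars[pos]:
                    continue
                trial = chars.copy()
                trial[pos] = cand
                val = _objective(trial, g_target, p_target, g_norm, p_norm,
                                 scale, pi_model)
                if val < best - 1e-12:
                    chars = trial
                    best = val
                    improved = True
                    break
        if not improved:
            break
    return "".join(chars)


def in_plane_refine(
    spec: RefinementSpec,
    template: PeriodicityTemplate = PILOT_TEMPLATE,
    ladder: ResidueLadder | None = None,
    scale: HydropathyScale = KYTE_DOOLITTLE,
    pi_model: ChargeModel = HH_MODEL,
) -> MatrixLibrary:
    """Realize the In-Plane refinement grid from its corner peptides."""
    ladder = ladder or DEFAULT_LADDER
    targets = in_plane_targets(spec.corners, spec.out_shape, scale, pi_model)
    rows, cols = spec.out_shape
    (p00, p01), (p10, p11) = spec.corners
    corner_seqs = np.array(
        [[p00.sequence, p01.sequence], [p10.sequence, p11.sequence]], dtype=object
    )
    g_norm = max(float(np.ptp(targets.gravy)), 1e-6)
    p_norm = max(float(np.ptp(targets.pi)), 1e-6)
    hydro_pool = ladder.hydrophobic_pool
    polar_pool = ladder.polar_pool

    row_labels = tuple("ABCDEFGHIJKLMNOPQRSTUVWXYZ"[:rows])
    col_indices = tuple(range(1, cols + 1))
    grid: dict[tuple[str, int], PeptideSequence] = {}
    for i, r in enumerate(row_labels):
        for j, c in enumerate(col_indices):
            base = corner_seqs[round(i / (rows - 1)), round(j / (cols - 1))]
            seq = _greedy_fit(
                base, targets.gravy[i, j], targets.pi[i, j], g_norm, p_norm,
                template, hydro_pool, polar_pool, scale, pi_model,
            )
            realized_g = gravy(seq, scale)
            if abs(realized_g - targets.gravy[i, j]) > 0.35:
                logger.warning(
                    "cell (%s,%s): GRAVY target %.3f clamped to realized %.3f "
                    "(outside pool range)", r, c, targets.gravy[i, j], realized_g,
                )
            grid[(r, c)] = PeptideSequence(id=f"{r}{c}", sequence=seq, row=r, col=c)
    return MatrixLibrary(
        row_labels=row_labels, column_indices=col_indices, grid=grid,
        template=template, row_axis="gravy", column_axis="pI",
    )


def repack_sequence(
    seq: PeptideSequence,
    template: PeriodicityTemplate,
    source: PeriodicityTemplate = PILOT_TEMPLATE,
    scale: HydropathyScale = KYTE_DOOLITTLE,
) -> PeptideSequence:
    """Re-lay a 9-mer onto a new periodicity mask, preserving composition.

    Residues are split into hydrophobic-slot and polar-slot classes by the
    source mask and written onto the target mask in their original
    within-class order.  When the two masks allot different class sizes,
    the excess residues are reassigned by hydropathy rank: the most
    hydrophobic polar-class residues are promoted to H slots first (and
    symmetrically the least hydrophobic H-class residues demoted).
    """
    if len(seq) != 9:
        raise DesignError(f"repack requires a 9-mer, got length {len(seq)}")
    s = seq.sequence
    h_res = [s[i - 1] for i in source.h_positions]
    p_res = [s[i - 1] for i in source.p_positions]
    n_h = len(template.h_positions)

    if len(h_res) < n_h:
        need = n_h - len(h_res)
        # promote the most hydrophobic polar-class residues, ties by position
        order = sorted(range(len(p_res)), key=lambda k: (-scale[p_res[k]], k))
        promoted_idx = sorted(order[:need])
        h_res = h_res + [p_res[k] for k in promoted_idx]
        p_res = [r for k, r in enumerate(p_res) if k not in set(promoted_idx)]
    elif len(h_res) > n_h:
        drop = len(h_res) - n_h
        order = sorted(range(len(h_res)), key=lambda k: (scale[h_res[k]], k))
        demoted_idx = sorted(order[:drop])
        p_res = [h_res[k] for k in demoted_idx] + p_res
        h_res = [r for k, r in enumerate(h_res) if k not in set(demoted_idx)]

    out = [""] * 9
    for pos, res in zip(template.h_positions, h_res):
        out[pos - 1] = res
    for pos, res in zip(template.p_positions, p_res):
        out[pos - 1] = res
    return PeptideSequence(id=f"{seq.id}:{template.name}", sequence="".join(out))


def orthogonal_refine(
    diagonal,
    templates: tuple[PeriodicityTemplate, ...] | None = None,
    source: PeriodicityTemplate = PILOT_TEMPLATE,
    scale: HydropathyScale = KYTE_DOOLITTLE,
) -> MatrixLibrary:
    """Build the Orthogonal matrix: periodicity varies down the rows.

    Column j holds ``repack(diagonal[j], template_i)`` for rows i = 1..4;
    the row carrying the source (pilot) periodicity reproduces the input
    diagonal verbatim.
    """
    diagonal = tuple(diagonal)
    templates = tuple(templates) if templates is not None else periodicity_templates()
    if len(diagonal) != 4 or len(templates) != 4:
        raise DesignError(
            f"orthogonal refinement needs 4 diagonal peptides and 4 templates, "
            f"got {len(diagonal)} and {len(templates)}"
        )
    row_labels = tuple("ABCD")
    col_indices = tuple(range(1, 5))
    grid: dict[tuple[str, int], PeptideSequence] = {}
    for i, (r, tmpl) in enumerate(zip(row_labels, templates)):
        for j, c in enumerate(col_indices):
            repacked = repack_sequence(diagonal[j], tmpl, source=source, scale=scale)
            grid[(r, c)] = PeptideSequence(
                id=f"{r}{c}", sequence=repacked.sequence, row=r, col=c
            )
    return MatrixLibrary(
        row_labels=row_labels, column_indices=col_indices, grid=grid,
        template=None, row_axis="periodicity", column_axis="gravy+pI",
    )
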