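"""Forward simulators with known ground truth.

Three generators make the analysis pipeline testable end to end without
laboratory data:

* :func:`simulate_pulldown` — equilibrium depletion of peptide by a
  Langmuir surface.  For each initial concentration the free equilibrium
  concentration is the unique non-negative root of the mass-balance
  quadratic; absorbances are emitted with optional multiplicative
  Gaussian noise.
* :func:`simulate_fingerprint` — per-organism binding-profile grids
  driven by a surface archetype (charge / hydrophobicity preference)
  plus multiplicative log-normal noise.  The score is a deliberately
  simple monotone model whose only job is to create separable, noisy
  profiles.
* :func:`simulate_disk_image` — synthetic fluorescence fields (disks on
  background) with pixel masks, as fixtures for intensity-ratio
  quantitation.

All simulators are bit-reproducible given (parameters, seed).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .binding import PulldownSample, total_surface_area
from .design import MatrixLibrary
from .errors import MeasurementError
from .fingerprint import BindingProfile
from .properties import FAUCHERE_PLISKA, FORMAL_MODEL, gravy, net_charge


def equilibrium_free_concentration(
    Ka: float, N: float, area: float, volume: float, C0: float
) -> float:
    """Unique non-negative root of the Langmuir mass-balance quadratic.

    Conservation C0·V = C_eq·V + A·Ka·N·C_eq/(1+Ka·C_eq) rearranges to
    Ka·V·C_eq² + (V + Ka·N·A − Ka·C0·V)·C_eq − C0·V = 0.
    """
    if C0 == 0.0:
        return 0.0
    if Ka == 0.0 or N == 0.0:
        return C0
    a = Ka * volume
    b = volume + Ka * N * area - Ka * C0 * volume
    c = -C0 * volume
    disc = b * b - 4.0 * a * c
    assert disc >= 0.0, "mass-balance discriminant negative for valid inputs"
    c_eq = (-b + math.sqrt(disc)) / (2.0 * a)
    assert 0.0 <= c_eq <= C0 * (1.0 + 1e-12)
    return min(c_eq, C0)


def simulate_pulldown(
    Ka: float,
    N: float,
    cell_count: float,
    cell_diameter: float,
    volume: float,
    C0_list,
    noise_sd: float = 0.0,
    seed: int | None = None,
    peptide_id: str = "sim",
) -> list[PulldownSample]:
    """Simulate depletion samples for a Langmuir surface (SI units).

    Emits A_i = 1.0 and A_f = (C_eq/C0)·(1+ε), ε ~ Normal(0, noise_sd).
    Initial concentrations must be positive (A_f/A_i is undefined at C0=0).
    """
    if Ka < 0 or N < 0 or noise_sd < 0:
        raise MeasurementError("Ka, N, and noise_sd must be non-negative")
    rng = np.random.default_rng(seed)
    area = total_surface_area(cell_count, cell_diameter)
    samples = []
    for c0 in C0_list:
        if c0 <= 0:
            raise MeasurementError(f"C0 must be positive, got {c0}")
        c_eq = equilibrium_free_concentration(Ka, N, area, volume, c0)
        eps = rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0
        a_f = max((c_eq / c0) * (1.0 + eps), 0.0)
        samples.append(
            PulldownSample(
                C0=c0, A_i=1.0, A_f=a_f, cell_count=cell_count,
                cell_diameter=cell_diameter, volume=volume, peptide_id=peptide_id,
            )
        )
    return samples


@dataclass(frozen=True)
class SurfaceArchetype:
    """Idealized surface character driving a simulated fingerprint.

    ``charge_affinity`` < 0 models an anionic surface that prefers cationic
    peptides (the score rewards net_charge·|charge_affinity|); > 0 the
    reverse.  ``hydro_affinity`` scales the reward for hydrophobic
    peptides.  ``baseline`` is the ratio with no specific binding (>= 1);
    ``noise_sd`` is log-ratio noise.
    """

    label: str
    charge_affinity: float
    hydro_affinity: float
    baseline: float = 1.2
    noise_sd: float = 0.1

    def __post_init__(self) -> None:
        if self.baseline < 1.0:
            raise ValueError("baseline ratio must be >= 1")
        if self.noise_sd < 0 or self.hydro_affinity < 0:
            raise ValueError("noise_sd and hydro_affinity must be >= 0")


def default_archetypes() -> tuple[SurfaceArchetype, ...]:
    """Four separable surface archetypes used by the classification benchmark."""
    return (
        SurfaceArchetype("anionic-surface", charge_affinity=-0.6, hydro_affinity=0.0),
        SurfaceArchetype("cationic-surface", charge_affinity=0.6, hydro_affinity=0.0),
        SurfaceArchetype("hydrophobic-surface", charge_affinity=0.0, hydro_affinity=1.0),
        SurfaceArchetype("amphiphilic-surface", charge_affinity=-0.3, hydro_affinity=0.8),
    )


def simulate_fingerprint(
    archetype: SurfaceArchetype,
    library: MatrixLibrary,
    weights: tuple[float, float] = (0.5, 0.5),
    seed: int | None = None,
) -> BindingProfile:
    """Simulate one organism's binding profile over a matrix library.

    Per peptide the log-binding score is
    S = w_q·max(0, −q·charge_affinity) + w_h·max(0, GRAVY)·hydro_affinity
    with q the formal net charge at pH 7 and GRAVY under the
    Fauchère–Pliška scale (a transfer free energy, positive for
    hydrophobic residues, so the hydrophobic reward is graded across the
    whole library); the emitted ratio is baseline·exp(S + ε),
    ε ~ Normal(0, noise_sd).
    """
    rng = np.random.default_rng(seed)
    w_q, w_h = weights
    rows, cols = library.shape
    ratios = np.empty((rows, cols))
    for i, r in enumerate(library.row_labels):
        for j, c in enumerate(library.column_indices):
            pep = library[(r, c)]
            q = net_charge(pep, 7.0, FORMAL_MODEL)
            g = gravy(pep, FAUCHERE_PLISKA)
            score = (
                w_q * max(0.0, -q * archetype.charge_affinity)
                + w_h * max(0.0, g) * archetype.hydro_affinity
            )
            eps = rng.normal(0.0, archetype.noise_sd) if archetype.noise_sd > 0 else 0.0
            ratios[i, j] = archetype.baseline * math.exp(score + eps)
    return BindingProfile(
        organism=archetype.label, ratios=ratios,
        row_labels=library.row_labels, column_indices=library.column_indices,
    )


def simulate_disk_image(
    size: tuple[int, int],
    disk_centers,
    disk_radius: float,
    disk_level: float = 150.0,
    background_level: float = 50.0,
    noise_sd: float = 0.0,
    seed: int | None = None,
):
    """Synthetic fluorescence field: disks on a flat background, plus masks.

    Returns (image, cell_mask, background_mask); the two masks partition
    the pixels.  Disks must lie fully inside the image.
    """
    h, w = size
    yy, xx = np.ogrid[:h, :w]
    cell_mask = np.zeros((h, w), dtype=bool)
    for cy, cx in disk_centers:
        if not (disk_radius <= cy <= h - 1 - disk_radius
                and disk_radius <= cx <= w - 1 - disk_radius):
            raise ValueError(
                f"disk at ({cy}, {cx}) with radius {disk_radius} leaves the image"
            )
        cell_mask |= (yy - cy) ** 2 + (xx - cx) ** 2 <= disk_radius**2
    image = np.where(cell_mask, disk_level, background_level).astype(float)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        image = image + rng.normal(0.0, noise_sd, size=image.shape)
    return image, cell_mask, ~cell_mask
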