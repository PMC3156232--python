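"""Binding-profile ("fingerprint") quantitation, comparison, and pooling.

A binding profile is the matrix-shaped grid of cell-to-background
fluorescence ratios obtained by screening one organism against a peptide
matrix library.  The ratio normalization removes well-to-well effects of
peptide precipitation or nonspecific binding to the plate.  Because
different organisms present different surface chemistries, the profile
acts as an identification signature; profiles are compared by rank
correlation of log-ratios (robust to per-experiment gain) and unknowns
classified by nearest reference.

Pooled screening: a library is partitioned row-major into pools, positive
pools into subpools, and positive subpools screened member by member —
the 36-peptide grid resolves one hit in 4 + 3 + 3 = 10 assays.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .design import MatrixLibrary
from .errors import ConsistencyError, PlanError, ProfileError, QuantitationError


@dataclass(frozen=True)
class BindingProfile:
    """Grid of positive cell/background fluorescence ratios for one organism."""

    organism: str
    ratios: np.ndarray
    row_labels: tuple[str, ...] | None = None
    column_indices: tuple[int, ...] | None = None

    def __post_init__(self) -> None:
        arr = np.asarray(self.ratios, dtype=float)
        object.__setattr__(self, "ratios", arr)
        if arr.ndim != 2:
            raise ProfileError("ratios must form a 2-D grid")
        if not np.all(np.isfinite(arr)) or np.any(arr <= 0):
            raise ProfileError("all ratios must be finite and > 0")

    @property
    def shape(self) -> tuple[int, int]:
        return self.ratios.shape

    def flatten(self) -> np.ndarray:
        return self.ratios.ravel()


def intensity_ratio(cell_values, background_values) -> float:
    """Mean cell intensity over mean background intensity."""
    cell = np.asarray(cell_values, dtype=float)
    bg = np.asarray(background_values, dtype=float)
    if cell.size == 0 or bg.size == 0:
        raise QuantitationError("cell and background pixel lists must be non-empty")
    bg_mean = float(bg.mean())
    if bg_mean <= 0:
        raise QuantitationError(f"background mean must be > 0, got {bg_mean}")
    return float(cell.mean()) / bg_mean


def assemble_profile(
    measurements,
    layout: MatrixLibrary,
    organism: str = "unknown",
) -> BindingProfile:
    """Place (grid position, ratio) measurements onto the library layout.

    ``measurements`` is an iterable of ((row_label, col_index), ratio);
    every grid cell must appear exactly once, in any order.
    """
    expected = set(layout.positions())
    seen: dict[tuple[str, int], float] = {}
    for pos, ratio in measurements:
        pos = (pos[0], int(pos[1]))
        if pos not in expected:
            raise ProfileError(f"position {pos} is not in the library layout")
        if pos in seen:
            raise ProfileError(f"duplicate measurement for position {pos}")
        seen[pos] = float(ratio)
    missing = expected - set(seen)
    if missing:
        raise ProfileError(f"missing measurements for positions {sorted(missing)}")
    rows, cols = layout.shape
    ratios = np.empty((rows, cols))
    for i, r in enumerate(layout.row_labels):
        for j, c in enumerate(layout.column_indices):
            ratios[i, j] = seen[(r, c)]
    return BindingProfile(
        organism=organism, ratios=ratios,
        row_labels=layout.row_labels, column_indices=layout.column_indices,
    )


def profile_similarity(p: BindingProfile, q: BindingProfile, method: str = "rank") -> float:
    """Similarity in [−1, 1] between two same-shaped profiles.

    "rank" (default): Spearman rank correlation of flattened log-ratios.
    "cosine": cosine of the flattened log-ratio vectors.
    """
    if p.shape != q.shape:
        raise ProfileError(f"profile shapes differ: {p.shape} vs {q.shape}")
    a = np.log(p.flatten())
    b = np.log(q.flatten())
    if method == "rank":
        if np.ptp(a) == 0 or np.ptp(b) == 0:
            warnings.warn("constant profile: rank correlation undefined, returning 0")
            return 0.0
        return float(stats.spearmanr(a, b).statistic)
    if method == "cosine":
        na, nb = np.linalg.norm(a), np.linalg.norm(b)
        if na == 0 or nb == 0:
            warnings.warn("zero log-profile: cosine undefined, returning 0")
            return 0.0
        return float(np.dot(a, b) / (na * nb))
    raise ValueError(f"unknown similarity method {method!r}")


def classify(
    unknown: BindingProfile,
    references: list[BindingProfile],
    method: str = "rank",
) -> tuple[str, float, float]:
    """Nearest-reference classification: (label, score, margin).

    Margin is best-minus-second-best similarity; exact ties are broken by
    label order with a warning.
    """
    if not references:
        raise ProfileError("reference set must be non-empty")
    scored = sorted(
        ((profile_similarity(unknown, ref, method), ref.organism) for ref in references),
        key=lambda t: (-t[0], t[1]),
    )
    best_score, best_label = scored[0]
    if len(scored) == 1:
        return best_label, best_score, math.inf
    second_score = scored[1][0]
    if best_score == second_score:
        warnings.warn(
            f"similarity tie between {best_label!r} and {scored[1][1]!r}; "
            f"broken by label order"
        )
    return best_label, best_score, best_score - second_score


@dataclass(frozen=True)
class PoolPlan:
    """Hierarchical pooling of library positions: pools → subpools → singles."""

    pools: tuple[tuple[tuple[str, int], ...], ...]
    subpool_size: int

    def __post_init__(self) -> None:
        flat = [p for pool in self.pools for p in pool]
        if len(flat) != len(set(flat)):
            raise PlanError("pools must be disjoint")
        for pool in self.pools:
            if len(pool) % self.subpool_size != 0:
                raise PlanError(
                    f"pool size {len(pool)} not divisible by subpool size "
                    f"{self.subpool_size}"
                )

    @property
    def n_pools(self) -> int:
        return len(self.pools)

    def subpools(self, pool_index: int) -> tuple[tuple[tuple[str, int], ...], ...]:
        pool = self.pools[pool_index]
        k = self.subpool_size
        return tuple(pool[i:i + k] for i in range(0, len(pool), k))


def make_pool_plan(
    library: MatrixLibrary, n_pools: int = 4, subpool_size: int = 3
) -> PoolPlan:
    """Deterministic row-major partition of a library into pools and subpools."""
    positions = library.positions()
    if len(positions) % n_pools != 0:
        raise PlanError(
            f"library size {len(positions)} not divisible into {n_pools} pools"
        )
    pool_size = len(positions) // n_pools
    if pool_size % subpool_size != 0:
        raise PlanError(
            f"pool size {pool_size} not divisible into subpools of {subpool_size}"
        )
    pools = tuple(
        tuple(positions[i:i + pool_size]) for i in range(0, len(positions), pool_size)
    )
    return PoolPlan(pools=pools, subpool_size=subpool_size)


@dataclass(frozen=True)
class ScreenCalls:
    """Positive/negative calls at each pooling level."""

    pool: dict[int, bool] = field(default_factory=dict)
    subpool: dict[tuple[int, int], bool] = field(default_factory=dict)
    peptide: dict[tuple[str, int], bool] = field(default_factory=dict)


def simulate_screen(plan: PoolPlan, hits) -> tuple[set, int, ScreenCalls]:
    """Run a perfect-call hierarchical screen for a known hit set.

    Returns (recovered hit positions, number of assays performed, calls).
    Every pool is assayed; subpools only inside positive pools; individual
    peptides only inside positive subpools.
    """
    hits = set(hits)
    calls = ScreenCalls()
    n_assays = 0
    for i, pool in enumerate(plan.pools):
        n_assays += 1
        calls.pool[i] = bool(hits & set(pool))
    for i, positive in list(calls.pool.items()):
        if not positive:
            continue
        subs = plan.subpools(i)
        for j, sub in enumerate(subs):
            n_assays += 1
            calls.subpool[(i, j)] = bool(hits & set(sub))
        for j, sub in enumerate(subs):
            if not calls.subpool[(i, j)]:
                continue
            for pos in sub:
                n_assays += 1
                calls.peptide[pos] = pos in hits
    found = deconvolve(plan, calls)
    return found, n_assays, calls


def deconvolve(plan: PoolPlan, calls: ScreenCalls) -> set:
    """Positions consistent with the positive-call paths through the plan.

    A position is returned when its pool and subpool calls are positive
    and its individual call (if assayed) is positive; positive subpools
    with no individual calls contribute all their members as candidates.
    Contradictory calls (positive subpool inside a negative pool, or
    positive peptide in a negative subpool) raise :class:`ConsistencyError`.
    """
    sub_index: dict[tuple[str, int], tuple[int, int]] = {}
    for i in range(plan.n_pools):
        for j, sub in enumerate(plan.subpools(i)):
            for pos in sub:
                sub_index[pos] = (i, j)

    for (i, j), positive in calls.subpool.items():
        if positive and calls.pool.get(i) is False:
            raise ConsistencyError(
                f"subpool {j} of pool {i} called positive inside a negative pool"
            )
    for pos, positive in calls.peptide.items():
        i, j = sub_index[pos]
        if positive and (calls.subpool.get((i, j)) is False or calls.pool.get(i) is False):
            raise ConsistencyError(
                f"peptide {pos} called positive inside a negative pool/subpool"
            )

    result = set()
    for (i, j), positive in calls.subpool.items():
        if not positive or not calls.pool.get(i, False):
            continue
        sub = plan.subpools(i)[j]
        assayed = [pos for pos in sub if pos in calls.peptide]
        if assayed:
            result.update(pos for pos in assayed if calls.peptide[pos])
        else:
            result.update(sub)
    return result
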