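"""Fingerprint quantitation, similarity, classification, pooled screening."""

import numpy as np
import pytest

from pepmatrix import (
    BindingProfile,
    assemble_profile,
    classify,
    deconvolve,
    default_archetypes,
    intensity_ratio,
    make_pool_plan,
    profile_similarity,
    simulate_fingerprint,
    simulate_screen,
)
from pepmatrix.fingerprint import ScreenCalls
from pepmatrix.errors import (
    ConsistencyError,
    PlanError,
    ProfileError,
    QuantitationError,
)


class TestIntensityRatio:
    def test_basic_ratio(self):
        assert intensity_ratio([200] * 10, [100] * 10) == pytest.approx(2.0)

    def test_no_signal(self):
        assert intensity_ratio([100.0] * 5, [100.0] * 7) == pytest.approx(1.0)

    def test_nonpositive_background(self):
        with pytest.raises(QuantitationError):
            intensity_ratio([100.0], [0.0])

    def test_empty_inputs(self):
        with pytest.raises(QuantitationError):
            intensity_ratio([], [1.0])


class TestAssembleProfile:
    def _measurements(self, pilot):
        return [((r, c), 1.0 + 0.01 * i)
                for i, (r, c) in enumerate(pilot.positions())]

    def test_full_grid(self, pilot):
        prof = assemble_profile(self._measurements(pilot), pilot, organism="sa")
        assert prof.shape == (6, 6)
        assert prof.organism == "sa"

    def test_missing_position_named(self, pilot):
        meas = self._measurements(pilot)[:-1]
        with pytest.raises(ProfileError, match=r"\('F', 6\)"):
            assemble_profile(meas, pilot)

    def test_duplicate_position_rejected(self, pilot):
        meas = self._measurements(pilot) + [(("A", 1), 2.0)]
        with pytest.raises(ProfileError, match="duplicate"):
            assemble_profile(meas, pilot)

    def test_order_invariance(self, pilot):
        meas = self._measurements(pilot)
        a = assemble_profile(meas, pilot)
        b = assemble_profile(list(reversed(meas)), pilot)
        assert np.array_equal(a.ratios, b.ratios)


class TestSimilarity:
    @pytest.fixture()
    def prof(self):
        rng = np.random.default_rng(5)
        return BindingProfile("x", np.exp(rng.normal(size=(4, 4))))

    def test_self_similarity(self, prof):
        assert profile_similarity(prof, prof) == pytest.approx(1.0)

    def test_scale_invariance_under_rank(self, prof):
        scaled = BindingProfile("y", prof.ratios * 3.7)
        assert profile_similarity(prof, scaled) == pytest.approx(1.0)

    def test_rank_reversal(self, prof):
        inverted = BindingProfile("y", 1.0 / prof.ratios)
        assert profile_similarity(prof, inverted) == pytest.approx(-1.0)

    def test_shape_mismatch(self, prof):
        other = BindingProfile("y", np.ones((3, 3)) * 2.0)
        with pytest.raises(ProfileError):
            profile_similarity(prof, other)


class TestClassify:
    def test_known_profile_recovers_label(self, pilot):
        refs = [
            simulate_fingerprint(
                type(a)(a.label, a.charge_affinity, a.hydro_affinity,
                        a.baseline, 0.0), pilot)
            for a in default_archetypes()
        ]
        label, score, margin = classify(refs[0], refs)
        assert label == refs[0].organism
        assert score == pytest.approx(1.0)
        assert margin > 0

    def test_identical_references_tie_warning(self):
        rng = np.random.default_rng(2)
        prof = BindingProfile("u", np.exp(rng.normal(size=(3, 3))))
        refs = [BindingProfile("a", prof.ratios), BindingProfile("b", prof.ratios)]
        with pytest.warns(UserWarning, match="tie"):
            label, _, margin = classify(prof, refs)
        assert label == "a" and margin == 0

    def test_empty_reference_set(self, pilot):
        prof = BindingProfile("u", np.ones((2, 2)) * 2)
        with pytest.raises(ProfileError):
            classify(prof, [])


class TestPoolPlan:
    def test_default_pools_of_nine(self, pilot):
        plan = make_pool_plan(pilot)
        assert plan.n_pools == 4
        assert all(len(p) == 9 for p in plan.pools)
        assert all(len(s) == 3 for s in plan.subpools(0))

    def test_singleton_plan(self, pilot):
        plan = make_pool_plan(pilot, n_pools=36, subpool_size=1)
        assert plan.n_pools == 36
        assert all(len(p) == 1 for p in plan.pools)

    def test_indivisible_rejected(self, pilot):
        with pytest.raises(PlanError):
            make_pool_plan(pilot, n_pools=5)
        with pytest.raises(PlanError):
            make_pool_plan(pilot, n_pools=4, subpool_size=4)


class TestScreening:
    def test_single_planted_hit_in_ten_assays(self, pilot):
        plan = make_pool_plan(pilot)
        hit = ("E", 4)
        found, n_assays, _ = simulate_screen(plan, {hit})
        assert found == {hit}
        assert n_assays == 10  # 4 pools + 3 subpools + 3 individuals

    def test_no_positive_pools(self, pilot):
        plan = make_pool_plan(pilot)
        found, n_assays, _ = simulate_screen(plan, set())
        assert found == set()
        assert n_assays == 4

    def test_two_hits_in_different_pools(self, pilot):
        plan = make_pool_plan(pilot)
        hits = {plan.pools[0][0], plan.pools[2][5]}
        found, n_assays, _ = simulate_screen(plan, hits)
        assert found == hits
        assert n_assays == 4 + 2 * (3 + 3)

    def test_hits_never_escape_their_pool(self, pilot):
        plan = make_pool_plan(pilot)
        rng = np.random.default_rng(9)
        positions = pilot.positions()
        for _ in range(25):
            k = int(rng.integers(0, 4))
            hits = {positions[i] for i in rng.choice(36, size=k, replace=False)}
            found, _, calls = simulate_screen(plan, hits)
            assert found == hits
            positive_pools = {i for i, v in calls.pool.items() if v}
            for pos in found:
                pool_idx = next(i for i, p in enumerate(plan.pools) if pos in p)
                assert pool_idx in positive_pools

    def test_contradictory_calls_rejected(self, pilot):
        plan = make_pool_plan(pilot)
        calls = ScreenCalls(pool={0: False}, subpool={(0, 0): True})
        with pytest.raises(ConsistencyError):
            deconvolve(plan, calls)

    def test_positive_subpool_without_individuals_returns_members(self, pilot):
        plan = make_pool_plan(pilot)
        calls = ScreenCalls(pool={0: True}, subpool={(0, 0): True, (0, 1): False,
                                                     (0, 2): False})
        assert deconvolve(plan, calls) == set(plan.subpools(0)[0])
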