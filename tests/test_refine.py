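"""In-Plane and Orthogonal refinement: targets, realization, repacking."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from pepmatrix import (
    AMINO_ACIDS,
    KYTE_DOOLITTLE,
    PILOT_TEMPLATE,
    PeptideSequence,
    RefinementSpec,
    gravy,
    in_plane_refine,
    in_plane_targets,
    isoelectric_point,
    orthogonal_refine,
    periodicity_templates,
    repack_sequence,
    summarize,
)
from pepmatrix.refine import bilinear_grid
from pepmatrix.errors import DesignError

ninemers = st.text(alphabet=AMINO_ACIDS, min_size=9, max_size=9)


@pytest.fixture(scope="module")
def corners(pilot):
    return ((pilot[("C", 3)], pilot[("C", 4)]),
            (pilot[("D", 3)], pilot[("D", 4)]))


@pytest.fixture(scope="module")
def in_plane(corners):
    return in_plane_refine(RefinementSpec(corners=corners))


class TestInPlaneTargets:
    def test_pi_axis_mean_step(self):
        # endpoints 5.52 and 6.07 across 4 columns
        grid = bilinear_grid(5.52, 6.07, 5.52, 6.07, (4, 4))
        steps = np.diff(grid, axis=1)
        assert np.mean(np.abs(steps)) == pytest.approx(0.18, abs=0.005)

    def test_gravy_axis_mean_step(self):
        grid = bilinear_grid(1.567, 1.567, 0.455, 0.455, (4, 4))
        steps = np.diff(grid, axis=0)
        assert np.mean(np.abs(steps)) == pytest.approx((1.567 - 0.455) / 3, abs=1e-12)

    def test_steps_smaller_than_corner_differences(self, corners):
        t = in_plane_targets(corners)
        g_span = np.ptp([gravy(p) for row in corners for p in row])
        assert np.all(np.abs(np.diff(t.gravy, axis=0)) < g_span + 1e-12)

    def test_identical_corners_warn_and_flatten(self, pilot):
        p = pilot[("C", 3)]
        with pytest.warns(UserWarning, match="degenerate"):
            t = in_plane_targets(((p, p), (p, p)))
        assert np.ptp(t.gravy) == 0 and np.ptp(t.pi) == 0


class TestInPlaneRefine:
    def test_shape_and_lengths(self, in_plane):
        assert len(in_plane) == 16
        assert all(len(p) == 9 for p in in_plane.peptides())

    def test_realized_gravy_within_pool_reach_of_corners(self, in_plane, corners):
        cg = [gravy(p) for row in corners for p in row]
        for pep in in_plane.peptides():
            assert min(cg) - 0.35 <= gravy(pep) <= max(cg) + 0.35

    def test_realized_row_mean_gravy_monotone(self, in_plane):
        s = summarize(in_plane)
        means = s.row_means.gravy.to_numpy()
        assert np.all(np.diff(means) <= 1e-12)

    def test_realized_pi_monotone_along_columns(self, in_plane):
        for r in in_plane.row_labels:
            pis = [isoelectric_point(in_plane[(r, c)])
                   for c in in_plane.column_indices]
            assert all(a >= b - 1e-9 for a, b in zip(pis, pis[1:]))

    def test_identity_refinement_returns_corners(self, corners):
        spec = RefinementSpec(corners=corners, out_shape=(2, 2))
        lib = in_plane_refine(spec)
        (p00, p01), (p10, p11) = corners
        assert lib[("A", 1)].sequence == p00.sequence
        assert lib[("A", 2)].sequence == p01.sequence
        assert lib[("B", 1)].sequence == p10.sequence
        assert lib[("B", 2)].sequence == p11.sequence


class TestPeriodicityTemplates:
    def test_the_four_masks(self):
        masks = {t.name: t.mask for t in periodicity_templates()}
        assert masks == {
            "block": "HHHHHPPPP",
            "three-three": "HHHPPPHHH",
            "pilot": "HHPPHHPPH",
            "alternating": "HPHPHPHPH",
        }

    def test_alternating_flips_every_pair(self):
        mask = dict((t.name, t.mask) for t in periodicity_templates())["alternating"]
        assert all(a != b for a, b in zip(mask, mask[1:]))

    def test_pilot_hydrophobic_positions(self):
        tmpl = periodicity_templates()[2]
        assert tmpl.h_positions == (1, 2, 5, 6, 9)

    def test_block_puts_all_h_first(self):
        mask = periodicity_templates()[0].mask
        assert mask == "H" * mask.count("H") + "P" * mask.count("P")


class TestRepack:
    def test_same_template_is_identity(self):
        pep = PeptideSequence(id="E4", sequence="AMKDAMERM")
        assert repack_sequence(pep, PILOT_TEMPLATE).sequence == pep.sequence

    def test_block_repack_of_e4(self):
        # hydrophobic class (A,M,A,M,M) then polar class (K,D,E,R), orders kept
        pep = PeptideSequence(id="E4", sequence="AMKDAMERM")
        block = periodicity_templates()[0]
        assert repack_sequence(pep, block).sequence == "AMAMMKDER"

    @given(s=ninemers)
    @settings(derandomize=True, max_examples=50)
    def test_anagram_property(self, s):
        pep = PeptideSequence(id="x", sequence=s)
        for tmpl in periodicity_templates():
            out = repack_sequence(pep, tmpl)
            assert sorted(out.sequence) == sorted(s)

    @given(s=ninemers)
    @settings(derandomize=True, max_examples=50)
    def test_round_trip_when_class_sizes_match(self, s):
        pep = PeptideSequence(id="x", sequence=s)
        alt = periodicity_templates()[3]  # 5H/4P, same as pilot
        there = repack_sequence(pep, alt, source=PILOT_TEMPLATE)
        back = repack_sequence(there, PILOT_TEMPLATE, source=alt)
        assert back.sequence == s

    def test_wrong_length_rejected(self):
        pep = PeptideSequence(id="short", sequence="AMKDA")
        with pytest.raises(DesignError):
            repack_sequence(pep, periodicity_templates()[0])


@pytest.fixture(scope="module")
def diagonal(in_plane):
    return [in_plane[(r, c)] for r, c in
            zip(in_plane.row_labels, in_plane.column_indices)]


class TestOrthogonalRefine:
    def test_size_and_row3_passthrough(self, diagonal):
        lib = orthogonal_refine(diagonal)
        assert len(lib) == 16
        # row C carries the pilot periodicity: the diagonal verbatim
        for j, c in enumerate(lib.column_indices):
            assert lib[("C", c)].sequence == diagonal[j].sequence

    def test_columns_are_anagram_sets(self, diagonal):
        lib = orthogonal_refine(diagonal)
        for j, c in enumerate(lib.column_indices):
            ref = sorted(diagonal[j].sequence)
            for r in lib.row_labels:
                assert sorted(lib[(r, c)].sequence) == ref

    def test_wrong_counts_rejected(self, diagonal):
        with pytest.raises(DesignError):
            orthogonal_refine(diagonal[:3])
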