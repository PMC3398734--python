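"""Encoding geometry: distances, phases, transforms, classes, the matrix."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from veasl.encoding import (
    AffineTransform6,
    ArteryGeometry,
    EncodingCycle,
    EncodingMatrix,
    EncodingScheme,
    RigidTransform3,
    build_encoding_matrix,
    class_matrices,
    encoding_phase,
    four_artery_scheme,
    signed_distance,
)


class TestSignedDistance:
    @pytest.mark.parametrize(
        "loc,centre,theta,expected",
        [
            ((10, 0), (0, 0), 0, 10.0),
            ((0, 10), (0, 0), 270, -10.0),  # pure-y branch
            ((10, 10), (20, 20), 135, 0.0),  # orthogonal displacement
        ],
    )
    def test_reference_values(self, loc, centre, theta, expected):
        cyc = EncodingCycle("spatial", centre[0], centre[1], theta, 10.0)
        assert signed_distance(np.array(loc, float), cyc) == pytest.approx(expected, abs=1e-12)

    def test_requires_spatial_cycle(self):
        with pytest.raises(ValueError):
            signed_distance(np.array([0.0, 0.0]), EncodingCycle("tag_all"))

    @given(
        st.floats(-30, 30), st.floats(-30, 30),
        st.floats(-30, 30), st.floats(-30, 30),
        st.floats(0, 359.9), st.floats(-15, 15), st.floats(-15, 15),
    )
    @settings(derandomize=True, max_examples=40)
    def test_translation_invariance(self, x, y, cx, cy, th, tx, ty):
        c1 = EncodingCycle("spatial", cx, cy, th, 10.0)
        c2 = EncodingCycle("spatial", cx + tx, cy + ty, th, 10.0)
        d1 = signed_distance(np.array([x, y]), c1)
        d2 = signed_distance(np.array([x + tx, y + ty]), c2)
        assert d1 == pytest.approx(d2, abs=1e-9)


class TestEncodingPhase:
    @pytest.mark.parametrize(
        "d,D,expected",
        [(10, 10, np.pi / 2), (0, 7, 0.0), (-30, 10, -3 * np.pi / 2)],
    )
    def test_values(self, d, D, expected):
        assert encoding_phase(d, D) == pytest.approx(expected)

    def test_rejects_nonpositive_scale(self):
        with pytest.raises(ValueError):
            encoding_phase(1.0, 0.0)


class TestTransforms:
    def test_pure_translation(self, corner_arteries):
        t = RigidTransform3(theta_deg=0.0, xd=1.5, yd=3.2)
        got = t.apply(corner_arteries.planned)
        np.testing.assert_allclose(
            got, corner_arteries.planned + [1.5, 3.2], atol=1e-12
        )

    def test_rotation_matrix_as_specified(self):
        # [[cos, sin], [-sin, cos]] rotates (+10, 0) about the centroid to
        # (0, -10) for theta = 90
        pts = np.array([[10.0, 0.0], [-10.0, 0.0]])
        got = RigidTransform3(theta_deg=90.0).apply(pts)
        np.testing.assert_allclose(got, [[0.0, -10.0], [0.0, 10.0]], atol=1e-12)

    def test_identity(self, corner_arteries):
        got = RigidTransform3().apply(corner_arteries.planned)
        np.testing.assert_array_equal(got, corner_arteries.planned)

    def test_affine_identity_and_scaling(self, corner_arteries):
        pts = corner_arteries.planned
        np.testing.assert_array_equal(AffineTransform6().apply(pts), pts)
        doubled = AffineTransform6(a=2.0, d=2.0).apply(pts)
        c = pts.mean(axis=0)
        np.testing.assert_allclose(doubled - c, 2 * (pts - c), atol=1e-12)

    def test_affine_reduces_to_rigid(self, corner_arteries):
        r = RigidTransform3(theta_deg=13.0, xd=0.7, yd=-1.1)
        a = AffineTransform6.from_rigid(r)
        np.testing.assert_allclose(
            a.apply(corner_arteries.planned),
            r.apply(corner_arteries.planned),
            atol=1e-12,
        )

    @given(st.floats(-180, 180), st.floats(-5, 5), st.floats(-5, 5))
    @settings(derandomize=True, max_examples=30)
    def test_rigid_preserves_pairwise_distances(self, th, tx, ty):
        pts = np.array([[10.0, 10.0], [10.0, -10.0], [-3.0, 4.0]])
        moved = RigidTransform3(theta_deg=th, xd=tx, yd=ty).apply(pts)
        d0 = np.linalg.norm(pts[:, None] - pts[None, :], axis=-1)
        d1 = np.linalg.norm(moved[:, None] - moved[None, :], axis=-1)
        np.testing.assert_allclose(d0, d1, atol=1e-9)


class TestEncodingMatrix:
    def test_reference_scheme_row_signs(self, scheme6, corner_arteries):
        # cycle 3 (x-encoding at the origin) tags the left arteries and
        # controls the right; cycle 4 swaps them
        E = build_encoding_matrix(scheme6, corner_arteries).values
        x = corner_arteries.planned[:, 0]
        np.testing.assert_allclose(E[2, :4], np.where(x > 0, 1.0, -1.0), atol=1e-9)
        np.testing.assert_allclose(E[3, :4], np.where(x > 0, -1.0, 1.0), atol=1e-9)

    def test_tag_control_rows(self, scheme6, corner_arteries):
        E = build_encoding_matrix(scheme6, corner_arteries).values
        np.testing.assert_allclose(E[0, :4], -1.0)
        np.testing.assert_allclose(E[1, :4], 1.0)

    def test_static_column_all_ones(self, scheme8, corner_arteries):
        E = build_encoding_matrix(scheme8, corner_arteries).values
        np.testing.assert_array_equal(E[:, -1], 1.0)

    def test_rank_structure(self, scheme6, scheme8, corner_arteries):
        E6 = build_encoding_matrix(scheme6, corner_arteries).values
        E8 = build_encoding_matrix(scheme8, corner_arteries).values
        assert np.linalg.matrix_rank(E6) == 4
        assert np.linalg.matrix_rank(E8) == 5

    def test_tag_control_only_independent_of_locations(self):
        sch = EncodingScheme((EncodingCycle("tag_all"), EncodingCycle("control_all")))
        a1 = ArteryGeometry(names=["a"], planned=[[0.0, 0.0]])
        a2 = ArteryGeometry(names=["a"], planned=[[7.0, -3.0]])
        np.testing.assert_array_equal(
            build_encoding_matrix(sch, a1).values,
            build_encoding_matrix(sch, a2).values,
        )

    def test_validates_static_column(self):
        with pytest.raises(ValueError):
            EncodingMatrix(values=np.array([[1.0, 0.5], [1.0, 0.5]]).T)


class TestClassMatrices:
    def test_pairs_of_three_match_reference(self):
        # the three size-2 selection matrices for M=3
        spec = class_matrices(3, 2, mode="exact")
        assert spec.subsets == ((0, 1), (0, 2), (1, 2))
        want_01 = np.array(
            [[1, 0, 0], [0, 1, 0], [0, 0, 0], [0, 0, 1]], dtype=float
        )
        np.testing.assert_array_equal(spec.selection[0], want_01)
        for P, sub in zip(spec.selection, spec.subsets):
            assert P.shape == (4, 3)
            np.testing.assert_array_equal(P.sum(axis=0), 1.0)

    @pytest.mark.parametrize("M,L,mode,count", [
        (4, 2, "upto", 11),
        (4, 1, "upto", 5),
        (4, 2, "exact", 6),
        (3, 3, "upto", 8),
    ])
    def test_class_counts(self, M, L, mode, count):
        assert class_matrices(M, L, mode=mode).n_classes == count

    def test_rejects_bad_sizes(self):
        with pytest.raises(ValueError):
            class_matrices(3, 4)
        with pytest.raises(ValueError):
            class_matrices(3, -1)

    def test_selection_semantics(self, scheme8, corner_arteries):
        # E @ P_c equals the selected artery columns plus the static column
        E = build_encoding_matrix(scheme8, corner_arteries).values
        spec = class_matrices(4, 2)
        for c, P in enumerate(spec.selection):
            picked = E @ P
            np.testing.assert_array_equal(picked, E[:, spec.column_indices(c)])


class TestRoundTrips:
    def test_scheme_csv(self, tmp_path, scheme8):
        p = tmp_path / "scheme.csv"
        scheme8.to_csv(p)
        back = EncodingScheme.from_csv(p)
        assert back == scheme8

    def test_arteries_csv(self, tmp_path, corner_arteries):
        p = tmp_path / "arteries.csv"
        corner_arteries.to_csv(p)
        back = ArteryGeometry.from_csv(p)
        assert back.names == corner_arteries.names
        np.testing.assert_array_equal(back.planned, corner_arteries.planned)
        np.testing.assert_array_equal(back.speeds, corner_arteries.speeds)
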