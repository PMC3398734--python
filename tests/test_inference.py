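"""The marginalized posterior and the flow estimator.

The key check is an independent brute-force oracle: the analytic objective
(projection residuals to the power -N/2) must agree with a dense-grid
numerical marginalization of the Gaussian likelihood over the flow vector
and noise precision under the joint flow/precision prior.
"""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.special import gammaln

from veasl.encoding import (
    ArteryGeometry,
    ClassSpec,
    build_encoding_matrix,
    class_matrices,
    four_artery_scheme,
)
from veasl.model import (
    VEASLModel,
    class_residuals,
    estimate_flow,
    marginal_neg_log_posterior,
)
from veasl.model import _class_posteriors  # noqa: internal, used as reference


def oracle_neg_log_marginal(E, y):
    """-log of the marginal likelihood by dense grid integration over the
    flow vector (precision integral via the Gamma identity).

    The grid lives in whitened coordinates ``f = f_lsq + L g`` so that the
    quadrature resolves the posterior ridge for any conditioning of ``E``;
    residuals at the grid points are evaluated directly from ``||y - E f||^2``.
    """
    E = np.asarray(E, float)
    y = np.asarray(y, float)
    N, d = E.shape
    fhat, *_ = np.linalg.lstsq(E, y, rcond=None)
    rhat = float(np.sum((y - E @ fhat) ** 2))
    rr = max(rhat, 1e-12 * float(np.sum(y**2)))
    Sig = np.linalg.inv(E.T @ E)
    L = np.linalg.cholesky(Sig * rr)
    half, npts = (40.0, 241) if d == 2 else (30.0, 121)
    g1 = np.linspace(-half, half, npts)
    mesh = np.meshgrid(*([g1] * d), indexing="ij")
    G = np.stack([m.ravel() for m in mesh], axis=1)
    F = fhat[None, :] + G @ L.T
    r = np.sum((y[None, :] - F @ E.T) ** 2, axis=1)
    a = (N + d) / 2.0
    log_inner = gammaln(a) + a * np.log(2.0) - a * np.log(r)
    m = log_inner.max()
    integral = np.exp(log_inner - m).reshape([npts] * d)
    dx = g1[1] - g1[0]
    for _ in range(d):
        integral = np.trapezoid(integral, dx=dx, axis=0)
    _, logdetL = np.linalg.slogdet(L)
    _, logdetG = np.linalg.slogdet(E.T @ E)
    return -(m + np.log(integral) + logdetL + 0.5 * logdetG
             - 0.5 * N * np.log(2 * np.pi))


def _single_class(M: int) -> ClassSpec:
    return ClassSpec(n_arteries=M, max_per_class=M, subsets=(tuple(range(M)),))


class TestMarginalPosteriorOracle:
    def test_matches_grid_marginalization(self):
        """Analytic objective differences track the brute-force marginal on
        random one-voxel toys to 1e-4 relative after constant alignment."""
        rng = np.random.default_rng(7)
        for _ in range(10):
            M = int(rng.integers(1, 3))
            N = int(rng.integers(4, 7))
            spec = _single_class(M)
            f_true = rng.normal(size=M + 1)
            Es = [
                np.column_stack([rng.uniform(-1, 1, size=(N, M)), np.ones(N)])
                for _ in range(2)
            ]
            y = Es[0] @ f_true + 0.3 * rng.normal(size=N)
            impl = np.array(
                [marginal_neg_log_posterior(E, spec, np.array([1.0]), y[None, :])
                 for E in Es]
            )
            orc = np.array([oracle_neg_log_marginal(E, y) for E in Es])
            di = impl - impl.mean()
            do = orc - orc.mean()
            assert np.max(np.abs(di - do)) <= 1e-4 * max(1.0, np.ptp(orc))

    def test_residual_ratio_form(self):
        """With one all-artery class and flat priors, objective differences
        equal -(N/2) log of the residual-norm ratio."""
        rng = np.random.default_rng(1)
        M, N = 2, 6
        spec = _single_class(M)
        y = rng.normal(size=(1, N))
        E1 = np.column_stack([rng.uniform(-1, 1, (N, M)), np.ones(N)])
        E2 = np.column_stack([rng.uniform(-1, 1, (N, M)), np.ones(N)])
        r1 = class_residuals(E1, spec, y)[0, 0]
        r2 = class_residuals(E2, spec, y)[0, 0]
        d_obj = (
            marginal_neg_log_posterior(E2, spec, np.array([1.0]), y)
            - marginal_neg_log_posterior(E1, spec, np.array([1.0]), y)
        )
        assert d_obj == pytest.approx(0.5 * N * np.log(r2 / r1), rel=1e-10)

    @given(st.floats(0.01, 100.0))
    @settings(derandomize=True, max_examples=20)
    def test_data_rescaling_shifts_by_constant(self, lam):
        rng = np.random.default_rng(3)
        arts = ArteryGeometry(
            names=list("abcd"),
            planned=[[10, 10], [10, -10], [-10, 10], [-10, -10]],
        )
        E = build_encoding_matrix(four_artery_scheme(6), arts)
        spec = class_matrices(4, 2)
        Y = rng.normal(size=(9, 6))
        pis = [np.full(spec.n_classes, 1 / spec.n_classes),
               rng.dirichlet(np.ones(spec.n_classes))]
        shifts = [
            marginal_neg_log_posterior(E, spec, pi, lam * Y)
            - marginal_neg_log_posterior(E, spec, pi, Y)
            for pi in pis
        ]
        # the shift is independent of the parameters: posterior unchanged
        assert shifts[0] == pytest.approx(shifts[1], abs=1e-6)


class TestClassPosteriors:
    def test_rows_sum_to_one_and_scale_invariant(self):
        rng = np.random.default_rng(5)
        arts = ArteryGeometry(
            names=list("abcd"),
            planned=[[10, 10], [10, -10], [-10, 10], [-10, -10]],
        )
        E = build_encoding_matrix(four_artery_scheme(8), arts)
        spec = class_matrices(4, 2)
        pi = rng.dirichlet(np.ones(spec.n_classes))
        Y = rng.normal(size=(50, 8))
        w = _class_posteriors(E, spec, pi, Y)
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-10)
        w2 = _class_posteriors(E, spec, pi, 31.7 * Y)
        np.testing.assert_allclose(w, w2, atol=1e-9)

    def test_equal_residuals_give_uniform_posteriors(self):
        # zero data: every class has the (floored) zero residual
        spec = class_matrices(2, 2)  # 4 classes: empty, two singles, the pair
        E = np.array([[1.0, -1.0, 1.0], [-1.0, 1.0, 1.0], [1.0, 1.0, 1.0],
                      [0.5, -0.5, 1.0]])
        w = _class_posteriors(E, spec, np.full(4, 0.25), np.zeros((3, 4)))
        np.testing.assert_allclose(w, 0.25, atol=1e-12)

    def test_hand_computed_two_class_posterior(self):
        # one voxel, two single-artery classes: p_c ~ pi_c r_c^{-N/2}
        E = np.array(
            [[-1.0, -1.0, 1.0], [1.0, 1.0, 1.0], [1.0, -1.0, 1.0],
             [-1.0, 1.0, 1.0]]
        )
        spec = ClassSpec(n_arteries=2, max_per_class=1, subsets=((0,), (1,)))
        y = np.array([[0.2, 1.4, 1.1, -0.3]])
        pi = np.array([0.3, 0.7])
        r = class_residuals(E, spec, y)[0]
        expect = pi * r ** (-2.0)
        expect = expect / expect.sum()
        got = _class_posteriors(E, spec, pi, y)[0]
        np.testing.assert_allclose(got, expect, rtol=1e-12)


class TestEstimateFlow:
    def test_noiseless_recovery_single_class(self, scheme8, corner_arteries):
        rng = np.random.default_rng(11)
        E = build_encoding_matrix(scheme8, corner_arteries)
        f = rng.normal(size=(20, 5))
        Y = f @ E.values.T
        from veasl.model import VEASLImage

        flow, w, phi = estimate_flow(
            E, _single_class(4), np.array([1.0]), VEASLImage(Y)
        )
        np.testing.assert_allclose(flow[:, :, 0], f, atol=1e-9)

    def test_label_equivariance_under_artery_permutation(self, scheme8):
        rng = np.random.default_rng(13)
        names = list("abcd")
        planned = np.array([[10.0, 10.0], [10.0, -10.0], [-10.0, 10.0], [-10.0, -10.0]])
        perm = np.array([2, 0, 3, 1])
        a1 = ArteryGeometry(names=names, planned=planned)
        a2 = ArteryGeometry(names=[names[i] for i in perm], planned=planned[perm])
        Y = rng.normal(size=(40, 8))
        from veasl.model import VEASLImage

        spec = class_matrices(4, 1)
        pi = np.full(spec.n_classes, 1 / spec.n_classes)
        E1 = build_encoding_matrix(scheme8, a1)
        E2 = build_encoding_matrix(scheme8, a2)
        f1, _, _ = estimate_flow(E1, spec, pi, VEASLImage(Y))
        f2, _, _ = estimate_flow(E2, spec, pi, VEASLImage(Y))
        # artery planes permute with the artery labels; static unchanged
        np.testing.assert_allclose(f1[:, perm, 0], f2[:, :4, 0], atol=1e-9)
        np.testing.assert_allclose(f1[:, 4, 0], f2[:, 4, 0], atol=1e-9)

    def test_multiframe_flow_with_fixed_posteriors(self, scheme8, corner_arteries):
        # global/class information from the first frame, flow per frame
        rng = np.random.default_rng(29)
        E = build_encoding_matrix(scheme8, corner_arteries)
        f = rng.normal(size=(15, 5, 4))  # 4 frames
        Y = np.einsum("nm,vmt->vnt", E.values, f)
        from veasl.model import VEASLImage

        flow, w, _ = estimate_flow(
            E, _single_class(4), np.array([1.0]), VEASLImage(Y)
        )
        np.testing.assert_allclose(flow, f, atol=1e-9)
        assert w.shape == (15, 1)

    def test_per_frame_posteriors_option(self, scheme6, corner_arteries):
        rng = np.random.default_rng(31)
        Y = rng.normal(size=(20, 6, 3))
        spec = class_matrices(4, 1)
        E = build_encoding_matrix(scheme6, corner_arteries)
        from veasl.model import VEASLImage

        flow, w, _ = estimate_flow(
            E, spec, np.full(spec.n_classes, 1 / spec.n_classes),
            VEASLImage(Y), posterior_frames="each",
        )
        assert flow.shape == (20, 5, 3)
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-9)

    def test_complex_data_supported(self, scheme6, corner_arteries):
        rng = np.random.default_rng(17)
        E = build_encoding_matrix(scheme6, corner_arteries)
        f = rng.normal(size=(10, 5)) + 1j * rng.normal(size=(10, 5))
        Y = f @ E.values.T
        from veasl.model import VEASLImage

        spec = class_matrices(4, 2)
        flow, w, _ = estimate_flow(
            E, spec, np.full(spec.n_classes, 1 / spec.n_classes), VEASLImage(Y)
        )
        assert np.iscomplexobj(flow)
        np.testing.assert_allclose(w.sum(axis=1), 1.0, atol=1e-10)


class TestFixedGeometryDecoders:
    def test_bi_equals_mi_at_full_rank_single_class(self, scheme8, corner_arteries):
        rng = np.random.default_rng(19)
        Y = rng.normal(size=(30, 8))
        m = VEASLModel(Y, scheme8, corner_arteries, apc=4, class_mode="exact")
        f_mi = m.fit("MI").flow
        f_bi = m.fit("BI").flow
        np.testing.assert_allclose(f_mi, f_bi, atol=1e-10)

    def test_mi_minimum_norm_on_rank_deficient_data(self, scheme6, corner_arteries):
        rng = np.random.default_rng(23)
        Y = rng.normal(size=(12, 6))
        m = VEASLModel(Y, scheme6, corner_arteries)
        res = m.fit("MI")
        E = res.encoding.values
        # residual orthogonal to the column space of E
        resid = Y - res.flow[:, :, 0] @ E.T
        np.testing.assert_allclose(resid @ E, 0.0, atol=1e-9)
        # minimum-norm: the solution has no null-space component
        _, _, Vt = np.linalg.svd(E)
        null = Vt[np.linalg.matrix_rank(E):]
        np.testing.assert_allclose(res.flow[:, :, 0] @ null.T, 0.0, atol=1e-9)

    def test_zero_data_zero_flow_uniform_posteriors(self, scheme6, corner_arteries):
        m = VEASLModel(np.zeros((9, 6)), scheme6, corner_arteries, apc=2)
        r_mi = m.fit("MI")
        np.testing.assert_array_equal(r_mi.flow, 0.0)
        r_bi = m.fit("BI")
        np.testing.assert_allclose(r_bi.flow, 0.0, atol=1e-12)
        np.testing.assert_allclose(r_bi.class_posteriors, 1.0 / 11.0, atol=1e-12)

    def test_bi_uniform_proportions_over_upto_classes(self, scheme6, corner_arteries):
        m = VEASLModel(np.zeros((4, 6)), scheme6, corner_arteries, apc=2)
        res = m.fit("BI")
        assert m.classes.n_classes == 11
        np.testing.assert_allclose(res.params.pi, 1.0 / 11.0)


class TestRidgeStabilization:
    def test_duplicate_arteries_warn_not_raise(self, scheme6):
        # two arteries at the same location make pair submatrices singular
        arts = ArteryGeometry(names=["a", "b"], planned=[[10.0, 0.0], [10.0, 0.0]])
        E = build_encoding_matrix(scheme6, arts)
        spec = class_matrices(2, 2)
        Y = np.random.default_rng(0).normal(size=(5, 6))
        with pytest.warns(RuntimeWarning):
            r = class_residuals(E, spec, Y)
        assert np.all(np.isfinite(r))
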