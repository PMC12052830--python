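"""Fisher information, CRB closed form, maps, EFOV, optimal L, Van Trees."""

import math

import numpy as np
import pytest

from vortexflux import (
    ExposurePattern,
    PhotonModel,
    PriorModel,
    VortexBeam,
    bayesian_crb,
    central_crb_closed_form,
    crb_map,
    crb_sigma,
    efov_diameter,
    fisher_field,
    fisher_matrix,
    make_four_point_tcp,
    make_raster_tcp,
    optimal_pattern_size,
    probability_field,
    sigma_field,
)


def _model(l=1, L=50.0, sbr=math.inf, mode="all_exposures", kind="four_point",
           dim=4, N=100, n=1, p=0):
    pat = make_four_point_tcp(L) if kind == "four_point" else \
        make_raster_tcp(L, dim)
    return PhotonModel(
        beam=VortexBeam(l=l, p=p, waist=300.0, photon_order=n),
        pattern=pat, n_photons=N, sbr=sbr, sbr_mode=mode,
    )


class TestFisherMatrix:
    @pytest.mark.parametrize("kind", ["four_point", "raster"])
    def test_center_is_isotropic(self, kind):
        J = fisher_matrix([0.0, 0.0], _model(kind=kind, sbr=4.0)).fisher
        assert J[0, 0] == pytest.approx(J[1, 1], rel=1e-9)
        assert J[0, 1] == pytest.approx(0.0, abs=1e-12 * J[0, 0])

    def test_noiseless_center_closed_form(self):
        # J_xx = N g^2 / 2 with g = (4/L)(|l| - L^2/(2 w^2))
        model = _model(l=1, L=50.0)
        J = fisher_matrix([0.0, 0.0], model).fisher
        g = (4.0 / 50.0) * (1.0 - 50.0**2 / (2 * 300.0**2))
        assert J[0, 0] == pytest.approx(100 * g**2 / 2, rel=1e-9)

    def test_analytic_gradients_match_finite_differences(self):
        rng = np.random.default_rng(42)
        model = _model(sbr=4.0)
        pos = rng.uniform(-20, 20, size=(20, 2))
        h = 1e-3
        J_an = fisher_field(model, pos)
        for m, r in enumerate(pos):
            grads = np.empty((model.pattern.n_exposures, 2))
            for ax in range(2):
                dr = np.zeros(2)
                dr[ax] = h
                pp = probability_field(model, (r + dr)[None])[0]
                pm = probability_field(model, (r - dr)[None])[0]
                grads[:, ax] = (pp - pm) / (2 * h)
            p0 = probability_field(model, r[None])[0]
            J_fd = model.n_photons * np.einsum(
                "k,ki,kj->ij", 1.0 / p0, grads, grads
            )
            np.testing.assert_allclose(J_an[m], J_fd, rtol=1e-6)

    def test_positive_semidefinite_everywhere(self):
        rng = np.random.default_rng(3)
        for kind in ("four_point", "raster"):
            model = _model(kind=kind, sbr=4.0)
            J = fisher_field(model, rng.uniform(-40, 40, size=(50, 2)))
            evals = np.linalg.eigvalsh(J)
            assert np.all(evals >= -1e-9 * np.abs(evals).max())

    def test_dark_exposure_limit_behaviour(self):
        # noiseless, emitter -> center.  For |l| >= 2 the dark exposure's
        # Fisher weight |grad p|^2 / p vanishes, so dropping the p = 0 term
        # is exact.  For l = 1 the weight tends to a finite constant (the
        # relative rate change d(lam)/lam ~ 2/r diverges at a perfect
        # zero); at exactly r = 0 no photon ever lands there and only the
        # ring exposures inform the bound, which is what the closed form
        # expresses.
        from vortexflux.photon_model import probability_gradient_field

        model2 = _model(l=2)
        vals2 = []
        for eps in (1.0, 0.1, 0.01):
            p, g = probability_gradient_field(model2, [[eps, 0.0]])
            vals2.append(float(np.sum(g[0, 0] ** 2) / p[0, 0]))
        assert vals2[0] > vals2[1] > vals2[2]
        assert vals2[2] < 1e-8

        model1 = _model(l=1)
        vals1 = []
        for eps in (0.1, 0.01, 0.001):
            p, g = probability_gradient_field(model1, [[eps, 0.0]])
            vals1.append(float(np.sum(g[0, 0] ** 2) / p[0, 0]))
        # finite, position-independent limit
        assert vals1[0] == pytest.approx(vals1[2], rel=1e-3)


class TestCentralCrb:
    def test_noiseless_value(self):
        # frozen: (50 / (2 sqrt(200))) / (1 - 2500/180000)
        res = crb_sigma([0.0, 0.0], _model())
        assert res.sigma == pytest.approx(1.792665079, rel=1e-8)

    def test_all_exposures_value(self):
        res = crb_sigma([0.0, 0.0], _model(sbr=4.0, mode="all_exposures"))
        assert res.sigma == pytest.approx(2.184092232, rel=1e-8)

    def test_signal_exposures_matches_reported_precision(self):
        res = crb_sigma([0.0, 0.0], _model(sbr=4.0, mode="signal_exposures"))
        assert res.sigma == pytest.approx(2.31, abs=0.005)

    @pytest.mark.parametrize("l", [1, 2, 3])
    @pytest.mark.parametrize("L", [20.0, 35.0, 50.0, 65.0, 80.0])
    @pytest.mark.parametrize("sbr", [math.inf, 4.0])
    def test_closed_form_equals_numeric(self, l, L, sbr):
        model = _model(l=l, L=L, sbr=sbr, mode="all_exposures")
        numeric = crb_sigma([0.0, 0.0], model).sigma
        closed = central_crb_closed_form(model)
        assert numeric == pytest.approx(closed, rel=1e-6)

    def test_third_order_noiseless_frozen(self):
        assert central_crb_closed_form(_model(l=3)) == pytest.approx(
            0.5919963749, rel=1e-8
        )

    def test_order_improvement_ratio(self):
        # noiseless ratio sigma(l=2)/sigma(l=1) = (1 - L^2/2w^2)/(2 - L^2/2w^2)
        r = central_crb_closed_form(_model(l=2)) / central_crb_closed_form(_model(l=1))
        assert r == pytest.approx(0.4965034965, rel=1e-9)

    def test_multiphoton_scaling(self):
        s1 = crb_sigma([0.0, 0.0], _model(n=1)).sigma
        s2 = crb_sigma([0.0, 0.0], _model(n=2)).sigma
        assert s2 == pytest.approx(s1 / 2, rel=1e-9)

    def test_rejects_oversized_pattern(self):
        with pytest.raises(ValueError):
            central_crb_closed_form(_model(l=1, L=500.0))

    def test_result_invariants(self):
        res = crb_sigma([5.0, 3.0], _model(sbr=4.0))
        cov = res.covariance
        assert res.sigma == pytest.approx(
            math.sqrt(0.5 * np.trace(cov)), rel=1e-12
        )
        assert res.eigenvalues[0] <= res.sigma**2 <= res.eigenvalues[-1]
        np.testing.assert_allclose(res.fisher @ cov, np.eye(2), atol=1e-9)

    def test_singular_fisher_flagged_not_raised(self):
        # one exposure: p = 1 everywhere, so the counts carry no
        # positional information at all
        pat = ExposurePattern(kind="custom", size=1.0,
                              positions=np.array([[0.0, 0.0]]))
        model = PhotonModel(beam=VortexBeam(l=1), pattern=pat, sbr=math.inf)
        res = crb_sigma([5.0, 0.0], model)
        assert not res.identifiable
        assert math.isnan(res.sigma)


class TestRadialIndexEffect:
    def test_near_identical_at_small_L_divergence_grows(self):
        for l in (1, 2):
            devs = []
            for L in (25.0, 60.0, 100.0):
                s0 = crb_sigma([0.0, 0.0], _model(l=l, L=L, sbr=4.0)).sigma
                s1 = crb_sigma([0.0, 0.0], _model(l=l, L=L, sbr=4.0, p=1)).sigma
                devs.append(abs(s1 - s0) / s0)
            assert devs[0] < 0.02
            assert devs[0] < devs[1] < devs[2]

    def test_divergence_shrinks_with_order(self):
        def dev(l):
            s0 = crb_sigma([0.0, 0.0], _model(l=l, L=100.0, sbr=4.0)).sigma
            s1 = crb_sigma([0.0, 0.0], _model(l=l, L=100.0, sbr=4.0, p=1)).sigma
            return abs(s1 - s0) / s0

        assert dev(3) < dev(2) < dev(1)


class TestMapsAndSymmetry:
    def test_four_point_map_120_degree_symmetry(self):
        model = _model(sbr=4.0)
        rng = np.random.default_rng(5)
        pos = rng.uniform(-25, 25, size=(30, 2))
        c, s = math.cos(2 * math.pi / 3), math.sin(2 * math.pi / 3)
        R = np.array([[c, -s], [s, c]])
        np.testing.assert_allclose(
            sigma_field(model, pos), sigma_field(model, pos @ R.T), rtol=1e-9
        )

    def test_raster_map_90_degree_symmetry(self):
        model = _model(kind="raster", sbr=4.0)
        rng = np.random.default_rng(6)
        pos = rng.uniform(-25, 25, size=(30, 2))
        R = np.array([[0.0, -1.0], [1.0, 0.0]])
        np.testing.assert_allclose(
            sigma_field(model, pos), sigma_field(model, pos @ R.T), rtol=1e-9
        )

    def test_map_center_consistent_with_pointwise(self):
        model = _model(sbr=4.0)
        pmap = crb_map(model, roi_half_width=10.0, grid_step=5.0)
        i = len(pmap.x) // 2
        assert pmap.sigma[i, i] == pytest.approx(
            crb_sigma([0.0, 0.0], model).sigma, rel=1e-12
        )
        df = pmap.to_frame()
        assert {"x_nm", "y_nm", "sigma_nm", "sigma_max_nm",
                "sigma_min_nm", "axis_angle_rad"} <= set(df.columns)

    @pytest.mark.parametrize("kind", ["four_point", "raster"])
    def test_monotone_increase_along_x_ray(self, kind):
        model = _model(kind=kind, sbr=4.0)
        r = np.linspace(0.0, 25.0, 26)
        sig = sigma_field(model, np.c_[r, np.zeros_like(r)])
        assert np.all(np.diff(sig) > -1e-12)


class TestEfov:
    def test_zero_when_center_fails_threshold(self):
        model = _model(sbr=4.0, mode="signal_exposures")
        assert efov_diameter(model, threshold=1.0) == 0.0

    def test_first_order_diameter_matches_reported(self):
        model = _model(sbr=4.0, mode="all_exposures")
        assert efov_diameter(model, 4.0) == pytest.approx(35.85, abs=0.05)

    def test_mean_definition_is_no_smaller(self):
        model = _model(sbr=4.0)
        worst = efov_diameter(model, 4.0, definition="worst_case")
        mean = efov_diameter(model, 4.0, definition="azimuthal_mean")
        assert mean >= worst


class TestOptimalL:
    def test_noiseless_has_no_interior_minimum(self):
        res = optimal_pattern_size(_model(), (10.0, 100.0))
        assert res.boundary
        assert res.L_star == 10.0

    def test_first_order_minimum(self):
        res = optimal_pattern_size(
            _model(sbr=4.0, mode="all_exposures"), (10.0, 100.0),
            sbr_anchor=(4.0, 50.0),
        )
        assert not res.boundary
        assert 22.0 <= res.L_star <= 23.0
        assert res.sigma_star == pytest.approx(1.64, abs=0.01)

    def test_curve_is_returned(self):
        res = optimal_pattern_size(_model(sbr=4.0), (20.0, 30.0))
        assert set(res.curve.columns) == {"L_nm", "sigma_nm"}
        assert len(res.curve) == 11


class TestBayesian:
    def test_no_photons_returns_prior_std(self):
        model = _model(sbr=4.0, N=0)
        assert bayesian_crb(model, PriorModel(50.0)) == 50.0

    def test_monotone_in_photon_budget(self):
        vals = [
            bayesian_crb(_model(sbr=4.0, N=N), PriorModel(50.0), quad_order=41)
            for N in (0, 50, 100, 200)
        ]
        assert all(a >= b for a, b in zip(vals, vals[1:]))

    def test_tight_prior_dominates(self):
        model = _model(sbr=4.0)
        assert bayesian_crb(model, PriorModel(0.5)) < 0.5

    def test_first_order_matches_reported(self):
        model = _model(sbr=4.0, mode="all_exposures")
        assert bayesian_crb(model, PriorModel(50.0)) == pytest.approx(
            6.95, rel=0.005
        )
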