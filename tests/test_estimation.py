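import math

import numpy as np
import pytest

from oracles import (
    agq_marginal,
    agq_marginal_2d,
    els_sum,
    gls_standard_errors,
    linear_gaussian_m2ll,
)

from htr3mix import synthetic_data as sd
from htr3mix.estimation import (
    ModelSpec,
    fit_logistic_ls,
    fit_model,
    information_criteria,
    inner_objective,
    laplace_marginal,
    standard_errors,
)
from htr3mix.population_model import (
    OmegaMatrix,
    RandomEffectsSpec,
    RuvParameters,
    individual_parameters,
    ruv_variance,
)
from htr3mix.structural_model import (
    DrugParams,
    ObservationRecord,
    PopulationParameters,
    predict_peak,
    pxc50_to_conc,
)

from conftest import (
    small_citral_design,
    small_citral_model,
    small_citral_population,
)


def linear_toy(y, max0=4.0, omega_sd=0.8, alpha=0.4):
    """y_i = max0 + eta + e: agonist at 1 M makes the Hill factor exactly 1."""
    pop = PopulationParameters(max0=max0, pec50_0=5.65, nh_a=2.94)
    spec = RandomEffectsSpec(entries=(("max0", "additive"),))
    omega = OmegaMatrix(np.array([[omega_sd**2]]))
    ruv = RuvParameters(alpha=alpha, gamma=0.0)
    recs = [ObservationRecord(oocyte_id="o", agonist_conc=1.0,
                              peak_current=v) for v in y]
    return recs, pop, spec, omega, ruv


class TestInnerObjective:
    def setup_method(self):
        self.pop = PopulationParameters(
            max0=4.94, pec50_0=5.65, nh_a=2.94,
            drugs={"citral": DrugParams(pic50=3.92, nh=1.34)},
        )
        self.spec = RandomEffectsSpec(
            entries=(("pec50_0", "additive"), ("max0", "exponential"))
        )
        self.omega = OmegaMatrix(np.eye(2))
        self.ruv = RuvParameters(alpha=0.3, gamma=1.3)

    def recs(self, concs):
        return [
            ObservationRecord(oocyte_id="o", agonist_conc=c,
                              peak_current=0.0)
            for c in concs
        ]

    def test_perfect_fit_leaves_log_variance_terms(self):
        concs = [1e-6, 3e-6, 1e-5]
        recs = []
        for c in concs:
            pred = predict_peak(
                ObservationRecord(oocyte_id="o", agonist_conc=c),
                self.pop,
            )
            recs.append(ObservationRecord(
                oocyte_id="o", agonist_conc=c, peak_current=pred
            ))
        expected = sum(
            math.log(ruv_variance(r.peak_current, self.ruv))
            for r in recs
        )
        got = inner_objective(recs, self.pop, np.zeros(2), self.spec,
                              self.omega, self.ruv)
        assert got == pytest.approx(expected, abs=1e-12)

    def test_unit_standardized_residual(self):
        c = 3e-6
        pred = predict_peak(
            ObservationRecord(oocyte_id="o", agonist_conc=c), self.pop
        )
        v = ruv_variance(pred, self.ruv)
        rec = ObservationRecord(oocyte_id="o", agonist_conc=c,
                                peak_current=pred + math.sqrt(v))
        got = inner_objective([rec], self.pop, np.zeros(2), self.spec,
                              self.omega, self.ruv)
        assert got == pytest.approx(1.0 + math.log(v), abs=1e-12)

    def test_matches_straight_line_summation(self):
        concs = [1e-6, 3e-6, 1e-5]
        eta = np.array([0.15, -0.3])
        ind = individual_parameters(self.pop, eta, self.spec)
        preds, variances, y = [], [], [1.1, 2.0, 3.4]
        for c in concs:
            p = predict_peak(
                ObservationRecord(oocyte_id="o", agonist_conc=c), ind
            )
            preds.append(p)
            variances.append(ruv_variance(p, self.ruv))
        recs = [
            ObservationRecord(oocyte_id="o", agonist_conc=c,
                              peak_current=v)
            for c, v in zip(concs, y)
        ]
        expected = els_sum(y, preds, variances, eta, self.omega.matrix)
        got = inner_objective(recs, self.pop, eta, self.spec,
                              self.omega, self.ruv)
        assert got == pytest.approx(expected, rel=1e-12)

    def test_singular_omega_rejected(self):
        recs = self.recs([1e-6])
        with pytest.raises(np.linalg.LinAlgError):
            inner_objective(recs, self.pop, np.zeros(2), self.spec,
                            OmegaMatrix(np.zeros((2, 2))), self.ruv)


class TestVectorizedEngineAgreement:
    def test_inner_objective_matches_scalar_path_all_groups(
        self, reference
    ):
        """The batched engine reproduces the scalar inner objective for
        every oocyte class, including the T6'S covariate shifts."""
        from htr3mix import _core
        from htr3mix.population_model import (
            OmegaMatrix as OM,
            RandomEffectsSpec as RES,
        )

        pop, respec = reference["pop"], reference["respec"]
        omega, ruv = reference["omega"], reference["ruv"]
        design = sd.reference_design(include_t6s=True)
        data = sd.simulate_dataset(design, pop, respec, omega, ruv,
                                   seed=17)
        by_oocyte: dict[str, list] = {}
        for r in data:
            by_oocyte.setdefault(r.oocyte_id, []).append(r)
        compiled = _core.compile_dataset(data, respec,
                                         tuple(pop.drugs))
        table = compiled.table.from_population(pop)[None]
        rng = np.random.default_rng(0)
        worst = 0.0
        for group in compiled.groups:
            st = _core.assemble_instances(
                group, table, omega.matrix[None],
                np.array([ruv.alpha]), np.array([ruv.gamma]),
            )
            eta = rng.normal(0.0, 0.3, (st.M, 1, group.ka))
            g_vec, _ = _core._evaluate(st, eta, want_grad=False)
            sub_spec = RES(entries=tuple(
                respec.entries[j] for j in group.active
            ))
            sub_omega = OM(omega.submatrix(group.active))
            for i, oid in enumerate(group.oocyte_ids):
                g_scalar = inner_objective(
                    by_oocyte[oid], pop, eta[i, 0], sub_spec,
                    sub_omega, ruv,
                )
                worst = max(worst, abs(g_scalar - g_vec[i, 0]))
        assert worst < 1e-8


class TestLaplaceMarginal:
    def test_equals_closed_form_linear_gaussian(self):
        y = [4.5, 3.8, 4.2, 5.0]
        recs, pop, spec, omega, ruv = linear_toy(y)
        contrib, eta_hat = laplace_marginal(recs, pop, spec, omega, ruv)
        exact = linear_gaussian_m2ll(y, 4.0, 0.4**2, 0.8**2)
        assert contrib == pytest.approx(exact, abs=1e-8)
        assert eta_hat.shape == (1,)

    def test_zero_variance_limit_recovers_inner_objective(self):
        """As omega -> 0 the contribution approaches the eta = 0 data fit.

        The penalty's ln det Omega and the Hessian's ln det(Omega^-1)
        cancel, leaving only the data terms of the inner objective.
        """
        y = [4.5, 3.8, 4.2, 5.0]
        recs, pop, spec, _, ruv = linear_toy(y)
        omega = OmegaMatrix(np.array([[1e-10]]))
        contrib, eta_hat = laplace_marginal(recs, pop, spec, omega, ruv)
        data_terms = sum(
            (v - 4.0) ** 2 / 0.4**2 + math.log(0.4**2) for v in y
        )
        assert contrib == pytest.approx(data_terms, abs=1e-4)
        assert abs(eta_hat[0]) < 1e-5

    @pytest.mark.parametrize("omega_sd", [0.1, 0.3, 1.0])
    def test_matches_quadrature_one_eta(self, omega_sd):
        """Laplace within 0.1 of 64-node adaptive Gauss-Hermite."""
        pop = PopulationParameters(max0=4.94, pec50_0=5.65, nh_a=2.94)
        spec = RandomEffectsSpec(entries=(("pec50_0", "additive"),))
        omega = OmegaMatrix(np.array([[omega_sd**2]]))
        ruv = RuvParameters(alpha=0.3, gamma=0.0)
        rng = np.random.default_rng(3)
        concs = [0.5e-6, 1e-6, 2e-6, 5e-6, 1e-5]
        recs = []
        for c in concs:
            ind = individual_parameters(pop, np.array([0.2]), spec)
            p = predict_peak(
                ObservationRecord(oocyte_id="o", agonist_conc=c), ind
            )
            recs.append(ObservationRecord(
                oocyte_id="o", agonist_conc=c,
                peak_current=max(p + rng.normal(0, 0.3), 0.0),
            ))
        contrib, _ = laplace_marginal(recs, pop, spec, omega, ruv)
        quad = agq_marginal(
            lambda e: inner_objective(recs, pop, np.array([e]), spec,
                                      omega, ruv)
        )
        assert abs(contrib - quad) < 0.1

    @pytest.mark.parametrize("omega_sd", [0.3, 1.0])
    def test_matches_quadrature_two_eta(self, omega_sd):
        pop = PopulationParameters(max0=4.94, pec50_0=5.65, nh_a=2.94)
        spec = RandomEffectsSpec(
            entries=(("pec50_0", "additive"), ("max0", "exponential"))
        )
        omega = OmegaMatrix.from_sd_corr(
            np.array([omega_sd, omega_sd]), corr={(0, 1): 0.5}
        )
        ruv = RuvParameters(alpha=0.3, gamma=0.0)
        rng = np.random.default_rng(5)
        concs = [0.5e-6, 1e-6, 2e-6, 5e-6, 1e-5, 3e-5]
        recs = []
        for c in concs:
            p = predict_peak(
                ObservationRecord(oocyte_id="o", agonist_conc=c), pop
            )
            recs.append(ObservationRecord(
                oocyte_id="o", agonist_conc=c,
                peak_current=max(p + rng.normal(0, 0.3), 0.0),
            ))
        contrib, _ = laplace_marginal(recs, pop, spec, omega, ruv)
        quad = agq_marginal_2d(
            lambda e1, e2: inner_objective(
                recs, pop, np.array([e1, e2]), spec, omega, ruv
            )
        )
        assert abs(contrib - quad) < 0.1


class TestFitModel:
    def test_noiseless_identifiability(self):
        """Zero noise, no random effects: generating values recovered."""
        pop = PopulationParameters(max0=4.94, pec50_0=5.65, nh_a=2.94)
        respec = RandomEffectsSpec(entries=())
        omega = OmegaMatrix(np.zeros((0, 0)))
        ruv = RuvParameters(alpha=1e-3, gamma=0.0)
        recs = []
        for i in range(3):
            for c in (0.5e-6, 1e-6, 2e-6, 4e-6, 1e-5, 1e-4):
                p = predict_peak(
                    ObservationRecord(oocyte_id=f"o{i}",
                                      agonist_conc=c), pop
                )
                recs.append(ObservationRecord(
                    oocyte_id=f"o{i}", agonist_conc=c, peak_current=p
                ))
        model = ModelSpec(
            pop=PopulationParameters(max0=4.0, pec50_0=5.4, nh_a=2.0),
            free=("max0", "pec50_0", "nh_a"),
            random_effects=respec, omega=omega, ruv=ruv,
            free_corr=(), free_ruv=("alpha",),
        )
        fit = fit_model(recs, model)
        assert fit.converged
        assert fit.estimates["max0"] == pytest.approx(4.94, rel=1e-4)
        assert fit.estimates["pec50_0"] == pytest.approx(5.65, rel=1e-4)
        assert fit.estimates["nh_a"] == pytest.approx(2.94, rel=1e-4)

    def test_reduces_to_weighted_nls_without_etas(self):
        """No etas + constant variance: MLE equals plain nonlinear LS."""
        pop = PopulationParameters(max0=4.94, pec50_0=5.65, nh_a=2.94)
        rng = np.random.default_rng(11)
        recs = []
        for i in range(4):
            for c in (0.5e-6, 1e-6, 2e-6, 4e-6, 1e-5, 1e-4):
                p = predict_peak(
                    ObservationRecord(oocyte_id=f"o{i}",
                                      agonist_conc=c), pop
                )
                recs.append(ObservationRecord(
                    oocyte_id=f"o{i}", agonist_conc=c,
                    peak_current=max(p + rng.normal(0, 0.3), 0.0),
                ))
        model = ModelSpec(
            pop=PopulationParameters(max0=4.0, pec50_0=5.5, nh_a=2.5),
            free=("max0", "pec50_0", "nh_a"),
            random_effects=RandomEffectsSpec(entries=()),
            omega=OmegaMatrix(np.zeros((0, 0))),
            ruv=RuvParameters(alpha=0.3, gamma=0.0),
            free_corr=(), free_ruv=("alpha",),
        )
        fit = fit_model(recs, model)

        from scipy.optimize import least_squares

        x = np.array([r.agonist_conc for r in recs])
        y = np.array([r.peak_current for r in recs])

        def resid(theta):
            max0, pec50, lognh = theta
            nh = math.exp(lognh)
            ec50 = 10.0 ** -pec50
            return max0 * x**nh / (x**nh + ec50**nh) - y

        nls = least_squares(resid, [4.0, 5.5, math.log(2.5)],
                            method="lm")
        assert fit.estimates["max0"] == pytest.approx(nls.x[0], rel=1e-4)
        assert fit.estimates["pec50_0"] == pytest.approx(nls.x[1],
                                                         rel=1e-5)
        assert fit.estimates["nh_a"] == pytest.approx(
            math.exp(nls.x[2]), rel=1e-4
        )

    def test_invariant_to_oocyte_ordering(self, small_citral):
        data = small_citral["data"]
        model = small_citral["model"]
        fit1 = fit_model(data, model)
        rng = np.random.default_rng(0)
        shuffled = list(data)
        rng.shuffle(shuffled)
        fit2 = fit_model(shuffled, model)
        assert fit1.ofv == pytest.approx(fit2.ofv, abs=1e-6)
        for k in fit1.estimates:
            assert fit1.estimates[k] == pytest.approx(
                fit2.estimates[k], rel=1e-4, abs=1e-6
            )

    def test_concentration_rescaling_shifts_potency_only(
        self, small_citral
    ):
        """Relabelling concentrations by 10x shifts pXC50 by exactly -1."""
        data = small_citral["data"]
        model = small_citral["model"]
        fit1 = fit_model(data, model)
        scaled = [
            ObservationRecord(
                oocyte_id=r.oocyte_id, variant=r.variant,
                time_h=r.time_h, agonist_conc=r.agonist_conc * 10.0,
                drug_id=r.drug_id, drug_conc=r.drug_conc * 10.0,
                peak_current=r.peak_current,
            )
            for r in data
        ]
        pop2 = model.pop.copy()
        pop2.pec50_0 -= 1.0
        pop2.drugs["citral"].pic50 -= 1.0
        model2 = ModelSpec(
            pop=pop2, free=model.free,
            random_effects=model.random_effects, omega=model.omega,
            ruv=model.ruv, free_corr=model.free_corr,
            free_ruv=model.free_ruv,
        )
        fit2 = fit_model(scaled, model2)
        assert fit2.estimates["pec50_0"] == pytest.approx(
            fit1.estimates["pec50_0"] - 1.0, abs=2e-3
        )
        assert fit2.estimates["pic50_citral"] == pytest.approx(
            fit1.estimates["pic50_citral"] - 1.0, abs=2e-3
        )

    def test_nonfinite_start_rejected(self, small_citral):
        with pytest.raises(ValueError):
            fit_model(small_citral["data"], small_citral["model"],
                      start={"max0": float("nan")})

    def test_empty_dataset_rejected(self, small_citral):
        with pytest.raises(ValueError):
            fit_model([], small_citral["model"])


class TestStandardErrors:
    def test_matches_closed_form_gls(self):
        """Linear random-intercept toy: SE(max0) equals the GLS formula."""
        rng = np.random.default_rng(21)
        recs = []
        n_ooc, n_obs = 12, 5
        for i in range(n_ooc):
            eta = rng.normal(0, 0.8)
            for _ in range(n_obs):
                recs.append(ObservationRecord(
                    oocyte_id=f"o{i}", agonist_conc=1.0,
                    peak_current=max(4.0 + eta + rng.normal(0, 0.4),
                                     0.0),
                ))
        model = ModelSpec(
            pop=PopulationParameters(max0=4.0, pec50_0=5.65, nh_a=2.94),
            free=("max0",),
            random_effects=RandomEffectsSpec(
                entries=(("max0", "additive"),)
            ),
            omega=OmegaMatrix(np.array([[0.8**2]])),
            ruv=RuvParameters(alpha=0.4, gamma=0.0),
            free_corr=(), free_ruv=(), free_omega_sd=(),
        )
        fit = fit_model(recs, model, compute_se=True)
        # per-oocyte GLS information adds across oocytes
        se_one = gls_standard_errors(
            np.ones((n_obs, 1)), 0.4**2, 0.8**2
        )[0]
        se_exact = se_one / math.sqrt(n_ooc)
        assert fit.se is not None
        assert fit.se["max0"] == pytest.approx(se_exact, rel=0.05)

    def test_collinear_parameters_withhold_se(self, small_citral):
        """A parameter with no effect on the fit makes curvature singular."""
        model = small_citral["model"]
        # pa2/ns have zero likelihood gradient while ng is fixed at 0
        degenerate = model.with_free("pa2_citral", 3.0)
        fit = fit_model(small_citral["data"], degenerate)
        se = standard_errors(fit, small_citral["data"], degenerate)
        assert se is None

    def test_se_tracks_monte_carlo_sd(self):
        """SE(pec50_0) within 2x of the SD over replicate fits."""
        pop, respec, omega, ruv = small_citral_population()
        design = small_citral_design(n_oocytes=12)
        model = small_citral_model(pop, respec, omega, ruv)
        estimates, se0 = [], None
        fast = dict(outer_ftol=1e-9, outer_maxiter=80, n_restarts=0,
                    polish=False)
        for rep in range(20):
            data = sd.simulate_dataset(design, pop, respec, omega, ruv,
                                       seed=100 + rep)
            fit = fit_model(data, model, compute_se=(rep == 0), **fast)
            estimates.append(fit.estimates["pec50_0"])
            if rep == 0:
                assert fit.se is not None
                se0 = fit.se["pec50_0"]
        mc_sd = np.std(estimates, ddof=1)
        assert se0 == pytest.approx(mc_sd, rel=1.0)  # within a factor 2


class TestInformationCriteria:
    def test_no_parameter_case(self):
        aic, bic = information_criteria(123.4, 20, 0)
        assert aic == bic == 123.4

    def test_analytic_difference(self):
        aic, bic = information_criteria(50.0, 20, 3)
        assert bic - aic == pytest.approx(3 * (math.log(20) - 2.0))

    def test_fit_reports_consistent_criteria(self, small_citral):
        fit = fit_model(small_citral["data"], small_citral["model"])
        p, n = fit.n_params, fit.n_obs
        assert fit.ofv_full == pytest.approx(
            fit.ofv + n * math.log(2 * math.pi)
        )
        assert fit.aic == pytest.approx(fit.ofv_full + 2 * p)
        assert fit.bic == pytest.approx(fit.ofv_full + p * math.log(n))


class TestFitLogisticLS:
    def curve(self, pic50, nh, top=1000.0, bottom=50.0):
        x = np.logspace(-9, -4, 10)
        ic50 = pxc50_to_conc(pic50)
        y = bottom + (top - bottom) / (1.0 + (x / ic50) ** nh)
        return x, y

    @pytest.mark.parametrize(
        "pic50, nh, ic50_str",
        [(6.10, 2.1, "0.79 uM"), (8.42, 1.1, "3.8 nM")],
    )
    def test_noiseless_round_trip(self, pic50, nh, ic50_str):
        x, y = self.curve(pic50, nh)
        est_pic50, est_nh, top, bottom = fit_logistic_ls(x, y)
        assert est_pic50 == pytest.approx(pic50, abs=1e-6)
        assert est_nh == pytest.approx(nh, abs=1e-6)
        assert top == pytest.approx(1000.0, rel=1e-6)
        assert bottom == pytest.approx(50.0, rel=1e-6)

    def test_printed_ic50s(self):
        x, y = self.curve(6.10, 2.1)
        pic50 = fit_logistic_ls(x, y)[0]
        assert f"{pxc50_to_conc(pic50) * 1e6:.2g}" == "0.79"
        x, y = self.curve(8.42, 1.1)
        pic50 = fit_logistic_ls(x, y)[0]
        assert f"{pxc50_to_conc(pic50) * 1e9:.2g}" == "3.8"

    def test_degenerate_data_rejected(self):
        x = np.logspace(-9, -5, 6)
        with pytest.raises(ValueError):
            fit_logistic_ls(x, np.full(6, 100.0))
        with pytest.raises(ValueError):
            fit_logistic_ls(np.array([1e-6, 1e-6, 2e-6, 2e-6]),
                            np.array([1.0, 1.1, 0.4, 0.5]))


class TestRecoveryImprovesWithData:
    def test_median_error_shrinks_with_oocyte_count(self):
        """Estimation error decreases as the design doubles in size."""
        pop, respec, omega, ruv = small_citral_population()
        sizes = (10, 20, 40)
        fast = dict(outer_ftol=1e-9, outer_maxiter=80, n_restarts=0,
                    polish=False)
        med = {}
        for n in sizes:
            design = small_citral_design(n_oocytes=n)
            model = small_citral_model(pop, respec, omega, ruv)
            errs = []
            for rep in range(10):
                data = sd.simulate_dataset(
                    design, pop, respec, omega, ruv, seed=300 + rep
                )
                fit = fit_model(data, model, **fast)
                errs.append(
                    abs(fit.estimates["pec50_0"] - 5.65)
                    + abs(fit.estimates["pic50_citral"] - 3.92)
                )
            med[n] = float(np.median(errs))
        assert med[20] < med[10]
        assert med[40] < med[20]
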