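"""Mixture estimator: oracles, cross-checks, CIs, selection, joint fits."""

import numpy as np
import pytest

from pilintrack import (
    DiffusionMixture,
    confidence_intervals,
    displacement_sample,
    filter_tracks,
    fit_jd_pdf,
    fit_sqd_cdf,
    qq_diagnostic,
    select_components,
    simulate_trackset,
    simultaneous_fit,
)
from pilintrack.mixture import _mix_cdf_u, _quantile_grid, _unpack
from pilintrack.simulate import SimulationConfig, recovery_config

from conftest import DT, exact_exponential_sample, random_mixture_sample


def test_single_population_exact_quantile_recovery():
    """A sample placed at the exact model quantiles is recovered exactly."""
    for d in (0.1, 0.5):
        sample = exact_exponential_sample(d, 2000)
        for fitter in (fit_sqd_cdf, fit_jd_pdf):
            fit = fitter(sample, k=1)
            assert fit.components[0].d_app_um2_s == pytest.approx(d, rel=5e-3)
        assert fit_sqd_cdf(sample, k=1).r_squared > 0.9999


def test_k1_fit_agrees_with_moment_estimator():
    """Closed form: the k=1 SQD estimate matches mean(u)/(4 dt) within 2%."""
    sample = random_mixture_sample([1.0], [0.2], n=10_000, seed=1)
    fit = fit_sqd_cdf(sample, k=1)
    moment = sample.u_um2.mean() / (4 * DT)
    assert fit.components[0].d_app_um2_s == pytest.approx(moment, rel=0.02)


def test_two_component_fit_matches_grid_search_oracle():
    """Brute-force check: optimizer beats/equals a 50^3 grid on the same SSE.

    The sample sits at the exact quantiles of the f=0.5, D=0.05/0.5 mixture,
    so the continuum SSE optimum is the truth itself and the grid minimizer
    must land in an adjacent grid cell.
    """
    from pilintrack.mixture import _invert_mix_cdf

    q = (np.arange(1, 2001) - 0.5) / 2000
    u = _invert_mix_cdf(q, np.array([0.5, 0.5]),
                        4 * np.array([0.05, 0.5]) * DT)
    sample = __import__("pilintrack").JumpSample(lag=1, r_um=np.sqrt(u),
                                                 frame_interval_s=DT)
    fit = fit_sqd_cdf(sample, k=2)

    u_eval, p_eval = _quantile_grid(np.sort(sample.u_um2), 2000)
    fgrid = np.linspace(0.02, 0.98, 50)
    dgrid = np.geomspace(0.005, 2.0, 50)
    best = (np.inf, None)
    e = np.exp(-u_eval[:, None] / (4 * dgrid * DT))  # (m, 50)
    for fi in fgrid:
        # model CDF for all (D1, D2) pairs at fraction fi, vectorized over D2
        for i1, d1 in enumerate(dgrid):
            model = 1.0 - (fi * e[:, i1][:, None] + (1 - fi) * e)
            sse = ((model - p_eval[:, None]) ** 2).sum(axis=0)
            j = int(np.argmin(sse))
            if sse[j] < best[0]:
                best = (sse[j], (fi, d1, dgrid[j]))
    assert fit.sse <= best[0] + 1e-12
    f_star, d1_star, d2_star = best[1]
    slow, fast = fit.components
    d_lo, d_hi = min(d1_star, d2_star), max(d1_star, d2_star)
    f_lo = f_star if d1_star <= d2_star else 1 - f_star
    step = dgrid[1] / dgrid[0]  # log-grid ratio
    assert slow.d_app_um2_s == pytest.approx(d_lo, rel=step - 1)
    assert fast.d_app_um2_s == pytest.approx(d_hi, rel=step - 1)
    assert slow.fraction == pytest.approx(f_lo, abs=fgrid[1] - fgrid[0])


def test_jd_and_sqd_estimators_agree():
    sample = random_mixture_sample([0.5, 0.5], [0.05, 0.5], n=5000, seed=3)
    a = fit_sqd_cdf(sample, k=2)
    b = fit_jd_pdf(sample, k=2)
    for ca, cb in zip(a.components, b.components):
        assert ca.d_app_um2_s == pytest.approx(cb.d_app_um2_s, rel=0.15)
        assert ca.fraction == pytest.approx(cb.fraction, abs=0.05)


def test_fit_invariant_under_step_permutation():
    sample = random_mixture_sample([0.3, 0.7], [0.04, 0.5], n=3000, seed=4)
    rng = np.random.default_rng(0)
    shuffled = random_mixture_sample([0.3, 0.7], [0.04, 0.5], n=3000, seed=4)
    shuffled.r_um = rng.permutation(shuffled.r_um)
    a = fit_sqd_cdf(sample, k=2)
    b = fit_sqd_cdf(shuffled, k=2)
    assert a.d_app == pytest.approx(b.d_app)
    assert a.fractions == pytest.approx(b.fractions)


def test_fractions_normalized_and_sorted():
    sample = random_mixture_sample([0.3, 0.7], [0.04, 0.5], n=3000, seed=5)
    for k in (1, 2, 3):
        fit = fit_sqd_cdf(sample, k=k)
        assert fit.fractions.sum() == pytest.approx(1.0, abs=1e-9)
        assert np.all(np.diff(fit.d_app) >= 0)


def test_corrected_mode_subtracts_localization_term():
    sample = random_mixture_sample([0.3, 0.7], [0.042, 0.51], n=8000, seed=6)
    sigma = np.sqrt(0.042 * DT)  # slow population is pure localization error
    fit = fit_sqd_cdf(sample, k=2, sigma_mode="corrected", loc_error_um=sigma)
    slow, fast = fit.components
    assert slow.d_true_um2_s == pytest.approx(0.0, abs=0.01)
    assert fast.d_true_um2_s == pytest.approx(0.51 - 0.042, rel=0.1)


def test_k1_on_bimodal_data_fits_worse_than_k2():
    sample = random_mixture_sample([0.5, 0.5], [0.02, 0.6], n=5000, seed=7)
    f1 = fit_jd_pdf(sample, k=1)
    f2 = fit_jd_pdf(sample, k=2)
    assert f2.r_squared > f1.r_squared + 0.01
    q1 = qq_diagnostic(sample, fit_sqd_cdf(sample, k=1))
    q2 = qq_diagnostic(sample, fit_sqd_cdf(sample, k=2))
    assert q1.max_abs_deviation > 2 * q2.max_abs_deviation


def test_too_few_steps_raises():
    sample = exact_exponential_sample(0.1, 4)
    with pytest.raises(ValueError):
        fit_sqd_cdf(sample, k=3)


def test_estimator_sklearn_interface():
    """fit/score/get_params round trip on raw squared-displacement arrays."""
    sample = random_mixture_sample([1.0], [0.2], n=2000, seed=8)
    est = DiffusionMixture(k=1, frame_interval_s=DT)
    assert est.get_params()["k"] == 1
    est.set_params(n_restarts=3)
    est.fit(sample.u_um2)
    assert est.d_app_[0] == pytest.approx(0.2, rel=0.05)
    assert est.score(sample.u_um2) > 0.999
    cdf = est.predict_cdf(np.array([0.0, 1e9]))
    assert cdf == pytest.approx([0.0, 1.0], abs=1e-6)


# ----------------------------------------------------------- diagnostics


def test_qq_deviation_near_zero_on_exact_sample():
    sample = exact_exponential_sample(0.1, 2000)
    fit = fit_sqd_cdf(sample, k=1)
    report = qq_diagnostic(sample, fit)
    assert report.max_abs_deviation < 1e-3 * sample.u_um2.max()


def test_qq_matches_brute_force_quantile_comparison():
    """Direct oracle on a 10-point probability grid."""
    sample = random_mixture_sample([0.4, 0.6], [0.05, 0.4], n=4000, seed=9)
    fit = fit_sqd_cdf(sample, k=2)
    report = qq_diagnostic(sample, fit, n_quantiles=10)
    p = (np.arange(1, 11) - 0.5) / 10
    measured = np.quantile(sample.u_um2, p, method="hazen")
    w, tau = _unpack(fit.theta_, 2)
    grid = np.linspace(0, sample.u_um2.max() * 5, 2_000_001)
    cdf = _mix_cdf_u(grid, w, tau)
    modelled = np.array([grid[np.searchsorted(cdf, pi)] for pi in p])
    assert report.measured_quantiles == pytest.approx(measured)
    assert report.modelled_quantiles == pytest.approx(modelled, rel=1e-3)
    assert report.max_abs_deviation == pytest.approx(
        np.abs(measured - modelled).max(), rel=1e-2
    )


# ------------------------------------------------------- model selection


def test_selection_prefers_smaller_k_on_ties():
    sample = exact_exponential_sample(0.1, 1000)
    fits = {k: fit_jd_pdf(sample, k=k) for k in (1, 2)}
    report = select_components(fits, sample)
    assert report.chosen_k == 1


def test_selection_finds_two_populations_in_reference_mixture():
    cfg = recovery_config("-DNA", n_tracks=1200, seed=13)
    ts, _ = simulate_trackset(cfg)
    sample = displacement_sample(filter_tracks(ts))
    fits = {k: fit_jd_pdf(sample, k=k) for k in (1, 2)}
    report = select_components(fits, sample)
    assert report.chosen_k == 2
    assert report.f_pvalues[2] < 1e-6


def test_selection_rejects_inconsistent_fits():
    a = exact_exponential_sample(0.1, 1000)
    b = exact_exponential_sample(0.1, 900)
    fits = {1: fit_jd_pdf(a, k=1), 2: fit_jd_pdf(b, k=2)}
    with pytest.raises(ValueError):
        select_components(fits, a)


# -------------------------------------------------- confidence intervals


def test_interval_width_shrinks_with_sample_size():
    widths = []
    for n in (400, 8000):
        sample = random_mixture_sample([1.0], [0.2], n=n, seed=20)
        fit = confidence_intervals(fit_sqd_cdf(sample, k=1), sample,
                                   method="linearized")
        lo, hi = fit.components[0].ci95_d
        widths.append(hi - lo)
    assert widths[1] < widths[0]


def test_linearized_and_bootstrap_intervals_overlap():
    sample = random_mixture_sample([0.4, 0.6], [0.04, 0.5], n=4000, seed=14)
    fit = fit_sqd_cdf(sample, k=2)
    lin = confidence_intervals(fit, sample, method="linearized")
    boot = confidence_intervals(fit, sample, method="bootstrap", n_boot=60,
                                random_state=1)
    for cl, cb in zip(lin.components, boot.components):
        assert cl.ci95_d[0] <= cb.ci95_d[1] and cb.ci95_d[0] <= cl.ci95_d[1]


def test_bootstrap_coverage_on_single_population():
    """Percentile bootstrap covers the true D in most seeded replicates."""
    hits = 0
    n_rep = 20
    for rep in range(n_rep):
        sample = random_mixture_sample([1.0], [0.3], n=600, seed=100 + rep)
        fit = fit_sqd_cdf(sample, k=1, n_restarts=2)
        fit = confidence_intervals(fit, sample, method="bootstrap", n_boot=60,
                                   random_state=rep)
        lo, hi = fit.components[0].ci95_d
        hits += lo <= 0.3 <= hi
    assert hits >= int(0.8 * n_rep)


# ------------------------------------------------------ simultaneous fit


def test_simultaneous_fit_on_identical_samples_matches_independent():
    sample = random_mixture_sample([0.4, 0.6], [0.05, 0.5], n=4000, seed=15)
    twin = random_mixture_sample([0.4, 0.6], [0.05, 0.5], n=4000, seed=15)
    indep = fit_sqd_cdf(sample, k=2)
    joint = simultaneous_fit({"a": sample, "b": twin}, k=2)
    for lab in ("a", "b"):
        assert joint[lab].d_app == pytest.approx(indep.d_app, rel=0.02)
        assert joint[lab].fractions == pytest.approx(indep.fractions, abs=0.02)


def test_simultaneous_fit_recovers_shared_d_and_free_fractions():
    """Conditions share Ds but differ in composition (0.32 vs 0.47 slow)."""
    sams = {}
    for lab, f_slow, seed in (("-DNA", 0.32, 16), ("+DNA", 0.47, 17)):
        sams[lab] = random_mixture_sample([f_slow, 1 - f_slow], [0.042, 0.51],
                                          n=6000, seed=seed)
    joint = simultaneous_fit(sams, k=2)
    assert joint["-DNA"].d_app == pytest.approx(joint["+DNA"].d_app)
    assert joint["-DNA"].d_app == pytest.approx([0.042, 0.51], rel=0.1)
    assert joint["-DNA"].components[0].fraction == pytest.approx(0.32, abs=0.03)
    assert joint["+DNA"].components[0].fraction == pytest.approx(0.47, abs=0.03)


def test_simultaneous_fit_detects_genuinely_different_ds():
    """Shared-D constraint cannot reach the summed SSE of independent fits."""
    a = random_mixture_sample([1.0], [0.1], n=5000, seed=18)
    b = random_mixture_sample([1.0], [0.5], n=5000, seed=19)
    joint = simultaneous_fit({"a": a, "b": b}, k=1)
    indep_sse = fit_sqd_cdf(a, k=1).sse + fit_sqd_cdf(b, k=1).sse
    joint_sse = joint["a"].sse + joint["b"].sse
    assert joint_sse > 2 * indep_sse


def test_simultaneous_fit_rejects_mismatched_dt():
    a = exact_exponential_sample(0.1, 500, dt=0.03)
    b = exact_exponential_sample(0.1, 500, dt=0.05)
    with pytest.raises(ValueError, match="frame interval"):
        simultaneous_fit({"a": a, "b": b}, k=1)
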