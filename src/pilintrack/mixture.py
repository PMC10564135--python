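"""Mixture inference of diffusion coefficients and population fractions.

For a population diffusing with apparent coefficient D observed at frame
interval Δt, the squared frame-to-frame displacement u = r² is exponential
with mean 4·D·Δt, and the jump distance r is Rayleigh.  A k-population
sample therefore follows

    SQD (CDF of u):   P(u) = 1 − Σᵢ fᵢ · exp(−u / (4 Dᵢ Δt))
    JD  (PDF of r):   p(r) = Σᵢ fᵢ · r/(2 Dᵢ Δt) · exp(−r² / (4 Dᵢ Δt))

with fractions fᵢ summing to one.  The primary estimator is least squares of
the model CDF against the empirical CDF of u (the SQD analysis); the
Rayleigh-histogram fit is the cross-check.  Apparent coefficients include
the localization-error term σ²/Δt; subtraction is an explicit opt-in
(``sigma_mode='corrected'``).

:class:`DiffusionMixture` is a scikit-learn style estimator
(``fit``/``score``/``get_params``); the module-level functions
(:func:`fit_sqd_cdf`, :func:`fit_jd_pdf`, :func:`select_components`,
:func:`confidence_intervals`, :func:`simultaneous_fit`,
:func:`qq_diagnostic`) are thin wrappers over it operating on
:class:`~pilintrack.tracks.JumpSample` objects.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import optimize, stats
from sklearn.base import BaseEstimator

from .tracks import JumpSample

__all__ = [
    "DiffusionFit",
    "DiffusionMixture",
    "MixtureComponent",
    "QQReport",
    "SelectionReport",
    "confidence_intervals",
    "fit_jd_pdf",
    "fit_sqd_cdf",
    "qq_diagnostic",
    "select_components",
    "simultaneous_fit",
]


@dataclass
class MixtureComponent:
    """One diffusive population: fraction and apparent D with optional CIs."""

    fraction: float
    d_app_um2_s: float
    d_true_um2_s: float | None = None
    ci95_fraction: tuple[float, float] | None = None
    ci95_d: tuple[float, float] | None = None


@dataclass
class DiffusionFit:
    """Result of a k-component mixture fit, components sorted by ascending D."""

    components: list[MixtureComponent]
    k: int
    domain: str  # 'sqd_cdf' or 'jd_pdf'
    r_squared: float
    n_steps: int
    frame_interval_s: float
    converged: bool
    sse: float
    n_eval: int  # number of residual points the SSE was computed on
    theta_: np.ndarray = field(repr=False, default=None)

    def __post_init__(self) -> None:
        self.components.sort(key=lambda c: c.d_app_um2_s)
        total = sum(c.fraction for c in self.components)
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"fractions sum to {total}, expected 1")

    @property
    def fractions(self) -> np.ndarray:
        return np.array([c.fraction for c in self.components])

    @property
    def d_app(self) -> np.ndarray:
        return np.array([c.d_app_um2_s for c in self.components])

    def to_dict(self) -> dict:
        """Flat serializable report of the fit."""
        out = {
            "k": self.k,
            "domain": self.domain,
            "r_squared": self.r_squared,
            "n_steps": self.n_steps,
            "frame_interval_s": self.frame_interval_s,
            "converged": self.converged,
            "components": [],
        }
        for c in self.components:
            entry = {"fraction": c.fraction, "D_app_um2_s": c.d_app_um2_s}
            if c.d_true_um2_s is not None:
                entry["D_true_um2_s"] = c.d_true_um2_s
            if c.ci95_fraction is not None:
                entry["fraction_ci95"] = list(c.ci95_fraction)
            if c.ci95_d is not None:
                entry["D_ci95"] = list(c.ci95_d)
            out["components"].append(entry)
        return out


@dataclass
class QQReport:
    """Measured vs modelled quantiles at matched probabilities."""

    probabilities: np.ndarray
    measured_quantiles: np.ndarray
    modelled_quantiles: np.ndarray

    def __post_init__(self) -> None:
        if len(self.measured_quantiles) != len(self.modelled_quantiles):
            raise ValueError("quantile sequences must have equal length")
        if np.any(np.diff(self.probabilities) <= 0):
            raise ValueError("probabilities must be strictly increasing")

    @property
    def max_abs_deviation(self) -> float:
        return float(
            np.max(np.abs(self.measured_quantiles - self.modelled_quantiles))
        )


@dataclass
class SelectionReport:
    """Model-selection outcome across candidate component counts."""

    chosen_k: int
    r_squared: dict[int, float]
    qq_deviation: dict[int, float]
    f_pvalues: dict[int, float]  # p-value for the step (k-1) -> k


# ------------------------------------------------------------- model maths


def _unpack(theta: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """theta = [alpha_1..k-1, beta_1..k] -> (weights via softmax, taus)."""
    alpha = np.concatenate([theta[: k - 1], [0.0]])
    alpha = alpha - alpha.max()
    w = np.exp(alpha)
    w /= w.sum()
    tau = np.exp(theta[k - 1 :])
    return w, tau


def _pack(w: np.ndarray, tau: np.ndarray) -> np.ndarray:
    alpha = np.log(np.maximum(w, 1e-12))
    return np.concatenate([alpha[:-1] - alpha[-1], np.log(tau)])


def _mix_cdf_u(u: np.ndarray, w: np.ndarray, tau: np.ndarray) -> np.ndarray:
    """CDF of squared displacement for an exponential mixture (means tau)."""
    return 1.0 - np.exp(-u[:, None] / tau[None, :]) @ w


def _mix_pdf_r(r: np.ndarray, w: np.ndarray, tau: np.ndarray) -> np.ndarray:
    """Rayleigh-mixture density of jump distance; tau_i = 4 D_i dt."""
    z = r[:, None] ** 2 / tau[None, :]
    return (2.0 * r[:, None] / tau[None, :] * np.exp(-z)) @ w


def _quantile_grid(u: np.ndarray, max_points: int) -> tuple[np.ndarray, np.ndarray]:
    """Evaluation grid for the empirical CDF (Hazen plotting positions).

    Uses every sample point up to ``max_points``, beyond which the ECDF is
    compressed onto equally spaced Hazen probabilities — the fitted CDF is
    smooth, so the compressed SSE tracks the full one closely.
    """
    n = len(u)
    u_sorted = np.sort(u)
    if n <= max_points:
        p = (np.arange(1, n + 1) - 0.5) / n
        return u_sorted, p
    p = (np.arange(1, max_points + 1) - 0.5) / max_points
    q = np.quantile(u_sorted, p, method="hazen")
    return q, p


def _invert_mix_cdf(p: np.ndarray, w: np.ndarray, tau: np.ndarray) -> np.ndarray:
    """Numerical inverse of the exponential-mixture CDF (monotone interp)."""
    u_hi = float(np.max(tau)) * 60.0
    grid = np.concatenate([[0.0], np.geomspace(np.min(tau) * 1e-6, u_hi, 6000)])
    cdf = _mix_cdf_u(grid, w, tau)
    return np.interp(p, cdf, grid)


# --------------------------------------------------------------- estimator


class DiffusionMixture(BaseEstimator):
    """Least-squares mixture fit of diffusive populations to displacements.

    Parameters
    ----------
    k : number of populations (1-3).
    domain : 'sqd_cdf' fits the model CDF to the empirical CDF of squared
        displacements (primary); 'jd_pdf' fits the Rayleigh mixture density
        to a normalized jump-distance histogram (cross-check).
    frame_interval_s : Δt; overridden by the sample's own Δt when a
        :class:`JumpSample` is passed to :meth:`fit`.
    sigma_mode : 'apparent' (default) reports D including the σ²/Δt
        localization-error term; 'corrected' additionally reports
        D_true = D_app − σ²/Δt floored at 0 (requires ``loc_error_um``).
    n_restarts : seeded random restarts added to the quantile-spread start.
    max_eval_points : ECDF compression threshold for the SQD objective.

    Attributes (after fit)
    ----------------------
    fractions_, d_app_ : arrays sorted by ascending D.
    r_squared_, sse_, converged_, n_steps_ : goodness of fit.
    result_ : the full :class:`DiffusionFit`.
    """

    def __init__(
        self,
        k: int = 2,
        domain: str = "sqd_cdf",
        frame_interval_s: float = 0.030,
        sigma_mode: str = "apparent",
        loc_error_um: float | None = None,
        n_restarts: int = 10,
        max_eval_points: int = 2000,
        min_steps_per_component: int = 50,
        random_state: int = 0,
    ):
        self.k = k
        self.domain = domain
        self.frame_interval_s = frame_interval_s
        self.sigma_mode = sigma_mode
        self.loc_error_um = loc_error_um
        self.n_restarts = n_restarts
        self.max_eval_points = max_eval_points
        self.min_steps_per_component = min_steps_per_component
        self.random_state = random_state

    # -- data handling ----------------------------------------------------

    def _validate(self, X) -> tuple[np.ndarray, float]:
        """Return (u = squared displacements, dt)."""
        if isinstance(X, JumpSample):
            return np.asarray(X.u_um2, dtype=float), X.dt_s
        arr = np.asarray(X, dtype=float)
        if arr.ndim == 2 and arr.shape[1] == 1:
            arr = arr[:, 0]
        if arr.ndim != 1:
            raise ValueError("expected a 1-D array of squared displacements")
        if not np.isfinite(arr).all() or (arr < 0).any():
            raise ValueError("squared displacements must be finite and >= 0")
        return arr, self.frame_interval_s

    # -- objectives -------------------------------------------------------

    def _build_objective(self, u: np.ndarray):
        k = self.k
        if self.domain == "sqd_cdf":
            x_eval, y_eval = _quantile_grid(u, self.max_eval_points)

            def predict(theta):
                w, tau = _unpack(theta, k)
                return _mix_cdf_u(x_eval, w, tau)

        elif self.domain == "jd_pdf":
            r = np.sqrt(u)
            counts, edges = np.histogram(r, bins="fd", density=False)
            if np.mean(counts == 0) >= 0.5:
                raise ValueError(
                    "more than half of the jump-distance histogram bins are "
                    "empty; choose a different binning"
                )
            widths = np.diff(edges)
            density = counts / (counts.sum() * widths)
            x_eval = 0.5 * (edges[:-1] + edges[1:])
            y_eval = density

            def predict(theta):
                w, tau = _unpack(theta, k)
                return _mix_pdf_r(x_eval, w, tau)

        else:
            raise ValueError(f"unknown domain {self.domain!r}")

        def sse(theta):
            resid = predict(theta) - y_eval
            return float(resid @ resid)

        return x_eval, y_eval, predict, sse

    def _starting_points(self, u: np.ndarray, dt: float) -> list[np.ndarray]:
        """Quantile-spread start plus seeded log-perturbed restarts."""
        k = self.k
        rng = np.random.default_rng(self.random_state)
        mean_tau = max(float(np.mean(u)), 1e-12)
        if k == 1:
            base_tau = np.array([mean_tau])
        else:
            # spread exponential-mean guesses across the sample's quantiles
            qs = (np.arange(1, k + 1) - 0.5) / k
            uq = np.maximum(np.quantile(u, qs), 1e-12)
            base_tau = uq / -np.log1p(-qs)
            base_tau = np.sort(base_tau)
        w0 = np.full(k, 1.0 / k)
        starts = [_pack(w0, base_tau)]
        for _ in range(self.n_restarts):
            tau = np.sort(base_tau * np.exp(rng.normal(0.0, 1.0, k)))
            w = rng.dirichlet(np.ones(k))
            starts.append(_pack(w, tau))
        return starts

    # -- fitting ----------------------------------------------------------

    def fit(self, X, y=None) -> "DiffusionMixture":
        u, dt = self._validate(X)
        k = self.k
        if k not in (1, 2, 3):
            raise ValueError("k must be 1, 2 or 3")
        n = len(u)
        if 2 * k - 1 >= n:
            raise ValueError(f"{2 * k - 1} parameters but only {n} steps")
        if n < self.min_steps_per_component * k:
            warnings.warn(
                f"only {n} steps for k={k}; the guideline is >= "
                f"{self.min_steps_per_component} per component",
                stacklevel=2,
            )
        if self.sigma_mode == "corrected" and self.loc_error_um is None:
            raise ValueError("sigma_mode='corrected' requires loc_error_um")
        if self.sigma_mode not in ("apparent", "corrected"):
            raise ValueError(f"unknown sigma_mode {self.sigma_mode!r}")

        x_eval, y_eval, predict, sse = self._build_objective(u)

        best = None
        any_converged = False
        for theta0 in self._starting_points(u, dt):
            res = optimize.minimize(sse, theta0, method="Nelder-Mead",
                                    options={"xatol": 1e-8, "fatol": 1e-12,
                                             "maxiter": 4000})
            any_converged = any_converged or bool(res.success)
            cand = (res.fun, float(_unpack(res.x, k)[1].min()), res)
            if best is None or cand[0] < best[0] - 1e-14 or (
                abs(cand[0] - best[0]) <= 1e-14 and cand[1] < best[1]
            ):
                best = cand
        res = best[2]
        if not any_converged:
            warnings.warn("mixture fit did not converge from any start",
                          stacklevel=2)
        w, tau = _unpack(res.x, k)
        order = np.argsort(tau)
        w, tau = w[order], tau[order]
        d_app = tau / (4.0 * dt)

        ss_tot = float(np.sum((y_eval - y_eval.mean()) ** 2))
        r2 = 1.0 - best[0] / ss_tot if ss_tot > 0 else 1.0

        comps = []
        for fi, di in zip(w, d_app):
            d_true = None
            if self.sigma_mode == "corrected":
                d_true = max(di - self.loc_error_um**2 / dt, 0.0)
            comps.append(
                MixtureComponent(fraction=float(fi), d_app_um2_s=float(di),
                                 d_true_um2_s=d_true)
            )
        self.result_ = DiffusionFit(
            components=comps,
            k=k,
            domain=self.domain,
            r_squared=float(r2),
            n_steps=n,
            frame_interval_s=dt,
            converged=any_converged,
            sse=float(best[0]),
            n_eval=len(x_eval),
            theta_=_pack(w, tau),
        )
        self.fractions_ = self.result_.fractions
        self.d_app_ = self.result_.d_app
        self.r_squared_ = self.result_.r_squared
        self.sse_ = self.result_.sse
        self.converged_ = self.result_.converged
        self.n_steps_ = n
        self._u = u
        self._dt = dt
        return self

    def score(self, X, y=None) -> float:
        """R² of the fitted model on (the ECDF/histogram of) X."""
        u, _ = self._validate(X)
        saved_u = self._u
        try:
            self._u = u
            x_eval, y_eval, predict, sse = self._build_objective(u)
            ss_tot = float(np.sum((y_eval - y_eval.mean()) ** 2))
            return 1.0 - sse(self.result_.theta_) / ss_tot if ss_tot > 0 else 1.0
        finally:
            self._u = saved_u

    def predict_cdf(self, u: np.ndarray) -> np.ndarray:
        w, tau = _unpack(self.result_.theta_, self.k)
        return _mix_cdf_u(np.asarray(u, dtype=float), w, tau)


# ------------------------------------------------------- functional facade


def _estimator_for(sample: JumpSample, k: int, domain: str, **kw) -> DiffusionMixture:
    est = DiffusionMixture(k=k, domain=domain,
                           frame_interval_s=sample.frame_interval_s, **kw)
    est.fit(sample)
    return est


def fit_sqd_cdf(
    sample: JumpSample,
    k: int = 2,
    sigma_mode: str = "apparent",
    loc_error_um: float | None = None,
    **kw,
) -> DiffusionFit:
    """SQD analysis: least-squares fit of the mixture CDF of u = r²."""
    est = _estimator_for(sample, k, "sqd_cdf", sigma_mode=sigma_mode,
                         loc_error_um=loc_error_um, **kw)
    return est.result_


def fit_jd_pdf(
    sample: JumpSample,
    k: int = 2,
    sigma_mode: str = "apparent",
    loc_error_um: float | None = None,
    **kw,
) -> DiffusionFit:
    """Jump-distance analysis: Rayleigh-mixture fit to the r histogram."""
    est = _estimator_for(sample, k, "jd_pdf", sigma_mode=sigma_mode,
                         loc_error_um=loc_error_um, **kw)
    return est.result_


def qq_diagnostic(
    sample: JumpSample, fit: DiffusionFit, n_quantiles: int = 100
) -> QQReport:
    """Measured vs model quantiles of u at matched Hazen probabilities."""
    p = (np.arange(1, n_quantiles + 1) - 0.5) / n_quantiles
    measured = np.quantile(sample.u_um2, p, method="hazen")
    w, tau = _unpack(fit.theta_, fit.k)
    modelled = _invert_mix_cdf(p, w, tau)
    return QQReport(probabilities=p, measured_quantiles=measured,
                    modelled_quantiles=modelled)


def select_components(
    fits: dict[int, DiffusionFit],
    sample: JumpSample,
    alpha: float = 0.01,
    qq_improvement_factor: float = 1.0,
    n_quantiles: int = 100,
) -> SelectionReport:
    """Choose the number of populations by nested F-test plus QQ improvement.

    Starting from k=1, each increment to k is accepted only if the extra
    parameters reduce the residual SSE significantly (F-test on nested
    least squares at ``alpha``) *and* the QQ max deviation improves by at
    least ``qq_improvement_factor`` (ratio old/new).  Identical fits tie
    toward the smaller k.
    """
    ks = sorted(fits)
    if ks[0] != 1 or ks != list(range(1, ks[-1] + 1)):
        raise ValueError("fits must cover consecutive k starting at 1")
    base = fits[ks[0]]
    for f in fits.values():
        if f.domain != base.domain or f.n_steps != base.n_steps:
            raise ValueError("fits must share the same sample and domain")

    qq_dev = {k: qq_diagnostic(sample, fits[k], n_quantiles).max_abs_deviation
              for k in ks}
    r2 = {k: fits[k].r_squared for k in ks}
    pvals: dict[int, float] = {}
    chosen = 1
    for k in ks[1:]:
        prev, cur = fits[k - 1], fits[k]
        d_params = 2  # one extra fraction + one extra D per added component
        df2 = cur.n_eval - (2 * k - 1)
        if cur.sse <= 0 or df2 <= 0:
            pvals[k] = 0.0 if prev.sse > cur.sse else 1.0
        else:
            f_stat = ((prev.sse - cur.sse) / d_params) / (cur.sse / df2)
            pvals[k] = float(stats.f.sf(max(f_stat, 0.0), d_params, df2))
        qq_ratio = (qq_dev[k - 1] / qq_dev[k]) if qq_dev[k] > 0 else np.inf
        if chosen == k - 1 and pvals[k] < alpha and qq_ratio >= qq_improvement_factor:
            chosen = k
    return SelectionReport(chosen_k=chosen, r_squared=r2, qq_deviation=qq_dev,
                           f_pvalues=pvals)


def confidence_intervals(
    fit: DiffusionFit,
    sample: JumpSample,
    method: str = "linearized",
    n_boot: int = 200,
    random_state: int = 0,
) -> DiffusionFit:
    """Attach 95% CIs per component (linearized covariance or bootstrap).

    ``linearized`` propagates the residual variance through the numerical
    Jacobian at the optimum (delta method to fractions and Ds); a singular
    Jacobian falls back to the bootstrap with a warning.  ``bootstrap``
    refits ``n_boot`` resamples of the steps, starting each refit at the
    optimum, and reports percentile intervals.
    """
    if not fit.converged:
        raise ValueError("confidence intervals require a converged fit")
    if method == "linearized":
        try:
            return _ci_linearized(fit, sample)
        except np.linalg.LinAlgError:
            warnings.warn("singular Jacobian; falling back to bootstrap",
                          stacklevel=2)
            method = "bootstrap"
    if method != "bootstrap":
        raise ValueError(f"unknown CI method {method!r}")
    return _ci_bootstrap(fit, sample, n_boot, random_state)


def _params_of_interest(theta: np.ndarray, k: int, dt: float) -> np.ndarray:
    w, tau = _unpack(theta, k)
    order = np.argsort(tau)
    return np.concatenate([w[order], tau[order] / (4.0 * dt)])


def _ci_linearized(fit: DiffusionFit, sample: JumpSample) -> DiffusionFit:
    k, dt = fit.k, fit.frame_interval_s
    est = DiffusionMixture(k=k, domain=fit.domain, frame_interval_s=dt)
    u = np.asarray(sample.u_um2, dtype=float)
    x_eval, y_eval, predict, _ = est._build_objective(u)
    theta = fit.theta_
    m, p = len(x_eval), len(theta)
    eps = 1e-6
    jac = np.empty((m, p))
    for j in range(p):
        step = np.zeros(p)
        step[j] = eps
        jac[:, j] = (predict(theta + step) - predict(theta - step)) / (2 * eps)
    jtj = jac.T @ jac
    if np.linalg.cond(jtj) > 1e12:
        raise np.linalg.LinAlgError("ill-conditioned Jacobian")
    resid = predict(theta) - y_eval
    s2 = float(resid @ resid) / max(m - p, 1)
    cov_theta = s2 * np.linalg.inv(jtj)
    # delta method: gradient of (fractions, Ds) wrt theta
    grad = np.empty((2 * k, p))
    for j in range(p):
        step = np.zeros(p)
        step[j] = eps
        grad[:, j] = (
            _params_of_interest(theta + step, k, dt)
            - _params_of_interest(theta - step, k, dt)
        ) / (2 * eps)
    var = np.einsum("ip,pq,iq->i", grad, cov_theta, grad)
    sd = np.sqrt(np.maximum(var, 0.0))
    centre = _params_of_interest(theta, k, dt)
    lo = centre - 1.96 * sd
    hi = centre + 1.96 * sd
    comps = []
    for i, c in enumerate(fit.components):
        comps.append(replace(
            c,
            ci95_fraction=(float(np.clip(lo[i], 0, 1)), float(np.clip(hi[i], 0, 1))),
            ci95_d=(float(max(lo[k + i], 0.0)), float(hi[k + i])),
        ))
    return replace(fit, components=comps)


def _ci_bootstrap(
    fit: DiffusionFit, sample: JumpSample, n_boot: int, random_state: int
) -> DiffusionFit:
    k, dt = fit.k, fit.frame_interval_s
    rng = np.random.default_rng(random_state)
    u = np.asarray(sample.u_um2, dtype=float)
    n = len(u)
    draws = np.empty((n_boot, 2 * k))
    est = DiffusionMixture(k=k, domain=fit.domain, frame_interval_s=dt,
                           n_restarts=0, min_steps_per_component=0)
    for b in range(n_boot):
        ub = u[rng.integers(0, n, n)]
        x_eval, y_eval, predict, sse = est._build_objective(ub)
        res = optimize.minimize(sse, fit.theta_, method="Nelder-Mead",
                                options={"xatol": 1e-7, "fatol": 1e-11,
                                         "maxiter": 2000})
        draws[b] = _params_of_interest(res.x, k, dt)
    lo = np.percentile(draws, 2.5, axis=0)
    hi = np.percentile(draws, 97.5, axis=0)
    comps = []
    for i, c in enumerate(fit.components):
        comps.append(replace(
            c,
            ci95_fraction=(float(lo[i]), float(hi[i])),
            ci95_d=(float(lo[k + i]), float(hi[k + i])),
        ))
    return replace(fit, components=comps)


def simultaneous_fit(
    samples: dict[str, JumpSample],
    k: int = 2,
    n_restarts: int = 10,
    max_eval_points: int = 2000,
    random_state: int = 0,
) -> dict[str, DiffusionFit]:
    """Joint multi-condition fit sharing component Ds, fractions free.

    Minimizes the summed SQD-CDF SSE across conditions with the diffusion
    coefficients constrained equal everywhere; each condition keeps its own
    fractions.  Returns one :class:`DiffusionFit` per condition (identical
    Ds across them).
    """
    if len(samples) < 2:
        raise ValueError("simultaneous fit needs >= 2 conditions")
    labels = list(samples)
    dts = {s.dt_s for s in samples.values()}
    if len(dts) != 1:
        raise ValueError(f"mismatched frame intervals: {sorted(dts)}")
    dt = dts.pop()

    grids = {}
    for lab in labels:
        u = np.asarray(samples[lab].u_um2, dtype=float)
        grids[lab] = _quantile_grid(u, max_eval_points)

    n_cond = len(labels)
    n_w = k - 1  # free weight logits per condition

    def split(theta):
        taus = np.exp(theta[:k])
        alphas = theta[k:].reshape(n_cond, n_w) if n_w else np.zeros((n_cond, 0))
        return taus, alphas

    def cond_weights(alpha_row):
        a = np.concatenate([alpha_row, [0.0]])
        a = a - a.max()
        w = np.exp(a)
        return w / w.sum()

    def total_sse(theta):
        taus, alphas = split(theta)
        total = 0.0
        for i, lab in enumerate(labels):
            x_eval, y_eval = grids[lab]
            w = cond_weights(alphas[i])
            resid = _mix_cdf_u(x_eval, w, taus) - y_eval
            total += float(resid @ resid)
        return total

    # starting points from per-condition independent fits plus restarts
    rng = np.random.default_rng(random_state)
    pooled_u = np.concatenate([np.asarray(s.u_um2, float) for s in samples.values()])
    helper = DiffusionMixture(k=k, frame_interval_s=dt, n_restarts=2,
                              random_state=random_state,
                              min_steps_per_component=0)
    helper.fit(pooled_u)
    w0, tau0 = _unpack(helper.result_.theta_, k)
    starts = []
    alpha0 = np.log(np.maximum(w0, 1e-12))
    alpha0 = alpha0[:-1] - alpha0[-1]
    starts.append(np.concatenate([np.log(tau0), np.tile(alpha0, n_cond)]))
    for _ in range(n_restarts):
        tau = np.sort(tau0 * np.exp(rng.normal(0.0, 0.7, k)))
        alphas = rng.normal(0.0, 1.0, n_cond * n_w)
        starts.append(np.concatenate([np.log(tau), alphas]))

    best = None
    any_converged = False
    for theta0 in starts:
        res = optimize.minimize(total_sse, theta0, method="Nelder-Mead",
                                options={"xatol": 1e-8, "fatol": 1e-12,
                                         "maxiter": 6000})
        any_converged = any_converged or bool(res.success)
        if best is None or res.fun < best.fun:
            best = res
    taus, alphas = split(best.x)
    order = np.argsort(taus)
    taus = taus[order]
    d_shared = taus / (4.0 * dt)

    out = {}
    for i, lab in enumerate(labels):
        w = cond_weights(alphas[i])[order]
        x_eval, y_eval = grids[lab]
        resid = _mix_cdf_u(x_eval, w, taus) - y_eval
        sse = float(resid @ resid)
        ss_tot = float(np.sum((y_eval - y_eval.mean()) ** 2))
        comps = [MixtureComponent(fraction=float(fi), d_app_um2_s=float(di))
                 for fi, di in zip(w, d_shared)]
        out[lab] = DiffusionFit(
            components=comps, k=k, domain="sqd_cdf",
            r_squared=1.0 - sse / ss_tot if ss_tot > 0 else 1.0,
            n_steps=samples[lab].n_steps, frame_interval_s=dt,
            converged=any_converged, sse=sse, n_eval=len(x_eval),
            theta_=_pack(w, taus),
        )
    return out
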