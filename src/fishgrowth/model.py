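"""Mixed-effects growth model: Laplace-approximated marginal likelihood.

The model: for individual *i* in group *j*, each growth-curve parameter
has a linear predictor of fixed effects plus a standardized individual
random effect scaled by an estimated sd,

    log(asymptote_i) = x_i' beta_a + sigma_a * v_i,    v_i ~ N(0, 1)
    log(rate_i)      = x_i' beta_r + sigma_r * u_i,    u_i ~ N(0, 1)
    location_i       = x_i' beta_l + sigma_l * z_i,    z_i ~ N(0, 1)

and an observed length is the curve value at the capture age plus
time-invariant Gaussian measurement error with sd sigma_eps (mm). The
random effects are integrated out of the likelihood with a Laplace
approximation: per fish, an inner Newton solver finds the joint-likelihood
mode of that fish's effects (the empirical-Bayes modes, using analytic
gradients and exact analytic curve Hessians), and the marginal negative
log-likelihood is the joint value at the mode plus half the log-determinant
of the inner Hessian minus q/2 log(2 pi). An adaptive Gauss-Hermite
quadrature of the same per-fish integrand is available as an independent
check of the approximation.

The outer problem maximizes the Laplace marginal likelihood over the
packed vector (fixed effects, log sds) with a quasi-Newton method;
standard errors come from the inverse of a finite-difference Hessian of
the objective at the optimum (delta method for derived natural-scale
quantities). Non-convergence is reported as data on the result object,
never raised: sparse mark-recapture data routinely defeat the richer
predictor sets, and a model that does not converge is simply dropped
from downstream ranking.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize

from .design import (
    PARAM_NAMES,
    DesignMatrices,
    GrowthDataset,
    ModelSpec,
    ParameterLayout,
    ParameterSet,
    build_design_matrices,
    design_rows_for_labels,
    linear_predictors,
)
from .quadrature import adaptive_gh_marginal_nll

__all__ = ["GrowthModel", "GrowthResults", "FitOptions"]

_LOG2PI = np.log(2.0 * np.pi)
_EXP_CLIP = 500.0  # caps exponent magnitude inside curve evaluation


def _curve_eval(function: str, eta_a, eta_r, loc, t, order: int = 0):
    """Curve value and derivatives w.r.t. the link-scale parameters.

    eta_a = log(asymptote), eta_r = log(rate), loc = location, all per
    observation. Returns (L, d1, d2) where d1 is (n, 3) and d2 is
    (n, 3, 3), both in (eta_a, eta_r, loc) order; d1/d2 are None when not
    requested. Exponents are clipped at +/-500 so extreme trial parameter
    values produce huge-but-finite lengths instead of overflow.
    """
    with np.errstate(over="ignore", invalid="ignore"):
        asym = np.exp(np.clip(eta_a, -_EXP_CLIP, _EXP_CLIP))
        k = np.exp(np.clip(eta_r, -_EXP_CLIP, _EXP_CLIP))
        s = t - loc
        if function == "vbgf":
            E = np.exp(np.clip(-k * s, -_EXP_CLIP, _EXP_CLIP))
            L = asym * (1.0 - E)
            if order == 0:
                return L, None, None
            ks = k * s
            d1 = np.stack([L, asym * ks * E, -asym * k * E], axis=-1)
            if order == 1:
                return L, d1, None
            d2 = np.empty(L.shape + (3, 3))
            d2[..., 0, 0] = L
            d2[..., 0, 1] = d2[..., 1, 0] = asym * ks * E
            d2[..., 0, 2] = d2[..., 2, 0] = -asym * k * E
            d2[..., 1, 1] = asym * ks * E * (1.0 - ks)
            d2[..., 1, 2] = d2[..., 2, 1] = asym * k * E * (ks - 1.0)
            d2[..., 2, 2] = -asym * k * k * E
            return L, d1, d2
        elif function == "gompertz":
            g = k * s
            w = np.exp(np.clip(-g, -_EXP_CLIP, _EXP_CLIP))
            L = asym * np.exp(np.clip(-w, -_EXP_CLIP, _EXP_CLIP))
            if order == 0:
                return L, None, None
            d1 = np.stack([L, L * w * g, -L * w * k], axis=-1)
            if order == 1:
                return L, d1, None
            c = w * g - g + 1.0
            d2 = np.empty(L.shape + (3, 3))
            d2[..., 0, 0] = L
            d2[..., 0, 1] = d2[..., 1, 0] = L * w * g
            d2[..., 0, 2] = d2[..., 2, 0] = -L * w * k
            d2[..., 1, 1] = L * w * g * c
            d2[..., 1, 2] = d2[..., 2, 1] = -L * w * k * c
            d2[..., 2, 2] = L * w * k * k * (w - 1.0)
            return L, d1, d2
        else:  # pragma: no cover - guarded by ModelSpec
            raise ValueError(f"unknown growth function {function!r}")


@dataclass
class FitOptions:
    """Tunable knobs of the nested optimization.

    inner_tol : inf-norm gradient tolerance of the per-fish Newton solver
    inner_maxiter : Newton iteration cap per fish
    outer_maxiter : quasi-Newton iteration cap
    grad_tol : relative gradient norm below which the outer problem
        counts as converged
    compute_se : whether to build the finite-difference Hessian and
        standard errors at the optimum
    """

    inner_tol: float = 1e-8
    inner_maxiter: int = 50
    outer_maxiter: int = 600
    grad_tol: float = 1e-4
    compute_se: bool = True


class GrowthModel:
    """Mixed-effects von Bertalanffy / Gompertz size-at-age model.

    Parameters
    ----------
    data : GrowthDataset of capture records.
    spec : ModelSpec naming the growth function, the fixed-effect
        predictors of each curve parameter and the active random effects.
    """

    def __init__(self, data: GrowthDataset, spec: ModelSpec):
        self.data = data
        self.spec = spec
        self.design: DesignMatrices = build_design_matrices(data, spec)
        for p in PARAM_NAMES:
            X = self.design.X[p]
            if np.linalg.matrix_rank(X) < X.shape[1]:
                raise ValueError(
                    f"design matrix for {p!r} is rank deficient "
                    f"(columns: {self.design.names[p]})"
                )
        self.layout = ParameterLayout(self.design, spec.random_effects)
        fr = data.frame
        self._t = fr["age"].to_numpy(dtype=float)
        self._y = fr["length"].to_numpy(dtype=float)
        self._fidx = data.fish_index()
        self._nobs_fish = np.bincount(self._fidx, minlength=data.n_fish)
        self.active = [j for j, on in enumerate(spec.random_effects) if on]
        self.q = len(self.active)
        self._warm_modes: np.ndarray | None = None

    # ------------------------------------------------------------------
    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        function: str = "vbgf",
        asymptote="constant",
        rate="constant",
        location="constant",
        random_effects=(True, True, True),
        covariates=(),
    ) -> "GrowthModel":
        spec = ModelSpec(
            function=function,
            asymptote=asymptote,
            rate=rate,
            location=location,
            random_effects=random_effects,
            covariates=covariates,
        )
        return cls(GrowthDataset(frame), spec)

    # -- likelihood pieces ---------------------------------------------
    def _obs_eta(self, theta: ParameterSet, effects: np.ndarray):
        """Per-observation link-scale parameters (eta_a, eta_r, loc)."""
        effects = np.asarray(effects, dtype=float)
        out = []
        for j, p in enumerate(PARAM_NAMES):
            eta = self.design.X[p] @ theta.beta[p] + theta.sigma(p) * effects[:, j]
            out.append(eta[self._fidx])
        return out

    def _data_nll_per_fish(self, theta: ParameterSet, effects: np.ndarray) -> np.ndarray:
        eta_a, eta_r, loc = self._obs_eta(theta, effects)
        L, _, _ = _curve_eval(self.spec.function, eta_a, eta_r, loc, self._t)
        sig2 = theta.sigma_eps**2
        with np.errstate(over="ignore", invalid="ignore"):
            r = self._y - L
            contrib = 0.5 * (_LOG2PI + np.log(sig2)) + r * r / (2.0 * sig2)
        contrib = np.where(np.isfinite(contrib), contrib, 1e12)
        return np.bincount(self._fidx, weights=contrib, minlength=self.data.n_fish)

    def _prior_nll_per_fish(self, effects: np.ndarray) -> np.ndarray:
        e = np.asarray(effects, dtype=float)[:, self.active]
        return 0.5 * (self.q * _LOG2PI + np.sum(e * e, axis=1))

    def joint_nll(self, theta: ParameterSet, effects: np.ndarray) -> float:
        """Joint negative log-likelihood of data and standardized effects."""
        per_fish = self._data_nll_per_fish(theta, effects) + self._prior_nll_per_fish(effects)
        return float(np.sum(per_fish))

    def _per_fish_joint(self, theta, effects) -> np.ndarray:
        return self._data_nll_per_fish(theta, effects) + self._prior_nll_per_fish(effects)

    def _inner_grad_hess(self, theta: ParameterSet, effects: np.ndarray):
        """Gradient and Hessian of each fish's joint nll w.r.t. its active effects."""
        eta_a, eta_r, loc = self._obs_eta(theta, effects)
        L, d1, d2 = _curve_eval(self.spec.function, eta_a, eta_r, loc, self._t, order=2)
        sig2 = theta.sigma_eps**2
        with np.errstate(over="ignore", invalid="ignore"):
            r = self._y - L
        sig = np.array([theta.sigma(p) for p in PARAM_NAMES])
        n_fish, q = self.data.n_fish, self.q
        g = np.zeros((n_fish, q))
        H = np.zeros((n_fish, q, q))
        for a, ja in enumerate(self.active):
            ga = -r * d1[:, ja] / sig2
            g[:, a] = sig[ja] * np.bincount(self._fidx, weights=ga, minlength=n_fish)
            g[:, a] += effects[:, ja]
            for b, jb in enumerate(self.active):
                if b < a:
                    continue
                hab = (d1[:, ja] * d1[:, jb] - r * d2[:, ja, jb]) / sig2
                Hab = sig[ja] * sig[jb] * np.bincount(
                    self._fidx, weights=hab, minlength=n_fish
                )
                H[:, a, b] = Hab
                H[:, b, a] = Hab
        H[:, range(q), range(q)] += 1.0  # prior curvature
        bad = ~np.isfinite(g).all(axis=1) | ~np.isfinite(H.reshape(n_fish, -1)).all(axis=1)
        if bad.any():
            g[bad] = 0.0
            H[bad] = np.eye(q)
        return g, H, bad

    def inner_modes(self, theta: ParameterSet, start: np.ndarray | None = None,
                    tol: float = 1e-8, maxiter: int = 50):
        """Per-fish Newton minimization of the joint nll over the effects.

        Fish blocks are independent (effects are individual-specific), so
        all fish are iterated simultaneously. Returns (effects, hessians,
        per_fish_joint_nll, converged_mask); hessians are the exact inner
        Hessians at the returned points, (n_fish, q, q).
        """
        n_fish, q = self.data.n_fish, self.q
        E = np.zeros((n_fish, 3))
        if start is not None:
            E[:, :] = start
            E[:, [j for j in range(3) if j not in self.active]] = 0.0
        if q == 0:
            f = self._per_fish_joint(theta, E)
            return E, np.zeros((n_fish, 0, 0)), f, np.ones(n_fish, bool)

        f = self._per_fish_joint(theta, E)
        converged = np.zeros(n_fish, bool)
        for _ in range(maxiter):
            g, H, bad = self._inner_grad_hess(theta, E)
            converged = np.max(np.abs(g), axis=1) < tol
            if converged.all():
                break
            # Levenberg damping where the Hessian is not safely PD
            eigmin = np.linalg.eigvalsh(H)[:, 0]
            ridge = np.maximum(0.0, 1e-6 - eigmin)
            Hd = H.copy()
            Hd[:, range(q), range(q)] += ridge[:, None]
            try:
                step = -np.linalg.solve(Hd, g[..., None])[..., 0]
            except np.linalg.LinAlgError:  # pragma: no cover - ridge prevents this
                step = -g
            # effects are standardized; cap the step so near-singular
            # Hessians cannot launch the iterate into absurd territory
            norms = np.linalg.norm(step, axis=1)
            with np.errstate(invalid="ignore", divide="ignore"):
                scale = np.where(norms > 4.0, 4.0 / norms, 1.0)
            step *= np.where(np.isfinite(scale), scale, 0.0)[:, None]
            step[converged] = 0.0
            # vectorized backtracking on the per-fish objective
            alpha = np.ones(n_fish)
            for _bt in range(30):
                Enew = E.copy()
                Enew[:, self.active] = E[:, self.active] + alpha[:, None] * step
                fnew = self._per_fish_joint(theta, Enew)
                worse = (fnew > f + 1e-12) & ~converged
                if not worse.any():
                    break
                alpha[worse] *= 0.5
            accept = (fnew <= f + 1e-12) & ~converged
            E[accept] = Enew[accept]
            f = np.where(accept, fnew, f)
        g, H, bad = self._inner_grad_hess(theta, E)
        converged = (np.max(np.abs(g), axis=1) < tol) & ~bad
        f = self._per_fish_joint(theta, E)
        return E, H, f, converged

    def laplace_nll(self, theta, start: np.ndarray | None = None) -> float:
        """Laplace-approximated marginal negative log-likelihood.

        ``theta`` may be a ParameterSet or a packed vector. Raises if any
        fish's inner problem fails or has a non-positive-definite Hessian
        (the optimizer-facing path handles these with penalties instead).
        """
        if not isinstance(theta, ParameterSet):
            theta = self.layout.unpack(theta)
        E, H, f, ok = self.inner_modes(theta, start=start)
        if not ok.all():
            bad = self.data.fish_ids[int(np.flatnonzero(~ok)[0])]
            raise RuntimeError(f"inner mode search failed for fish {bad!r}")
        return self._laplace_from_parts(H, f)

    def _laplace_from_parts(self, H: np.ndarray, f: np.ndarray) -> float:
        if self.q == 0:
            return float(np.sum(f))
        sign, logdet = np.linalg.slogdet(H)
        if np.any(sign <= 0):
            bad = self.data.fish_ids[int(np.flatnonzero(sign <= 0)[0])]
            raise RuntimeError(f"non-positive-definite inner Hessian for fish {bad!r}")
        return float(np.sum(f) + 0.5 * np.sum(logdet) - 0.5 * self.q * self.data.n_fish * _LOG2PI)

    # -- quadrature oracle ---------------------------------------------
    def _fish_joint_fn(self, i: int, theta: ParameterSet):
        """Vectorized joint nll of fish i as a function of its active effects."""
        sel = self._fidx == i
        t = self._t[sel]
        y = self._y[sel]
        base = []
        for p in PARAM_NAMES:
            base.append(float(self.design.X[p][i] @ theta.beta[p]))
        sig = [theta.sigma(p) for p in PARAM_NAMES]
        sig2 = theta.sigma_eps**2
        function = self.spec.function
        active = self.active
        q = self.q

        def f(E):
            E = np.atleast_2d(np.asarray(E, dtype=float))  # (m, q)
            full = np.zeros((E.shape[0], 3))
            full[:, active] = E
            eta_a = base[0] + sig[0] * full[:, 0]
            eta_r = base[1] + sig[1] * full[:, 1]
            loc = base[2] + sig[2] * full[:, 2]
            L, _, _ = _curve_eval(
                function, eta_a[:, None], eta_r[:, None], loc[:, None], t[None, :]
            )
            r = y[None, :] - L
            data_nll = np.sum(0.5 * (_LOG2PI + np.log(sig2)) + r * r / (2.0 * sig2), axis=1)
            prior = 0.5 * (q * _LOG2PI + np.sum(E * E, axis=1))
            return data_nll + prior

        return f

    def gh_quadrature_nll(self, theta, nodes_per_dim: int = 31) -> float:
        """Marginal nll by adaptive Gauss-Hermite quadrature (oracle).

        Centres a tensor Gauss-Hermite grid on each fish's joint mode,
        scaled by the inner Hessian; feasible for q <= 3 effects per fish.
        """
        if not isinstance(theta, ParameterSet):
            theta = self.layout.unpack(theta)
        if self.q > 3:  # pragma: no cover - q is structurally <= 3
            raise ValueError("quadrature supports at most 3 active effects per fish")
        E, H, f, ok = self.inner_modes(theta)
        if not ok.all():
            bad = self.data.fish_ids[int(np.flatnonzero(~ok)[0])]
            raise RuntimeError(f"inner mode search failed for fish {bad!r}")
        total = 0.0
        for i in range(self.data.n_fish):
            fn = self._fish_joint_fn(i, theta)
            total += adaptive_gh_marginal_nll(
                fn, E[i, self.active], H[i], nodes_per_dim
            )
        return float(total)

    # -- outer optimization ---------------------------------------------
    def start_values(self) -> ParameterSet:
        """Deterministic starting rule.

        Asymptote intercept at log(1.1 x max observed length), rate
        intercept at log(0.3 / yr), location intercept at 0, remaining
        coefficients at 0; random-effect sds start at 0.1 and the
        observation-error sd at 0.1 x sd of the observed lengths.
        """
        beta = {}
        for p in PARAM_NAMES:
            b = np.zeros(self.design.ncols(p))
            beta[p] = b
        beta["asymptote"][0] = np.log(1.1 * float(np.max(self._y)))
        beta["rate"][0] = np.log(0.3)
        log_sigma = {
            p: (np.log(0.1) if on else None)
            for p, on in zip(PARAM_NAMES, self.spec.random_effects)
        }
        sd_len = float(np.std(self._y))
        return ParameterSet(
            beta=beta,
            log_sigma=log_sigma,
            log_sigma_eps=float(np.log(max(0.1 * sd_len, 1e-2))),
        )

    def _objective(self, x: np.ndarray) -> float:
        theta = self.layout.unpack(x)
        try:
            E, H, f, ok = self.inner_modes(theta, start=self._warm_modes)
        except Exception:  # pragma: no cover - inner solver is penalty-guarded
            return 1e12
        if not ok.all():
            return 1e10 + 1e6 * float(np.sum(~ok))
        self._warm_modes = E
        try:
            return self._laplace_from_parts(H, f)
        except RuntimeError:
            return 1e10

    def _polish(self, x: np.ndarray, opts: "FitOptions", max_steps: int = 5) -> np.ndarray:
        f = self._objective(x)
        if not np.isfinite(f) or f >= 1e9:
            return x
        for _ in range(max_steps):
            g = _central_gradient(self._objective, x)
            if np.max(np.abs(g)) / max(1.0, abs(f)) < 0.3 * opts.grad_tol:
                break
            H = _central_hessian(self._objective, x)
            H = (H + H.T) / 2.0
            eig = np.linalg.eigvalsh(H)
            if eig[0] <= 0:
                H = H + (1e-6 * max(1.0, eig[-1]) - eig[0]) * np.eye(x.size)
            step = -np.linalg.solve(H, g)
            alpha, improved = 1.0, False
            for _bt in range(12):
                fnew = self._objective(x + alpha * step)
                if fnew <= f:
                    x, f, improved = x + alpha * step, fnew, True
                    break
                alpha *= 0.5
            if not improved:
                break
        return x

    def fit(self, start: ParameterSet | None = None, options: FitOptions | None = None
            ) -> "GrowthResults":
        """Maximize the Laplace marginal likelihood.

        Deterministic given data, spec and options. Never raises on
        non-convergence: the returned result carries ``converged=False``
        and diagnostics instead.
        """
        opts = options or FitOptions()
        theta0 = start or self.start_values()
        x0 = self.layout.pack(theta0)
        self._warm_modes = None
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.minimize(
                self._objective,
                x0,
                method="L-BFGS-B",
                options={
                    "maxiter": opts.outer_maxiter,
                    "ftol": 1e-11,
                    "gtol": 1e-7,
                    "maxcor": 25,
                },
            )
        xhat = res.x
        # Newton polish: the quasi-Newton stage stops on function-value
        # stalls; a few damped Newton steps on finite-difference
        # derivatives push the gradient down to the convergence criterion
        xhat = self._polish(xhat, opts)
        theta_hat = self.layout.unpack(xhat)
        nll = self._objective(xhat)
        E, H, f, ok = self.inner_modes(theta_hat, start=self._warm_modes,
                                       tol=opts.inner_tol, maxiter=opts.inner_maxiter)

        grad = _central_gradient(self._objective, xhat)
        grad_norm = float(np.max(np.abs(grad)))
        rel_grad = grad_norm / max(1.0, abs(nll))

        cov = None
        bse = None
        hess_pd = False
        if opts.compute_se:
            Hout = _central_hessian(self._objective, xhat)
            eig = np.linalg.eigvalsh((Hout + Hout.T) / 2.0)
            hess_pd = bool(eig[0] > 1e-10 * max(1.0, eig[-1]))
            if hess_pd:
                cov = np.linalg.inv((Hout + Hout.T) / 2.0)
                d = np.diag(cov)
                bse = np.sqrt(np.where(d > 0, d, np.nan))
        converged = bool(
            ok.all() and np.isfinite(nll) and nll < 1e9 and rel_grad < opts.grad_tol
            and (hess_pd or not opts.compute_se)
        )
        re_sd = np.full((self.data.n_fish, self.q), np.nan)
        if self.q:
            with np.errstate(invalid="ignore"):
                inv_diag = np.linalg.inv(H).diagonal(axis1=1, axis2=2)
                re_sd = np.sqrt(np.clip(inv_diag, 0.0, None))
        return GrowthResults(
            model=self,
            params=theta_hat,
            x=xhat,
            nll=float(nll),
            converged=converged,
            cov_params_=cov,
            bse_=bse,
            effects_=E,
            effect_sds_=re_sd,
            inner_hessians_=H,
            diagnostics={
                "grad_norm": grad_norm,
                "rel_grad": rel_grad,
                "outer_hessian_pd": hess_pd,
                "n_inner_failures": int(np.sum(~ok)),
                "optimizer_message": str(res.message),
                "n_outer_iter": int(res.nit),
            },
        )


def _central_gradient(fn, x, rel_step: float = 1e-6) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    g = np.zeros_like(x)
    for j in range(x.size):
        h = rel_step * max(1.0, abs(x[j]))
        xp, xm = x.copy(), x.copy()
        xp[j] += h
        xm[j] -= h
        g[j] = (fn(xp) - fn(xm)) / (2.0 * h)
    return g


def _central_hessian(fn, x, rel_step: float = 1e-4) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    n = x.size
    h = rel_step * np.maximum(1.0, np.abs(x))
    H = np.zeros((n, n))
    f0 = fn(x)
    # diagonal
    for j in range(n):
        xp, xm = x.copy(), x.copy()
        xp[j] += h[j]
        xm[j] -= h[j]
        H[j, j] = (fn(xp) - 2.0 * f0 + fn(xm)) / h[j] ** 2
    for j in range(n):
        for k in range(j + 1, n):
            xpp, xpm, xmp, xmm = x.copy(), x.copy(), x.copy(), x.copy()
            xpp[[j, k]] += [h[j], h[k]]
            xpm[j] += h[j]
            xpm[k] -= h[k]
            xmp[j] -= h[j]
            xmp[k] += h[k]
            xmm[[j, k]] -= [h[j], h[k]]
            H[j, k] = H[k, j] = (fn(xpp) - fn(xpm) - fn(xmp) + fn(xmm)) / (4.0 * h[j] * h[k])
    return H


@dataclass
class GrowthResults:
    """Converged (or not) fit of a GrowthModel.

    Carries the estimates, their uncertainties, the marginal nll/AIC,
    per-fish empirical-Bayes effects and convergence diagnostics.
    """

    model: GrowthModel
    params: ParameterSet
    x: np.ndarray
    nll: float
    converged: bool
    cov_params_: np.ndarray | None
    bse_: np.ndarray | None
    effects_: np.ndarray
    effect_sds_: np.ndarray
    inner_hessians_: np.ndarray
    diagnostics: dict = field(default_factory=dict)

    # -- information criteria -------------------------------------------
    @property
    def n_params(self) -> int:
        """Estimated parameters: fixed coefficients + estimated sds
        (random effects are integrated out, not counted)."""
        return self.model.layout.size

    @property
    def aic(self) -> float:
        if not self.converged:
            raise ValueError("AIC is undefined for a non-converged fit")
        return 2.0 * self.nll + 2.0 * self.n_params

    # -- uncertainties ---------------------------------------------------
    def cov_params(self) -> np.ndarray:
        if self.cov_params_ is None:
            raise ValueError("no covariance available (outer Hessian not PD or not computed)")
        return self.cov_params_

    @property
    def bse(self) -> pd.Series:
        if self.bse_ is None:
            raise ValueError("no standard errors available (outer Hessian not PD)")
        return pd.Series(self.bse_, index=self.model.layout.names)

    def params_series(self) -> pd.Series:
        return pd.Series(self.x, index=self.model.layout.names)

    # -- random effects / individual parameters --------------------------
    def random_effects(self) -> pd.DataFrame:
        """Empirical-Bayes modes (and approximate conditional sds)."""
        m = self.model
        df = pd.DataFrame(
            self.effects_, columns=[f"effect_{p}" for p in PARAM_NAMES],
            index=pd.Index(m.data.fish_ids, name="fish_id"),
        )
        for a, j in enumerate(m.active):
            df[f"sd_{PARAM_NAMES[j]}"] = self.effect_sds_[:, a]
        return df

    def individual_parameters(self) -> pd.DataFrame:
        """Natural-scale (asymptote, rate, location) per fish."""
        m = self.model
        asym, rate, loc = linear_predictors(self.params, self.effects_, m.design)
        out = m.data.fish_table[
            [c for c in ("species", "population", "cohort") if c in m.data.fish_table.columns]
        ].copy()
        out["asymptote"] = asym
        out["rate"] = rate
        out["location"] = loc
        return out

    def group_parameters(self) -> pd.DataFrame:
        """Natural-scale parameters of every modelled group (zero effects),
        with delta-method standard errors when a covariance is available.

        A "group" is a distinct combination of the categorical predictors
        the spec actually uses; with constant-only predictors there is a
        single overall row.
        """
        m = self.model
        used = []
        for p in PARAM_NAMES:
            for term in m.spec.terms(p):
                for piece in term.split(":"):
                    if piece in m.data.levels and piece not in used:
                        used.append(piece)
        zero = np.zeros((m.data.n_fish, 3))
        asym, rate, loc = linear_predictors(self.params, zero, m.design)
        df = m.data.fish_table[used].copy() if used else pd.DataFrame(index=m.data.fish_table.index)
        df["asymptote"], df["rate"], df["location"] = asym, rate, loc
        first_idx = ~df.duplicated()
        rows = df.loc[first_idx].reset_index(drop=True)
        if self.cov_params_ is not None:
            ses = {p: [] for p in PARAM_NAMES}
            # slice of the packed covariance for each coefficient block
            offs, slices = 0, {}
            for p in PARAM_NAMES:
                n = m.design.ncols(p)
                slices[p] = slice(offs, offs + n)
                offs += n
            for i in np.flatnonzero(first_idx.to_numpy()):
                for p, natural in zip(PARAM_NAMES, (asym, rate, loc)):
                    xrow = m.design.X[p][i]
                    var = float(xrow @ self.cov_params_[slices[p], slices[p]] @ xrow)
                    se_eta = np.sqrt(max(var, 0.0))
                    # log link on asymptote and rate: delta method multiplies by the value
                    ses[p].append(se_eta * (natural[i] if p != "location" else 1.0))
            for p in PARAM_NAMES:
                rows[f"se_{p}"] = ses[p]
        return rows

    # -- prediction -------------------------------------------------------
    def predict(self, fish_id, age, fallback_labels: dict | None = None) -> pd.DataFrame:
        """Predict length-at-age for fitted fish via their EB effects.

        ``fish_id`` and ``age`` may be scalars or equal-length sequences.
        Unknown fish raise KeyError unless ``fallback_labels`` supplies
        group labels, in which case the group-mean curve (zero effects)
        is used for those fish. Standard errors combine the fixed-effect
        covariance (delta method through the curve and linear predictors)
        with the conditional spread of the fish's effects.
        """
        m = self.model
        fish = np.atleast_1d(np.asarray(fish_id, dtype=object))
        ages = np.atleast_1d(np.asarray(age, dtype=float))
        if fish.size == 1 and ages.size > 1:
            fish = np.repeat(fish, ages.size)
        if ages.size == 1 and fish.size > 1:
            ages = np.repeat(ages, fish.size)
        if fish.size != ages.size:
            raise ValueError("fish_id and age must have matching lengths")
        sig = np.array([self.params.sigma(p) for p in PARAM_NAMES])
        recs = []
        for f_id, t in zip(fish, ages):
            if f_id in m.data._fish_index:
                i = m.data._fish_index[f_id]
                xrows = {p: m.design.X[p][i] for p in PARAM_NAMES}
                eff = self.effects_[i]
                Hin = self.inner_hessians_[i] if m.q else None
            elif fallback_labels is not None:
                xrows = design_rows_for_labels(m.data, m.spec, fallback_labels)
                eff = np.zeros(3)
                Hin = None
            else:
                raise KeyError(
                    f"fish {f_id!r} was not part of the fitted dataset "
                    "(pass fallback_labels for a group-mean prediction)"
                )
            eta = np.array(
                [float(xrows[p] @ self.params.beta[p]) + sig[j] * eff[j]
                 for j, p in enumerate(PARAM_NAMES)]
            )
            L, d1, _ = _curve_eval(
                m.spec.function, np.array(eta[0]), np.array(eta[1]), np.array(eta[2]),
                np.array(float(t)), order=1,
            )
            var = np.nan
            if self.cov_params_ is not None:
                gfull = np.concatenate(
                    [d1[j] * xrows[p] for j, p in enumerate(PARAM_NAMES)]
                )
                # pad for the sd entries (prediction holds modes fixed there)
                gfull = np.concatenate([gfull, np.zeros(m.layout.size - gfull.size)])
                var = float(gfull @ self.cov_params_ @ gfull)
                if Hin is not None and m.q:
                    v = np.array([sig[j] * d1[j] for j in m.active])
                    var += float(v @ np.linalg.solve(Hin, v))
            recs.append((f_id, float(t), float(L), float(np.sqrt(var)) if var == var else np.nan))
        return pd.DataFrame(recs, columns=["fish_id", "age", "predicted_length", "se"])

    # -- reporting --------------------------------------------------------
    def summary(self) -> str:
        m = self.model
        lines = [
            "Mixed-effects growth model (Laplace marginal likelihood)",
            "=" * 58,
            f"Model:        {m.spec.label}",
            f"Observations: {m.data.n_obs}   Fish: {m.data.n_fish}",
            f"Converged:    {self.converged}   "
            f"(rel. gradient {self.diagnostics.get('rel_grad', float('nan')):.2e})",
            f"Marginal NLL: {self.nll:.4f}",
        ]
        if self.converged:
            lines.append(f"AIC:          {self.aic:.4f}   (parameters: {self.n_params})")
        lines.append("-" * 58)
        lines.append(f"{'parameter':<34}{'estimate':>12}{'std err':>12}")
        se = self.bse_ if self.bse_ is not None else np.full(self.x.size, np.nan)
        for name, val, s in zip(m.layout.names, self.x, se):
            lines.append(f"{name:<34}{val:>12.4f}{s:>12.4f}")
        lines.append("-" * 58)
        for p in PARAM_NAMES:
            sd = self.params.sigma(p)
            lines.append(f"sigma({p}) = {sd:.4f}" + ("" if sd else "  (off)"))
        lines.append(f"sigma(eps) = {self.params.sigma_eps:.4f} mm")
        return "\n".join(lines)

    def plot_fish(self, fish_id, ax=None, ages=None):
        """Observed lengths and the fish's EB growth curve (needs matplotlib)."""
        import matplotlib.pyplot as plt

        m = self.model
        if ax is None:
            _, ax = plt.subplots()
        sel = m.data.frame["fish_id"] == fish_id
        obs = m.data.frame.loc[sel]
        if ages is None:
            ages = np.linspace(0.5, max(8.0, obs["age"].max() + 1), 100)
        pred = self.predict(fish_id, ages)
        ax.plot(pred["age"], pred["predicted_length"], "-", label=f"{fish_id} (EB curve)")
        ax.plot(obs["age"], obs["length"], "o", label="observed")
        ax.set_xlabel("age (yr)")
        ax.set_ylabel("length (mm)")
        ax.legend()
        return ax
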