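"""Generalized linear mixed models for pollen transfer and feeding efficiency.

Random-intercept GLMMs with a log link, fitted by maximum likelihood with
a Laplace approximation over the random effects.  Three response families
cover the study's variables:

* **NB2** (negative binomial, variance ``mu + mu^2/theta``) for stigma
  pollen counts;
* **Tweedie** (compound Poisson-gamma, power in (1, 2), point mass at
  zero) for anther-contact durations and pollen-patch areas, optionally
  with a structural zero-inflation probability per species;
* **Gamma** for strictly positive feeding durations and efficiencies.

Inference helpers mirror the standard mixed-model workflow: type-III
Wald chi-square tests per fixed-effect term, Tukey-adjusted pairwise
contrasts on the link scale, Cohen's d on the raw response, and
marginal/conditional R² with the trigamma observation-level variance.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, special, stats
from statsmodels.tools.numdiff import approx_hess1

__all__ = [
    "GlmmError",
    "ModelSpec",
    "ModelFit",
    "ContrastResult",
    "R2Pair",
    "fit_glmm",
    "type3_test",
    "pairwise_contrasts",
    "cohens_d",
    "percent_change",
    "r2_nakagawa",
    "trial_effect_check",
    "tweedie_logpdf",
]

_FAMILIES = ("negative_binomial", "tweedie", "gamma")

# effectively-infinite df for studentized-range p values (asymptotic z scale)
_TUKEY_DF = 1e6


class GlmmError(ValueError):
    """Invalid model specification, data, or degenerate fit."""


# --------------------------------------------------------------------------
# model specification and design matrices
# --------------------------------------------------------------------------

@dataclass
class ModelSpec:
    """Specification of one GLMM.

    ``random_effects`` is ``"bird_id"`` (one random intercept per bird) or
    ``"bird_id_in_species"`` (intercepts for species and for bird nested
    within species).  ``zero_inflation`` is ``None`` or ``"species"`` and
    is only valid with the Tweedie family.
    """

    response: str
    family: str
    fixed_effects: list[str]
    random_effects: str | None = "bird_id"
    zero_inflation: str | None = None
    name: str = ""

    def __post_init__(self) -> None:
        if self.family not in _FAMILIES:
            raise GlmmError(f"family must be one of {_FAMILIES}, got {self.family!r}")
        if self.zero_inflation not in (None, "species"):
            raise GlmmError("zero_inflation must be None or 'species'")
        if self.zero_inflation and self.family != "tweedie":
            raise GlmmError("zero inflation is only supported with the tweedie family")
        if self.random_effects not in (None, "bird_id", "bird_id_in_species"):
            raise GlmmError("random_effects must be None, 'bird_id' or 'bird_id_in_species'")


def _build_design(data: pd.DataFrame, fixed_effects: list[str]):
    """Treatment-coded design matrix with a term -> column-indices map."""
    n = len(data)
    cols = [np.ones(n)]
    names = ["(Intercept)"]
    term_cols: dict[str, list[int]] = {}
    levels: dict[str, list[str]] = {}
    for term in fixed_effects:
        if term not in data.columns:
            raise GlmmError(f"fixed effect {term!r} not in data")
        col = data[term]
        if col.dtype == object or isinstance(col.dtype, pd.CategoricalDtype):
            levs = sorted(col.astype(str).unique())
            if len(levs) < 2:
                raise GlmmError(f"factor {term!r} needs >= 2 levels")
            levels[term] = levs
            idxs = []
            for lev in levs[1:]:
                idxs.append(len(cols))
                cols.append((col.astype(str) == lev).to_numpy(dtype=float))
                names.append(f"{term}[{lev}]")
            term_cols[term] = idxs
        else:
            term_cols[term] = [len(cols)]
            cols.append(col.to_numpy(dtype=float))
            names.append(term)
    X = np.column_stack(cols)
    return X, names, term_cols, levels


def _random_factors(data: pd.DataFrame, random_effects: str | None):
    """List of (name, level_index_per_obs, n_levels)."""
    if random_effects is None:
        return []
    bird = pd.Categorical(data["bird_id"].astype(str))
    factors = []
    if random_effects == "bird_id_in_species":
        sp = pd.Categorical(data["species"].astype(str))
        if len(sp.categories) < 2:
            raise GlmmError("species grouping factor needs >= 2 levels")
        factors.append(("species", np.asarray(sp.codes), len(sp.categories)))
    if len(bird.categories) < 2:
        raise GlmmError("bird_id grouping factor needs >= 2 levels")
    factors.append(("bird_id", np.asarray(bird.codes), len(bird.categories)))
    return factors


# --------------------------------------------------------------------------
# response families (log link); derivatives are with respect to eta = log mu
# --------------------------------------------------------------------------

class _NB2:
    """NB2: variance mu + mu^2/theta."""

    def __init__(self, theta: float):
        self.theta = theta

    def loglik(self, y, mu):
        t = self.theta
        return np.sum(special.gammaln(y + t) - special.gammaln(t) - special.gammaln(y + 1)
                      + t * math.log(t) + y * np.log(mu) - (y + t) * np.log(mu + t))

    def d1(self, y, mu):
        return y - mu * (y + self.theta) / (mu + self.theta)

    def d2(self, y, mu):
        t = self.theta
        return -mu * t * (y + t) / (mu + t) ** 2


class _Gamma:
    """Gamma with shape k and mean mu (variance mu^2/k)."""

    def __init__(self, shape: float):
        self.shape = shape

    def loglik(self, y, mu):
        k = self.shape
        return np.sum(k * math.log(k) - special.gammaln(k) + (k - 1) * np.log(y)
                      - k * np.log(mu) - k * y / mu)

    def d1(self, y, mu):
        return self.shape * (y / mu - 1.0)

    def d2(self, y, mu):
        return -self.shape * y / mu


def tweedie_logpdf(y, mu, phi: float, power: float) -> np.ndarray:
    """Log density of the Tweedie compound Poisson-gamma distribution.

    Evaluated by the series expansion over the latent Poisson count; terms
    are summed in log space around the dominant index, which is exact to
    numerical truncation (terms below max - 40 log units are negligible).
    Valid for power in (1, 2); ``y = 0`` has the closed-form point mass
    ``exp(-mu^(2-p) / (phi (2-p)))``.
    """
    y = np.asarray(y, dtype=float)
    mu = np.broadcast_to(np.asarray(mu, dtype=float), y.shape)
    p = power
    if not 1.0 < p < 2.0:
        raise GlmmError(f"tweedie power must be in (1, 2), got {p}")
    out = np.empty_like(y)
    lam = mu ** (2.0 - p) / (phi * (2.0 - p))
    zero = y == 0
    out[zero] = -lam[zero]
    if np.any(~zero):
        yp = y[~zero]
        lamp = lam[~zero]
        mup = mu[~zero]
        alpha = (2.0 - p) / (p - 1.0)
        rate = 1.0 / (phi * (p - 1.0) * mup ** (p - 1.0))
        jstar = yp ** (2.0 - p) / (phi * (2.0 - p))
        j_hi = int(min(max(np.ceil(2.0 * jstar.max()) + 20, 40), 20000))
        log_lam = np.log(lamp)
        log_rate = np.log(rate)
        log_y = np.log(yp)
        acc = np.full(yp.shape, -np.inf)
        chunk = 512
        for j0 in range(1, j_hi + 1, chunk):
            js = np.arange(j0, min(j0 + chunk, j_hi + 1), dtype=float)
            a = js[None, :] * alpha
            logw = (js[None, :] * log_lam[:, None] - special.gammaln(js + 1.0)[None, :]
                    + a * log_rate[:, None] + (a - 1.0) * log_y[:, None]
                    - special.gammaln(a))
            acc = np.logaddexp(acc, special.logsumexp(logw, axis=1))
        out[~zero] = -lamp - rate * yp + acc
    return out


def _tweedie_tilt(y, mu, phi: float, p: float):
    """Exponential-family tilt ``(y theta - kappa(theta)) / phi`` at log link."""
    return (y * mu ** (1.0 - p) / (1.0 - p) - mu ** (2.0 - p) / (2.0 - p)) / phi


def _tweedie_logconst(y, phi: float, p: float) -> np.ndarray:
    """Normalizing term ``log a(y, phi, p)``, independent of the mean.

    Obtained by evaluating the series density at mu = y (its most stable
    point) and removing the tilt; zero observations contribute 0.
    """
    c = np.zeros_like(y)
    pos = y > 0
    if np.any(pos):
        yp = y[pos]
        c[pos] = tweedie_logpdf(yp, yp, phi, p) - _tweedie_tilt(yp, yp, phi, p)
    return c


class _Tweedie:
    """Tweedie with optional per-observation structural zero probability.

    ``logconst`` caches the mean-independent series term so the inner
    Newton iterations and most outer gradient steps skip the series.
    """

    def __init__(self, phi: float, power: float, zi_prob: np.ndarray | None = None,
                 logconst: np.ndarray | None = None):
        self.phi = phi
        self.power = power
        self.zi_prob = zi_prob  # per-observation pi, or None
        self.logconst = logconst

    def loglik(self, y, mu):
        if self.logconst is None:
            self.logconst = _tweedie_logconst(y, self.phi, self.power)
        ll = self.logconst + _tweedie_tilt(y, mu, self.phi, self.power)
        if self.zi_prob is None:
            return float(np.sum(ll))
        pi = self.zi_prob
        zero = y == 0
        out = np.where(zero,
                       np.log(pi + (1.0 - pi) * np.exp(ll)),
                       np.log1p(-pi) + ll)
        return float(np.sum(out))

    def d1(self, y, mu):
        p, phi = self.power, self.phi
        base = (y * mu ** (1.0 - p) - mu ** (2.0 - p)) / phi
        if self.zi_prob is None:
            return base
        pi = self.zi_prob
        zero = y == 0
        lam = mu ** (2.0 - p) / (phi * (2.0 - p))
        A = (1.0 - pi) * np.exp(-lam)
        f0 = pi + A
        c = (2.0 - p) * lam
        d_zero = -(A / f0) * c
        return np.where(zero, d_zero, base)

    def d2(self, y, mu):
        p, phi = self.power, self.phi
        base = ((1.0 - p) * y * mu ** (1.0 - p) - (2.0 - p) * mu ** (2.0 - p)) / phi
        if self.zi_prob is None:
            return base
        pi = self.zi_prob
        zero = y == 0
        lam = mu ** (2.0 - p) / (phi * (2.0 - p))
        A = (1.0 - pi) * np.exp(-lam)
        f0 = pi + A
        c = (2.0 - p) * lam
        d2_zero = -(2.0 - p) * c * (A / f0) + c ** 2 * A * pi / f0 ** 2
        return np.where(zero, d2_zero, base)


# --------------------------------------------------------------------------
# Laplace approximation over random intercepts
# --------------------------------------------------------------------------

def _laplace_loglik(y, eta_fix, fam, factors, sigma2s, b_cache):
    """Laplace-approximated marginal log likelihood.

    ``factors``: list of (name, obs->level index, n_levels); one
    independent intercept variance per factor.  ``b_cache`` warm-starts
    the inner Newton solve between outer-optimizer evaluations.
    """
    if not factors:  # pure GLM: the marginal likelihood is the likelihood
        return float(fam.loglik(y, np.exp(eta_fix)))
    offsets = np.cumsum([0] + [q for _, _, q in factors])
    q_tot = offsets[-1]
    b = b_cache.get("b")
    if b is None or len(b) != q_tot:
        b = np.zeros(q_tot)

    def eta_of(bv):
        e = eta_fix.copy()
        for (name, idx, q), off in zip(factors, offsets):
            e += bv[off:off + q][idx]
        return e

    def penalized(bv):
        ll = fam.loglik(y, np.exp(eta_of(bv)))
        pen = sum(0.5 * np.sum(bv[off:off + q] ** 2) / s2
                  for (_, _, q), off, s2 in zip(factors, offsets, sigma2s))
        return ll - pen

    obj = penalized(b)
    single = len(factors) == 1
    for _ in range(100):
        mu = np.exp(eta_of(b))
        d1 = fam.d1(y, mu)
        d2 = fam.d2(y, mu)
        if single:
            _, idx, q = factors[0]
            g = np.bincount(idx, weights=d1, minlength=q) - b / sigma2s[0]
            h = np.maximum(-np.bincount(idx, weights=d2, minlength=q) + 1.0 / sigma2s[0], 1e-10)
            step = g / h
        else:
            g = np.concatenate([
                np.bincount(idx, weights=d1, minlength=q) - b[off:off + q] / s2
                for (_, idx, q), off, s2 in zip(factors, offsets, sigma2s)])
            H = np.zeros((q_tot, q_tot))
            for (fa, ia, qa), offa in zip(factors, offsets):
                for (fb, ib, qb), offb in zip(factors, offsets):
                    np.add.at(H, (offa + ia, offb + ib), -d2)
            H[np.diag_indices_from(H)] += np.repeat(
                [1.0 / s2 for s2 in sigma2s], [q for _, _, q in factors])
            try:
                step = np.linalg.solve(H, g)
            except np.linalg.LinAlgError:
                step = np.linalg.lstsq(H, g, rcond=None)[0]
        # damped Newton: halve until the penalized objective improves
        t = 1.0
        for _ in range(30):
            b_new = b + t * step
            obj_new = penalized(b_new)
            if np.isfinite(obj_new) and obj_new >= obj - 1e-12:
                break
            t *= 0.5
        else:
            break
        moved = np.max(np.abs(t * step))
        b, obj = b_new, obj_new
        if moved < 1e-9:
            break
    b_cache["b"] = b

    mu = np.exp(eta_of(b))
    d2 = fam.d2(y, mu)
    if single:
        _, idx, q = factors[0]
        h = np.maximum(-np.bincount(idx, weights=d2, minlength=q) + 1.0 / sigma2s[0], 1e-12)
        logdet = float(np.sum(np.log(h)))
    else:
        H = np.zeros((q_tot, q_tot))
        for (fa, ia, qa), offa in zip(factors, offsets):
            for (fb, ib, qb), offb in zip(factors, offsets):
                np.add.at(H, (offa + ia, offb + ib), -d2)
        H[np.diag_indices_from(H)] += np.repeat(
            [1.0 / s2 for s2 in sigma2s], [q for _, _, q in factors])
        sign, logdet = np.linalg.slogdet(H)
        if sign <= 0:
            logdet = float(np.sum(np.log(np.maximum(np.diag(H), 1e-12))))
    ll_m = obj - 0.5 * logdet
    for (_, _, q), s2 in zip(factors, sigma2s):
        ll_m -= 0.5 * q * math.log(s2)
    return float(ll_m)


# --------------------------------------------------------------------------
# fitting
# --------------------------------------------------------------------------

@dataclass
class ModelFit:
    """A fitted random-intercept GLMM."""

    spec: ModelSpec
    coefficients_link: pd.Series
    coefficients_response: pd.Series
    vcov_fixed: pd.DataFrame
    random_variances: dict[str, float]
    dispersion: float                 # NB2 theta / gamma shape / tweedie phi
    tweedie_power: float | None
    zi_probs: dict[str, float] | None
    loglik: float
    converged: bool
    n_obs: int
    term_columns: dict[str, list[int]]
    factor_levels: dict[str, list[str]]
    param_table: pd.DataFrame         # all outer parameters, est + SE
    data: pd.DataFrame = field(repr=False)
    eta_fixed: np.ndarray = field(repr=False, default=None)

    @property
    def family(self) -> str:
        return self.spec.family


def _validate_response(y: np.ndarray, family: str) -> None:
    if np.any(~np.isfinite(y)):
        raise GlmmError("response contains non-finite values")
    if family == "negative_binomial":
        if np.any(y < 0) or np.any(y != np.round(y)):
            raise GlmmError("negative-binomial response must be nonnegative counts")
    elif family == "tweedie":
        if np.any(y < 0):
            raise GlmmError("tweedie response must be nonnegative")
        if not np.any(y > 0):
            raise GlmmError("tweedie response is identically zero")
    elif family == "gamma":
        if np.any(y <= 0):
            raise GlmmError("gamma response must be strictly positive "
                            "(zeros need the tweedie family)")


def fit_glmm(spec: ModelSpec, data: pd.DataFrame) -> ModelFit:
    """Fit a random-intercept GLMM by Laplace-approximated ML.

    Raises on invalid family/response combinations; a fit that does not
    converge is returned with ``converged=False`` and a warning, never
    silently.
    """
    data = data.reset_index(drop=True)
    y = data[spec.response].to_numpy(dtype=float)
    _validate_response(y, spec.family)
    X, names, term_cols, fac_levels = _build_design(data, spec.fixed_effects)
    factors = _random_factors(data, spec.random_effects)
    n, p = X.shape

    zi_species = None
    n_zi = 0
    if spec.zero_inflation == "species":
        zi_species = pd.Categorical(data["species"].astype(str))
        n_zi = len(zi_species.categories)
        fac_levels = dict(fac_levels)
        fac_levels.setdefault("species", list(zi_species.categories))

    # ---- starting values -------------------------------------------------
    ybar = max(y.mean(), 1e-6)
    logy = np.log(np.maximum(y, 0.1 * ybar))
    beta0, *_ = np.linalg.lstsq(X, logy, rcond=None)
    mu0 = np.exp(np.clip(X @ beta0, -20, 20))
    if spec.family == "negative_binomial":
        ex = max((y.var() - ybar), 1e-3)
        disp0 = float(np.clip(ybar ** 2 / ex, 0.05, 20.0))
    elif spec.family == "gamma":
        cv2 = max(np.var(y / mu0, ddof=1), 1e-3)
        disp0 = float(np.clip(1.0 / cv2, 0.05, 100.0))
    else:
        disp0 = float(np.clip(y.var() / ybar ** 1.5, 0.05, 20.0))
    params0 = list(beta0) + [math.log(disp0)]
    if spec.family == "tweedie":
        params0.append(0.0)  # power = 1.5
    if n_zi:
        for k in range(n_zi):
            frac = float(np.mean(y[np.asarray(zi_species.codes) == k] == 0))
            params0.append(float(np.clip(special.logit(max(frac * 0.5, 0.02)), -5, 3)))
    params0 += [math.log(0.3)] * len(factors)
    params0 = np.asarray(params0, dtype=float)

    lo = np.full_like(params0, -np.inf)
    hi = np.full_like(params0, np.inf)
    lo[p] , hi[p] = -5.0, 7.0                       # log dispersion
    k = p + 1
    if spec.family == "tweedie":
        lo[k], hi[k] = -4.0, 4.0                    # power transform
        k += 1
    if n_zi:
        lo[k:k + n_zi], hi[k:k + n_zi] = -10.0, 6.0
        k += n_zi
    lo[k:], hi[k:] = -6.0, 2.5                      # log sigma

    b_cache: dict = {}

    def unpack(theta):
        beta = theta[:p]
        disp = math.exp(theta[p])
        i = p + 1
        power = None
        if spec.family == "tweedie":
            power = 1.0 + special.expit(theta[i]) * 0.96 + 0.02  # (1.02, 1.98)
            i += 1
        zi = None
        if n_zi:
            zi = special.expit(theta[i:i + n_zi])
            i += n_zi
        sigmas2 = np.exp(2.0 * theta[i:])
        return beta, disp, power, zi, sigmas2

    const_cache: dict[tuple[float, float], np.ndarray] = {}

    def make_family(disp, power, zi):
        if spec.family == "negative_binomial":
            return _NB2(disp)
        if spec.family == "gamma":
            return _Gamma(disp)
        zi_obs = zi[np.asarray(zi_species.codes)] if zi is not None else None
        key = (disp, power)
        if key not in const_cache:
            if len(const_cache) > 64:
                const_cache.clear()
            const_cache[key] = _tweedie_logconst(y, disp, power)
        return _Tweedie(disp, power, zi_obs, logconst=const_cache[key])

    def negloglik(theta):
        beta, disp, power, zi, sigmas2 = unpack(theta)
        eta_fix = np.clip(X @ beta, -30, 30)
        fam = make_family(disp, power, zi)
        try:
            ll = _laplace_loglik(y, eta_fix, fam, factors, sigmas2, b_cache)
        except (FloatingPointError, OverflowError):
            return 1e10
        if not np.isfinite(ll):
            return 1e10
        return -ll

    with np.errstate(over="ignore", under="ignore", invalid="ignore", divide="ignore"):
        res = optimize.minimize(
            negloglik, params0, method="L-BFGS-B",
            bounds=list(zip(lo, hi)),
            options={"maxiter": 1000, "maxfun": 20000, "ftol": 1e-11, "gtol": 1e-7})
        theta_hat = res.x
        # covariance of all outer parameters from the observed information
        Hs = approx_hess1(theta_hat, negloglik)
        try:
            vcov_all = np.linalg.inv(Hs)
        except np.linalg.LinAlgError:
            vcov_all = np.linalg.pinv(Hs)
    d = np.diag(vcov_all)
    if np.any(d < 0):  # salvage an indefinite numerical Hessian
        vcov_all = np.linalg.pinv(approx_hess1(theta_hat, negloglik, epsilon=1e-4))
        d = np.diag(vcov_all)
    se_all = np.sqrt(np.abs(d))

    beta, disp, power, zi, sigmas2 = unpack(theta_hat)
    converged = bool(res.success) and np.isfinite(res.fun)
    if not converged:
        warnings.warn(f"WARN GLMM '{spec.name or spec.response}' did not converge: "
                      f"{res.message}", stacklevel=2)

    pnames = list(names) + ["log_dispersion"]
    if spec.family == "tweedie":
        pnames.append("power_raw")
    if n_zi:
        pnames += [f"zi[{lev}]" for lev in zi_species.categories]
    pnames += [f"log_sd({fname})" for fname, _, _ in factors]
    ptab = pd.DataFrame({"estimate": theta_hat, "se": se_all}, index=pnames)

    coef = pd.Series(beta, index=names)
    zi_probs = (dict(zip(zi_species.categories, map(float, zi))) if n_zi else None)
    fit = ModelFit(
        spec=spec,
        coefficients_link=coef,
        coefficients_response=np.exp(coef),
        vcov_fixed=pd.DataFrame(vcov_all[:p, :p], index=names, columns=names),
        random_variances={fname: float(s2) for (fname, _, _), s2 in zip(factors, sigmas2)},
        dispersion=float(disp),
        tweedie_power=(float(power) if power is not None else None),
        zi_probs=zi_probs,
        loglik=float(-res.fun),
        converged=converged,
        n_obs=n,
        term_columns=term_cols,
        factor_levels=fac_levels,
        param_table=ptab,
        data=data,
        eta_fixed=X @ beta,
    )
    return fit


# --------------------------------------------------------------------------
# inference
# --------------------------------------------------------------------------

def type3_test(fit: ModelFit, term: str) -> float:
    """Type-III Wald chi-square p value for one fixed-effect term.

    Each term is tested with all other terms present in the model, via
    the Wald statistic b' V^-1 b on the term's coefficient block.
    """
    if term not in fit.term_columns:
        raise GlmmError(f"term {term!r} not in fixed effects {list(fit.term_columns)}")
    idx = fit.term_columns[term]
    b = fit.coefficients_link.iloc[idx].to_numpy()
    V = fit.vcov_fixed.iloc[idx, idx].to_numpy()
    try:
        Vi = np.linalg.inv(V)
    except np.linalg.LinAlgError as exc:
        cols = [fit.coefficients_link.index[i] for i in idx]
        raise GlmmError(f"singular covariance for term {term!r}; aliased columns: {cols}") from exc
    W = float(b @ Vi @ b)
    return float(stats.chi2.sf(W, df=len(idx)))


@dataclass
class ContrastResult:
    """One Tukey-adjusted pairwise comparison between factor levels."""

    pair: tuple[str, str]
    estimate_link: float     # first-listed minus second-listed, link scale
    se: float
    p_adjusted: float
    cohens_d: float


def percent_change(beta: float) -> float:
    """Response-scale interpretation of a log-link coefficient.

    A one-unit increase in the predictor multiplies the mean response by
    ``exp(beta)``, i.e. changes it by ``(exp(beta) - 1) * 100`` percent.
    """
    return (math.exp(beta) - 1.0) * 100.0


def cohens_d(data: pd.DataFrame, response: str, group_a: str, group_b: str,
             group_col: str = "species") -> float:
    """Cohen's d between two groups on the raw response scale.

    ``(mean_a - mean_b) / s_pooled`` with the n-1-weighted pooled SD.
    """
    a = data.loc[data[group_col].astype(str) == str(group_a), response].to_numpy(dtype=float)
    b = data.loc[data[group_col].astype(str) == str(group_b), response].to_numpy(dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise GlmmError("cohens_d needs n >= 2 per group")
    na, nb = len(a), len(b)
    pooled = math.sqrt(((na - 1) * a.var(ddof=1) + (nb - 1) * b.var(ddof=1)) / (na + nb - 2))
    if pooled == 0:
        raise GlmmError("cohens_d undefined: pooled SD is zero")
    return float((a.mean() - b.mean()) / pooled)


def pairwise_contrasts(fit: ModelFit, factor: str = "species") -> list[ContrastResult]:
    """All pairwise link-scale contrasts of a factor with Tukey adjustment.

    Multiplicity adjustment uses the studentized-range distribution over
    the factor's k levels (asymptotic df); Cohen's d accompanies each
    pair, computed from the raw response values.
    """
    if factor not in fit.factor_levels:
        raise GlmmError(f"factor {factor!r} has no recorded levels in this fit")
    levels = fit.factor_levels[factor]
    k = len(levels)
    coef = fit.coefficients_link
    V = fit.vcov_fixed.to_numpy()
    pos = {lev: None for lev in levels}  # coefficient index per non-reference level
    for i, name in enumerate(coef.index):
        for lev in levels[1:]:
            if name == f"{factor}[{lev}]":
                pos[lev] = i
    results = []
    pvec = len(coef)
    for i in range(k):
        for j in range(i + 1, k):
            c = np.zeros(pvec)
            if pos[levels[i]] is not None:
                c[pos[levels[i]]] += 1.0
            if pos[levels[j]] is not None:
                c[pos[levels[j]]] -= 1.0
            est = float(c @ coef.to_numpy())
            se = float(math.sqrt(max(c @ V @ c, 0.0)))
            if se == 0:
                padj = 1.0
            else:
                q = abs(est) / se * math.sqrt(2.0)
                padj = float(stats.studentized_range.sf(q, k, _TUKEY_DF))
            d = cohens_d(fit.data, fit.spec.response, levels[i], levels[j], group_col=factor)
            results.append(ContrastResult(pair=(levels[i], levels[j]),
                                          estimate_link=est, se=se,
                                          p_adjusted=min(max(padj, 0.0), 1.0),
                                          cohens_d=d))
    return results


@dataclass
class R2Pair:
    """Marginal (fixed-effects) and conditional (fixed + random) R²."""

    marginal: float
    conditional: float


def r2_nakagawa(fit: ModelFit) -> R2Pair:
    """Marginal and conditional R² with the trigamma method.

    On the latent log scale, variance explained is partitioned into the
    fixed-effect linear-predictor variance, the summed random-intercept
    variances, and a distribution-specific observation-level variance:
    ``psi1((1/mu + 1/theta)^-1)`` for NB2, ``psi1(shape)`` for Gamma, and
    the lognormal approximation ``ln(1 + phi * mu^(p-2))`` for Tweedie
    (no closed trigamma form exists for that family).
    """
    var_fixed = float(np.var(fit.eta_fixed, ddof=1))
    var_random = float(sum(fit.random_variances.values()))
    mu_bar = float(np.mean(np.exp(fit.eta_fixed + 0.5 * var_random)))
    if mu_bar <= 0:
        raise GlmmError("mean response must be positive for trigamma R²")
    if fit.family == "negative_binomial":
        var_dist = float(special.polygamma(1, 1.0 / (1.0 / mu_bar + 1.0 / fit.dispersion)))
    elif fit.family == "gamma":
        var_dist = float(special.polygamma(1, fit.dispersion))
    else:
        var_dist = float(math.log1p(fit.dispersion * mu_bar ** (fit.tweedie_power - 2.0)))
    denom = var_fixed + var_random + var_dist
    return R2Pair(marginal=var_fixed / denom,
                  conditional=(var_fixed + var_random) / denom)


def trial_effect_check(data: pd.DataFrame,
                       response: str = "stigma_pollen_count") -> dict[str, float]:
    """Type-III ANOVA p values for trial, species, and their interaction.

    The pre-check that decides whether trial number must enter the
    pollen-deposition models: when neither the trial main effect nor the
    interaction is significant, the pipeline proceeds without a trial
    term.  Uses sum-to-zero contrasts so the type-III tests are valid
    under unbalanced designs.
    """
    import statsmodels.api as sm
    import statsmodels.formula.api as smf

    df = data[["trial_number", "species", response]].copy()
    df.columns = ["trial", "species", "y"]
    model = smf.ols("y ~ C(trial, Sum) * C(species, Sum)", data=df).fit()
    tab = sm.stats.anova_lm(model, typ=3)
    return {
        "trial": float(tab.loc["C(trial, Sum)", "PR(>F)"]),
        "species": float(tab.loc["C(species, Sum)", "PR(>F)"]),
        "interaction": float(tab.loc["C(trial, Sum):C(species, Sum)", "PR(>F)"]),
    }
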