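"""Full-information maximum likelihood for family-structured path models.

The likelihood is the product over families of multivariate-normal
densities with the model-implied mean and covariance reduced to each
family's observed (non-missing) entries.  Families within a relatedness
group that share a missingness pattern share the reduced covariance, so
the deviance is accumulated from per-pattern sufficient statistics
(count, mean, centered scatter); the cost of one likelihood evaluation is
then independent of the number of families.

The gradient is computed analytically in moment space (the classical
derivatives of the Gaussian deviance with respect to mean and covariance)
and chained through forward finite differences of the smooth polynomial
parameter-to-moment map.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats
from scipy.linalg import cho_factor, cho_solve

from .families import AnalysisDataset
from .pathmodel import GroupSpec, PathModel

_LOG2PI = math.log(2.0 * math.pi)
_BIG = 1e12


class FitError(RuntimeError):
    pass


@dataclass
class FitOptions:
    n_starts: int = 3
    jitter: float = 0.2
    seed: int = 0
    gtol: float = 1e-7
    ftol: float = 1e-11
    maxiter: int = 1000
    fd_step: float = 1e-7
    #: "current" starts at the parameters as set (builder defaults assume
    #: roughly unit-scale data; warm starts rely on this); "scaled" rescales
    #: the start values by the observed sample scale per variable/factor.
    start: str = "current"


@dataclass
class FitResult:
    estimates: dict[str, float]
    minus2lnL: float
    n_free: int
    converged: bool
    grad_norm: float
    n_individuals: int
    start_values: list[float] = field(default_factory=list)
    start_deviances: list[float] = field(default_factory=list)
    standardized: pd.DataFrame | None = None
    variance_proportions: pd.DataFrame | None = None
    ci: dict[str, tuple[float, float, float]] = field(default_factory=dict)
    ci_flags: dict[str, str] = field(default_factory=dict)
    model_name: str = ""
    variable_order: list[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "model": self.model_name,
            "estimates": self.estimates,
            "minus2lnL": self.minus2lnL,
            "n_free": self.n_free,
            "converged": self.converged,
            "grad_norm": self.grad_norm,
            "n_individuals": self.n_individuals,
            "variable_order": self.variable_order,
            "start_deviances": self.start_deviances,
            "ci": {k: list(v) for k, v in self.ci.items()},
            "ci_flags": self.ci_flags,
            "standardized": None
            if self.standardized is None
            else self.standardized.to_dict(orient="records"),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, default=float)


@dataclass
class LRTResult:
    chi_square: float
    df: int
    p_value: float


# ----------------------------------------------------------- sufficient stats
@dataclass
class _Pattern:
    idx: np.ndarray      # observed column indices within the group block
    n: int
    ybar: np.ndarray
    scatter: np.ndarray  # sum (y - ybar)(y - ybar)'


@dataclass
class _GroupPrep:
    spec: GroupSpec
    patterns: list[_Pattern]
    n_individuals: int


def prepare(data: AnalysisDataset, model: PathModel) -> list[_GroupPrep]:
    if list(data.variables) != list(model.observed):
        raise FitError(
            f"dataset variables {data.variables} do not match model "
            f"observed order {model.observed}"
        )
    preps = []
    for gd in data.groups.values():
        arr = gd.data
        mask = np.isnan(arr)
        complete_rows = ~mask.all(axis=1)
        arr = arr[complete_rows]
        mask = mask[complete_rows]
        pats = []
        if arr.size:
            uniq, inverse = np.unique(mask, axis=0, return_inverse=True)
            for k in range(uniq.shape[0]):
                rows = arr[inverse == k]
                idx = np.flatnonzero(~uniq[k])
                if idx.size == 0:
                    continue
                y = rows[:, idx]
                ybar = y.mean(axis=0)
                d = y - ybar
                pats.append(_Pattern(idx, y.shape[0], ybar, d.T @ d))
        preps.append(
            _GroupPrep(gd.spec, pats, gd.data.shape[0] * gd.spec.n_members)
        )
    return preps


def _safe_cholesky(S: np.ndarray):
    """Cholesky with escalating ridge; None if hopeless."""
    ridge = 0.0
    base = max(np.trace(S) / max(S.shape[0], 1), 1e-8)
    for _ in range(5):
        try:
            return cho_factor(S + ridge * np.eye(S.shape[0]), lower=True)
        except np.linalg.LinAlgError:
            ridge = base * 1e-10 if ridge == 0.0 else ridge * 100.0
    return None


def _group_moments(model: PathModel, preps: list[_GroupPrep]):
    return [model.implied_moments(p.spec) for p in preps]


def _deviance_terms(moments, preps):
    """Deviance plus per-group moment-space gradients (dD/dmu, dD/dSigma)."""
    total = 0.0
    grads = []
    for (mu, Sig), prep in zip(moments, preps):
        d = Sig.shape[0]
        G = np.zeros((d, d))
        gmu = np.zeros(d)
        for pat in prep.patterns:
            ix = pat.idx
            S_p = Sig[np.ix_(ix, ix)]
            cf = _safe_cholesky(S_p)
            if cf is None:
                return _BIG, None
            logdet = 2.0 * np.log(np.diag(cf[0])).sum()
            diff = pat.ybar - mu[ix]
            Sinv = cho_solve(cf, np.eye(ix.size))
            quad = diff @ Sinv @ diff
            tr = float((Sinv * pat.scatter).sum())
            total += pat.n * (ix.size * _LOG2PI + logdet + quad) + tr
            Sd = Sinv @ diff
            G[np.ix_(ix, ix)] += (
                pat.n * Sinv
                - Sinv @ pat.scatter @ Sinv
                - pat.n * np.outer(Sd, Sd)
            )
            gmu[ix] += -2.0 * pat.n * Sd
        grads.append((gmu, G))
    if not np.isfinite(total):
        return _BIG, None
    return total, grads


def make_objective(model: PathModel, preps: list[_GroupPrep], fd_step: float):
    """Return f(theta) -> (deviance, gradient)."""
    labels = model.free_parameter_vector()
    n_free = len(labels)

    def moments_at(theta):
        model.set_theta(theta)
        try:
            return _group_moments(model, preps)
        except FloatingPointError:
            return None

    def fun(theta):
        moments = moments_at(theta)
        if moments is None:
            return _BIG, np.zeros(n_free)
        dev, grads = _deviance_terms(moments, preps)
        if grads is None:
            # flat penalty plateau: bounds and restarts handle recovery
            return _BIG * (1 + 1e-3 * float(theta @ theta)), np.zeros(n_free)
        grad = np.zeros(n_free)
        for k in range(n_free):
            h = fd_step * max(1.0, abs(theta[k]))
            tp = theta.copy()
            tp[k] += h
            mp = moments_at(tp)
            if mp is None:
                grad[k] = 0.0
                continue
            acc = 0.0
            for (mu, Sig), (mu_p, Sig_p), (gmu, G) in zip(moments, mp, grads):
                acc += gmu @ (mu_p - mu) + float((G * (Sig_p - Sig)).sum())
            grad[k] = acc / h
        return dev, grad

    return fun


def _scaled_start(model: PathModel, data: AnalysisDataset) -> None:
    """Rescale builder start values by the observed sample scale.

    Builder defaults assume roughly unit-variance data; on raw scales the
    optimizer can stall far from the optimum.  Start loadings, residual and
    factor paths, regressions and means are multiplied by the appropriate
    ratio of sample standard deviations (each latent factor inherits the
    scale of the indicator whose loading is fixed).
    """
    p = len(model.observed)
    stacked = np.vstack(
        [gd.data.reshape(-1, p) for gd in data.groups.values()]
    )
    sds = {}
    mus = {}
    for j, v in enumerate(model.observed):
        col = stacked[:, j]
        col = col[~np.isnan(col)]
        sds[v] = float(col.std()) if col.size else 1.0
        mus[v] = float(col.mean()) if col.size else 0.0
        if sds[v] == 0.0:
            sds[v] = 1.0
    anchor = {l: 1.0 for l in model.latents}
    for (o, l), par in model.loadings.items():
        if not par.free:
            anchor[l] = sds[o] / max(abs(par.value), 1e-8)

    def clip(par, value):
        par.value = float(np.clip(value, par.lower, par.upper))

    for (o, l), par in model.loadings.items():
        if par.free:
            clip(par, par.value * sds[o] / anchor[l])
    for (o, s), par in model.residual_paths.items():
        if par.free:
            clip(par, par.value * sds[o])
    for (l, s), par in model.latent_paths.items():
        if par.free:
            clip(par, par.value * anchor[l])
    for (t, s), par in model.regressions.items():
        if par.free:
            clip(par, par.value * anchor[t] / anchor[s])
    for o, par in model.means.items():
        if par.free:
            clip(par, mus[o])


# -------------------------------------------------------------------- fitting
def fit_fiml(
    model: PathModel,
    data: AnalysisDataset,
    options: FitOptions | None = None,
    compute_standardized: bool = True,
) -> FitResult:
    """Fit ``model`` to ``data`` by FIML with multi-start quasi-Newton."""
    opt = options or FitOptions()
    preps = prepare(data, model)
    labels = model.free_parameter_vector()
    if not labels:
        raise FitError("model has no free parameters")
    fun = make_objective(model, preps, opt.fd_step)
    if opt.start == "scaled":
        _scaled_start(model, data)
    theta0 = model.get_theta()
    bounds = model.bounds()
    rng = np.random.default_rng(opt.seed)
    lo = np.array([b[0] for b in bounds])
    hi = np.array([b[1] for b in bounds])

    best = None
    start_devs = []
    for s in range(max(1, opt.n_starts)):
        if s == 0:
            t0 = theta0.copy()
        else:
            t0 = theta0 + opt.jitter * rng.standard_normal(len(theta0))
            t0 = np.clip(t0, np.where(np.isinf(lo), -10, lo + 1e-4),
                         np.where(np.isinf(hi), 10, hi - 1e-4))
        res = optimize.minimize(
            fun,
            t0,
            jac=True,
            method="L-BFGS-B",
            bounds=bounds,
            options={"maxiter": opt.maxiter, "ftol": opt.ftol, "gtol": opt.gtol},
        )
        start_devs.append(float(res.fun))
        if best is None or res.fun < best.fun:
            best = res
    model.set_theta(best.x)
    grad_norm = float(np.max(np.abs(best.jac))) if best.jac is not None else np.nan
    # gradient tolerance scaled by the deviance magnitude: a large absolute
    # gradient on a large deviance can still be a solved problem, but a
    # gradient comparable to the deviance scale is a stall
    converged = (
        bool(best.fun < _BIG / 10)
        and np.isfinite(best.fun)
        and (best.success or grad_norm < 1e-2)
        and grad_norm < 1e-4 * (1.0 + abs(best.fun))
    )
    estimates = dict(zip(labels, (float(v) for v in best.x)))
    result = FitResult(
        estimates=estimates,
        minus2lnL=float(best.fun),
        n_free=len(labels),
        converged=converged,
        grad_norm=grad_norm,
        n_individuals=sum(p.n_individuals for p in preps),
        start_values=list(map(float, theta0)),
        start_deviances=start_devs,
        model_name=model.name,
        variable_order=list(model.observed),
    )
    if compute_standardized:
        std, props = standardize(model)
        result.standardized = std
        result.variance_proportions = props
    return result


def deviance(model: PathModel, data: AnalysisDataset) -> float:
    """-2 lnL at the model's current parameter values."""
    preps = prepare(data, model)
    dev, _ = _deviance_terms(_group_moments(model, preps), preps)
    return float(dev)


# ------------------------------------------------------------- LRT and tests
def likelihood_ratio_test(full: FitResult, nested: FitResult) -> LRTResult:
    """Chi-square difference test; boundary deviances clipped at zero.

    The p-value uses the nominal chi-square reference with df equal to the
    difference in free-parameter counts (no boundary mixture correction).
    """
    extra = set(nested.estimates) - set(full.estimates)
    if extra:
        raise ValueError(f"models not nested by label: extra {sorted(extra)}")
    delta = nested.minus2lnL - full.minus2lnL
    if delta < -1e-4:
        raise ValueError(
            f"nested deviance below full ({delta:.3g}); refit or check nesting"
        )
    df = full.n_free - nested.n_free
    chi = max(0.0, float(delta))
    p = float(stats.chi2.sf(chi, df)) if df > 0 else (1.0 if chi == 0 else 0.0)
    return LRTResult(chi, df, p)


def wald_se(model: PathModel, data: AnalysisDataset, fit: FitResult,
            step: float = 1e-4) -> dict[str, float]:
    """Observed-information standard errors via a finite-difference Hessian."""
    preps = prepare(data, model)
    labels = model.free_parameter_vector()
    theta = np.array([fit.estimates[l] for l in labels])
    fun = make_objective(model, preps, 1e-7)
    n = len(theta)
    H = np.zeros((n, n))
    g0 = fun(theta)[1]
    hs = step * np.maximum(1.0, np.abs(theta))
    for k in range(n):
        tp = theta.copy()
        tp[k] += hs[k]
        H[:, k] = (fun(tp)[1] - g0) / hs[k]
    H = 0.5 * (H + H.T)  # of the deviance: 2 * information
    model.set_theta(theta)
    try:
        cov = np.linalg.inv(H / 2.0)
    except np.linalg.LinAlgError:
        cov = np.linalg.pinv(H / 2.0)
    se = np.sqrt(np.clip(np.diag(cov), 0, None))
    return dict(zip(labels, map(float, se)))


# ------------------------------------------------------------------ profiling
def profile_ci(
    model: PathModel,
    data: AnalysisDataset,
    fit: FitResult,
    label: str,
    level: float = 0.95,
    max_expand: int = 30,
) -> tuple[float, float, str]:
    """Likelihood-based confidence interval for one free parameter.

    Bounds solve ``profiled -2lnL = minimum + chi2_1(level)``; the other
    parameters are re-optimized at every probe (warm-started).  A bound that
    runs into the parameter-space boundary is reported at the boundary and
    flagged one-sided.
    """
    crit = float(stats.chi2.ppf(level, 1))
    target = fit.minus2lnL + crit
    param = model.parameters[label]
    if not param.free:
        raise ValueError(f"{label} is not free")
    labels = model.free_parameter_vector()
    mle = dict(fit.estimates)

    def profiled(value: float) -> float:
        for lab in labels:
            model.parameters[lab].value = mle[lab]
        param.value = float(value)
        param.free = False
        try:
            sub = fit_fiml(
                model, data,
                FitOptions(n_starts=1, gtol=1e-6, maxiter=400),
                compute_standardized=False,
            )
            return sub.minus2lnL
        finally:
            param.free = True

    est = mle[label]
    # crude curvature scale from a one-step probe
    h0 = 0.1 * max(abs(est), 0.1)
    flags = []
    out = []
    for direction in (-1.0, +1.0):
        lo_bound = param.lower if direction < 0 else param.upper
        step_val = est
        prev = est
        found = None
        step = h0
        for _ in range(max_expand):
            step_val = step_val + direction * step
            if (direction < 0 and step_val <= lo_bound) or (
                direction > 0 and step_val >= lo_bound
            ):
                step_val = lo_bound
            dev = profiled(step_val)
            if dev >= target:
                found = (prev, step_val)
                break
            if step_val == lo_bound:
                break
            prev = step_val
            step *= 1.6
        if found is None:
            out.append(float(lo_bound))
            flags.append("boundary" if np.isfinite(lo_bound) else "open")
            continue
        a, b = sorted(found)
        try:
            root = optimize.brentq(lambda v: profiled(v) - target, a, b, xtol=1e-4)
            out.append(float(root))
            flags.append("ok")
        except ValueError:
            out.append(float(b if direction > 0 else a))
            flags.append("bracket-failure")
    # restore MLE
    for lab in labels:
        model.parameters[lab].value = mle[lab]
    flag = "ok" if flags == ["ok", "ok"] else ",".join(flags)
    return out[0], out[1], flag


def bootstrap_ci(
    model: PathModel,
    data: AnalysisDataset,
    fit: FitResult,
    label: str,
    level: float = 0.95,
    n_boot: int = 200,
    seed: int = 0,
) -> tuple[float, float, str]:
    """Percentile interval from resampling families within each group."""
    rng = np.random.default_rng(seed)
    vals = []
    mle = dict(fit.estimates)
    labels = model.free_parameter_vector()
    for _ in range(n_boot):
        groups = {}
        for name, gd in data.groups.items():
            ix = rng.integers(0, gd.n_units, gd.n_units)
            groups[name] = type(gd)(gd.spec, gd.data[ix], [gd.family_ids[i] for i in ix])
        boot = AnalysisDataset(data.variables, groups)
        for lab in labels:
            model.parameters[lab].value = mle[lab]
        try:
            sub = fit_fiml(model, boot, FitOptions(n_starts=1),
                           compute_standardized=False)
            vals.append(sub.estimates[label])
        except FitError:
            continue
    for lab in labels:
        model.parameters[lab].value = mle[lab]
    alpha = (1 - level) / 2
    lo, hi = np.quantile(vals, [alpha, 1 - alpha])
    return float(lo), float(hi), f"bootstrap({len(vals)})"


# -------------------------------------------------------------- standardizing
def standardize(model: PathModel):
    """Standardized parameter table and per-variable variance proportions.

    Path coefficients are rescaled by SD(origin)/SD(target) at the current
    estimates; sources have unit variance by construction.  Variance
    proportions split each observed and latent variance into A / C / E /
    polygenic-score parts, which sum to one exactly.
    """
    _, T_lat, Phi = model.total_effects()
    lat_cov = T_lat @ Phi @ T_lat.T
    obs_mu, obs_cov = model.implied_moments(GroupSpec.singleton())
    sd = {}
    for i, v in enumerate(model.latents):
        sd[v] = math.sqrt(max(lat_cov[i, i], 0.0))
    for i, v in enumerate(model.observed):
        sd[v] = math.sqrt(max(obs_cov[i, i], 0.0))

    def ratio(num: float, den: float, label: str) -> float:
        if den == 0.0:
            raise FitError(f"standardization failed: zero variance at {label}")
        return num / den

    rows = []
    seen = set()

    def emit(label, kind, raw, std):
        if label in seen:
            return
        seen.add(label)
        p = model.parameters[label]
        rows.append(
            {"label": label, "type": kind, "free": p.free,
             "raw": raw, "standardized": std}
        )

    for (o, l), p in model.loadings.items():
        emit(p.label, "loading", p.value, p.value * ratio(sd[l], sd[o], o))
    for (t, s), p in model.regressions.items():
        emit(p.label, "regression", p.value, p.value * ratio(sd[s], sd[t], t))
    for (l, s), p in model.latent_paths.items():
        emit(p.label, "latent_path", p.value, ratio(p.value, sd[l], l))
    for (o, s), p in model.residual_paths.items():
        emit(p.label, "residual_path", p.value, ratio(p.value, sd[o], o))
    for pair, p in model.source_corr.items():
        emit(p.label, "correlation", p.value, p.value)
    for g, d in model.cross_overrides.items():
        for pair, p in d.items():
            emit(p.label, f"cross[{g}]", p.value, p.value)
    for o, p in model.means.items():
        emit(p.label, "mean", p.value, p.value)
    std_table = pd.DataFrame(rows)

    comp = model.variance_components()
    prop_rows = []
    for var, parts in comp.items():
        total = sum(parts.values())
        if total <= 0:
            continue
        row = {"variable": var, "total_variance": total}
        for k, v in parts.items():
            row[f"prop_{k}"] = v / total
        prop_rows.append(row)
    props = pd.DataFrame(prop_rows).fillna(0.0)
    return std_table, props
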