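"""Prebuilt model constructors for the MR-DoC twin analysis.

Builders return fully wired :class:`~twinmr.pathmodel.PathModel` objects:

* :func:`build_constrained_correlation_model` — maximum-likelihood factor
  correlations with within-person correlations equated across zygosity and
  member role and symmetric cross-member cross-trait correlations.
* :func:`build_biometric_factor_model` — bivariate common-pathway model with
  a factor-level Cholesky ACE decomposition and equality-constrained
  indicator-specific ACE residuals.
* :func:`build_mrdoc` — the MR-DoC model: a polygenic-score instrument
  factor with instrumental path ``b1``, a unidirectional causal path ``g1``,
  a pleiotropic path ``b2``, and correlated factor-level A/C residuals
  (``r_a``, ``r_c``); identified by fixing the E correlation ``r_e`` to 0.
* :func:`build_phenotypic_mr` — the same instrument/exposure/outcome chain
  without twin structure or residual exposure-outcome covariance.
* :func:`decompose_correlation` — splits the implied exposure-outcome factor
  correlation into causal (``g1``), pleiotropic (``b1*b2``) and residual
  genetic (``af1*r_a*af2``) contributions, all standardized.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .params import Parameter, fixed, free
from .pathmodel import GroupSpec, PathModel, StructureError

_EQUAL_SPLIT = math.sqrt(1.0 / 3.0)


@dataclass(frozen=True)
class Factor:
    name: str
    indicators: tuple[str, ...]

    def __post_init__(self):
        if not self.indicators:
            raise StructureError(f"factor {self.name} needs >= 1 indicator")


# Study factor definitions: same-sex attraction (SSA), psychological
# distress (PD), risky sexual behavior (RSB) and their polygenic-score
# instrument factors.
SSA = Factor("SSA", ("ssi", "ssp"))
PD = Factor("PD", ("dep", "anx"))
RSB = Factor("RSB", ("rsb",))
PS_SSA = Factor("PS_SSA", ("ps_ssi", "ps_ssp"))
PS_PD = Factor("PS_PD", ("ps_dep", "ps_anx"))
PS_RSB = Factor("PS_RSB", ("ps_nsp", "ps_risk"))


@dataclass(frozen=True)
class MrdocSpec:
    """Configuration of one MR-DoC model.

    ``direction="forward"`` sends the causal path exposure -> outcome with
    the instrument attached to the exposure; ``"reverse"`` swaps the roles
    (the outcome factor receives the instrumental path and emits the causal
    path), in which case ``instrument`` must instrument the outcome trait.
    """

    instrument: Factor
    exposure: Factor
    outcome: Factor
    direction: str = "forward"
    include_pleiotropy: bool = True
    drop_re: bool = True
    ae_only: bool = True
    allow_unidentified: bool = False

    def __post_init__(self):
        if self.direction not in ("forward", "reverse"):
            raise StructureError(f"unknown direction {self.direction!r}")
        overlap = set(self.exposure.indicators) & set(self.outcome.indicators)
        if overlap:
            raise StructureError(f"indicator assigned to two factors: {overlap}")


def _add_measurement(
    model: PathModel,
    factor: Factor,
    free_means: bool,
    loading_start: float = 0.8,
) -> None:
    """First loading fixed to 1, the rest free; free means per indicator."""
    for j, ind in enumerate(factor.indicators):
        if j == 0:
            model.set_loading(ind, factor.name, fixed(f"l_{ind}", 1.0, role="loading"))
        else:
            model.set_loading(
                ind, factor.name,
                free(f"l_{ind}", loading_start, lower=-10, upper=10, role="loading"),
            )
        if free_means:
            model.set_mean(ind, free(f"mu_{ind}", 0.0, role="mean"))


def _add_specifics(model: PathModel, factor: Factor, components: str) -> None:
    """Indicator-specific ACE residuals, equality-constrained per factor.

    Single-indicator factors get no residual (variance fixed to 0 to
    identify the measurement model).
    """
    if len(factor.indicators) < 2:
        return
    coeffs = {
        c: free(f"{c}s_{factor.name}", 0.45 if c != "c" else 0.2,
                lower=0.0, upper=10.0, role="path")
        for c in components
    }
    for i, ind in enumerate(factor.indicators):
        for c in components:
            src = model.add_source(f"{c.upper()}s_{ind}", c.upper())
            model.set_residual_path(ind, src, coeffs[c])


def _add_factor_ace(
    model: PathModel, factor: Factor, tag: int, components: str
) -> dict[str, str]:
    """Factor-level A/C/E sources with path coefficients af/cf/ef."""
    start = {"a": 0.55, "c": 0.3, "e": 0.55}
    srcs = {}
    for c in components:
        src = model.add_source(f"{c.upper()}f{tag}", c.upper())
        model.set_latent_path(
            factor.name, src,
            free(f"{c}f{tag}", start[c], lower=0.0, upper=10.0, role="path"),
        )
        srcs[c] = src
    return srcs


def _add_instrument(
    model: PathModel, instrument: Factor, free_means: bool
) -> None:
    """Polygenic-score factor: scale free, loadings per measurement rules,
    residual variances free and unequal (E-kind: uncorrelated across
    members; real scores are identical in MZ twins, but the factor carries
    all the shared genetic signal)."""
    model.set_latent_path(
        instrument.name,
        model.add_source("uP", "PS"),
        free("sdP", 0.9, lower=1e-4, upper=10.0, role="variance"),
    )
    _add_measurement(model, instrument, free_means, loading_start=0.9)
    for ind in instrument.indicators:
        src = model.add_source(f"Eres_{ind}", "E")
        model.set_residual_path(
            ind, src, free(f"es_{ind}", 0.3, lower=0.0, upper=10.0, role="path")
        )


DEFAULT_GROUPS = [GroupSpec.mz_pair(), GroupSpec.dz_pair()]


def build_mrdoc(spec: MrdocSpec, free_means: bool = True,
                check_identification: bool = True) -> PathModel:
    """Construct an MR-DoC model from its specification.

    Raises :class:`StructureError` with the identification report when the
    requested configuration is locally unidentified (both ``r_e`` and the
    pleiotropic path free), unless ``spec.allow_unidentified``.
    """
    if spec.direction == "forward":
        cause, effect = spec.exposure, spec.outcome
    else:
        cause, effect = spec.outcome, spec.exposure
    name = f"mrdoc_{spec.direction}_{cause.name}_to_{effect.name}"
    observed = [*spec.instrument.indicators, *cause.indicators, *effect.indicators]
    model = PathModel(name, observed, [spec.instrument.name, cause.name, effect.name])
    components = "ae" if spec.ae_only else "ace"

    _add_instrument(model, spec.instrument, free_means)
    _add_measurement(model, cause, free_means)
    _add_measurement(model, effect, free_means)
    _add_specifics(model, cause, components)
    _add_specifics(model, effect, components)
    f1 = _add_factor_ace(model, cause, 1, components)
    f2 = _add_factor_ace(model, effect, 2, components)

    model.set_regression(
        cause.name, spec.instrument.name,
        free("b1", 0.1, lower=-10, upper=10, role="regression"),
    )
    model.set_regression(
        effect.name, cause.name, free("g1", 0.1, lower=-10, upper=10, role="regression")
    )
    if spec.include_pleiotropy:
        model.set_regression(
            effect.name, spec.instrument.name,
            free("b2", 0.05, lower=-10, upper=10, role="regression"),
        )
    model.set_source_corr(
        f1["a"], f2["a"], free("r_a", 0.2, lower=-1, upper=1, role="correlation")
    )
    if "c" in components:
        model.set_source_corr(
            f1["c"], f2["c"], free("r_c", 0.2, lower=-1, upper=1, role="correlation")
        )
    re_param = (
        fixed("r_e", 0.0, role="correlation")
        if spec.drop_re
        else free("r_e", 0.2, lower=-1, upper=1, role="correlation")
    )
    model.set_source_corr(f1["e"], f2["e"], re_param)

    model.groups = list(DEFAULT_GROUPS)
    model.meta = {
        "g1": "g1", "b1": "b1", "r_a": "r_a",
        "af1": "af1", "af2": "af2", "ef1": "ef1", "ef2": "ef2",
        "cause": cause.name, "effect": effect.name,
        "instrument": spec.instrument.name,
    }
    if spec.include_pleiotropy:
        model.meta["b2"] = "b2"
    if "c" in components:
        model.meta["r_c"] = "r_c"
    if not spec.drop_re:
        model.meta["r_e"] = "r_e"

    if check_identification and not spec.allow_unidentified:
        report = model.check_identification(DEFAULT_GROUPS)
        if not report.identified:
            raise StructureError(
                f"{name} is locally unidentified:\n{report.summary()}"
            )
    return model


def build_bidirectional_mrdoc(
    exposure: Factor,
    outcome: Factor,
    instrument_exposure: Factor,
    instrument_outcome: Factor,
    free_means: bool = True,
) -> PathModel:
    """Experimental: both causal paths and both instruments in one model.

    The latent system is cyclic (g1: exposure -> outcome and g2: outcome ->
    exposure, solved through the reduced form), each trait instrumented by
    its own polygenic-score factor, AE factor structure, r_e fixed at 0 and
    no pleiotropic paths.  Excluded from pipeline defaults: with unbalanced
    pleiotropy between the instruments the causal estimates are unstable.
    """
    name = f"mrdoc_bidirectional_{exposure.name}_{outcome.name}"
    observed = [
        *instrument_exposure.indicators,
        *instrument_outcome.indicators,
        *exposure.indicators,
        *outcome.indicators,
    ]
    latents = [instrument_exposure.name, instrument_outcome.name,
               exposure.name, outcome.name]
    model = PathModel(name, observed, latents)
    for instr, tag in ((instrument_exposure, "P1"), (instrument_outcome, "P2")):
        model.set_latent_path(
            instr.name,
            model.add_source(f"u{tag}", "PS"),
            free(f"sd{tag}", 0.9, lower=1e-4, upper=10.0, role="variance"),
        )
        _add_measurement(model, instr, free_means, loading_start=0.9)
        for ind in instr.indicators:
            src = model.add_source(f"Eres_{ind}", "E")
            model.set_residual_path(
                ind, src, free(f"es_{ind}", 0.3, lower=0.0, upper=10.0,
                               role="path"),
            )
    _add_measurement(model, exposure, free_means)
    _add_measurement(model, outcome, free_means)
    _add_specifics(model, exposure, "ae")
    _add_specifics(model, outcome, "ae")
    f1 = _add_factor_ace(model, exposure, 1, "ae")
    f2 = _add_factor_ace(model, outcome, 2, "ae")
    model.set_regression(
        exposure.name, instrument_exposure.name,
        free("b1_fwd", 0.1, lower=-10, upper=10, role="regression"),
    )
    model.set_regression(
        outcome.name, instrument_outcome.name,
        free("b1_rev", 0.1, lower=-10, upper=10, role="regression"),
    )
    model.set_regression(
        outcome.name, exposure.name,
        free("g1", 0.1, lower=-0.95, upper=0.95, role="regression"),
    )
    model.set_regression(
        exposure.name, outcome.name,
        free("g2", 0.1, lower=-0.95, upper=0.95, role="regression"),
    )
    model.set_source_corr(
        f1["a"], f2["a"], free("r_a", 0.2, lower=-1, upper=1, role="correlation")
    )
    model.set_source_corr(f1["e"], f2["e"], fixed("r_e", 0.0, role="correlation"))
    model.groups = list(DEFAULT_GROUPS)
    model.meta = {"g1": "g1", "g2": "g2", "cause": exposure.name,
                  "effect": outcome.name}
    return model


def build_phenotypic_mr(spec: MrdocSpec, free_means: bool = True) -> PathModel:
    """Standard MR chain (instrument -> exposure -> outcome) on individuals.

    No twin structure and no residual exposure-outcome covariance (which
    would render the model unidentified alongside the pleiotropic path).
    """
    if spec.direction == "forward":
        cause, effect = spec.exposure, spec.outcome
    else:
        cause, effect = spec.outcome, spec.exposure
    name = f"phenotypic_mr_{cause.name}_to_{effect.name}"
    observed = [*spec.instrument.indicators, *cause.indicators, *effect.indicators]
    model = PathModel(name, observed, [spec.instrument.name, cause.name, effect.name])

    _add_instrument(model, spec.instrument, free_means)
    _add_measurement(model, cause, free_means)
    _add_measurement(model, effect, free_means)
    for fct, tag in ((cause, 1), (effect, 2)):
        src = model.add_source(f"res{tag}", "E")
        model.set_latent_path(
            fct.name, src, free(f"rv{tag}", 0.8, lower=1e-4, upper=10, role="variance")
        )
        if len(fct.indicators) >= 2:
            for ind in fct.indicators:
                isrc = model.add_source(f"Ures_{ind}", "E")
                model.set_residual_path(
                    ind, isrc,
                    free(f"res_{ind}", 0.5, lower=0.0, upper=10.0, role="path"),
                )
    model.set_regression(
        cause.name, spec.instrument.name,
        free("b1", 0.1, lower=-10, upper=10, role="regression"),
    )
    model.set_regression(
        effect.name, cause.name, free("g1", 0.1, lower=-10, upper=10, role="regression")
    )
    if spec.include_pleiotropy:
        model.set_regression(
            effect.name, spec.instrument.name,
            free("b2", 0.05, lower=-10, upper=10, role="regression"),
        )
    model.groups = [GroupSpec.singleton()]
    model.meta = {
        "g1": "g1", "b1": "b1",
        "cause": cause.name, "effect": effect.name,
        "instrument": spec.instrument.name,
    }
    if spec.include_pleiotropy:
        model.meta["b2"] = "b2"
    return model


def build_biometric_factor_model(
    exposure: Factor,
    outcome: Factor,
    drop_c: bool = False,
    free_means: bool = True,
) -> PathModel:
    """Bivariate common-pathway model with a factor-level ACE Cholesky.

    Polygenic scores never enter: their variance is wholly genetic and has
    no A/C/E decomposition.  For each component X in {A, C, E} the factor
    covariance is X11, X21, X22 (lower-triangular paths), guaranteeing a
    positive semidefinite component covariance.
    """
    name = f"biometric_{exposure.name}_{outcome.name}"
    observed = [*exposure.indicators, *outcome.indicators]
    model = PathModel(name, observed, [exposure.name, outcome.name])
    components = "ae" if drop_c else "ace"
    _add_measurement(model, exposure, free_means)
    _add_measurement(model, outcome, free_means)
    _add_specifics(model, exposure, components)
    _add_specifics(model, outcome, components)
    for c in components:
        K = c.upper()
        s1 = model.add_source(f"{K}1", K)
        s2 = model.add_source(f"{K}2", K)
        start = 0.55 if c != "c" else 0.25
        model.set_latent_path(
            exposure.name, s1, free(f"{c}11", start, lower=0.0, upper=10, role="path")
        )
        model.set_latent_path(
            outcome.name, s1, free(f"{c}21", 0.1, lower=-10, upper=10, role="path")
        )
        model.set_latent_path(
            outcome.name, s2, free(f"{c}22", start, lower=0.0, upper=10, role="path")
        )
    model.groups = list(DEFAULT_GROUPS)
    model.meta = {"exposure": exposure.name, "outcome": outcome.name,
                  "components": components}
    return model


def build_constrained_correlation_model(
    factors: list[Factor],
    instrument: Factor | None = None,
    zygosity_groups: tuple[str, ...] = ("MZ", "DZ"),
    free_means: bool = True,
) -> PathModel:
    """Constrained correlational (correlated-factors) model.

    Factor variances are fixed to 1, so every free factor-factor entry is a
    correlation.  Within-person correlations are shared across zygosity,
    birth order and sibship (one parameter each); cross-member correlations
    are free per zygosity group with cross-trait symmetry imposed; the
    instrument factor's own cross-member correlation is fixed at the
    genetic relatedness (1 MZ / 0.5 DZ-or-sibling).

    Fit this model on pair-extracted data (twin pairs plus singleton
    leftovers); mixed 3-member blocks are not supported here.
    """
    all_factors = ([] if instrument is None else [instrument]) + list(factors)
    seen: set[str] = set()
    for f in all_factors:
        dup = seen & set(f.indicators)
        if dup:
            raise StructureError(f"indicator assigned to two factors: {dup}")
        seen |= set(f.indicators)
    observed = [i for f in all_factors for i in f.indicators]
    model = PathModel("constrained_corr", observed, [f.name for f in all_factors])

    fsrc: dict[str, str] = {}
    for f in all_factors:
        kind = "PS" if instrument is not None and f is instrument else "F"
        src = model.add_source(f"u_{f.name}", kind)
        fsrc[f.name] = src
        model.set_latent_path(f.name, src, fixed(f"scale_{f.name}", 1.0))
        if len(f.indicators) == 1:
            ind = f.indicators[0]
            model.set_loading(ind, f.name, fixed(f"l_{ind}", 1.0, role="loading"))
            if free_means:
                model.set_mean(ind, free(f"mu_{ind}", 0.0, role="mean"))
        else:
            for ind in f.indicators:
                model.set_loading(
                    ind, f.name,
                    free(f"l_{ind}", 0.7, lower=-10, upper=10, role="loading"),
                )
                if free_means:
                    model.set_mean(ind, free(f"mu_{ind}", 0.0, role="mean"))
                src_i = model.add_source(f"res_{ind}", "E")
                model.set_residual_path(
                    ind, src_i,
                    free(f"e_{ind}", 0.6, lower=0.0, upper=10.0, role="path"),
                )

    # within-person factor correlations: equated across members and groups
    names = [f.name for f in all_factors]
    for i, fi in enumerate(names):
        for fj in names[i + 1 :]:
            model.set_source_corr(
                fsrc[fi], fsrc[fj],
                free(f"r_{fi}_{fj}", 0.2, lower=-1, upper=1, role="correlation"),
            )
    # cross-member correlations per zygosity group, symmetric cross-trait
    for g in zygosity_groups:
        for i, fi in enumerate(names):
            for fj in names[i:]:
                if instrument is not None and fi == fj == instrument.name:
                    r = 1.0 if g == "MZ" else 0.5
                    model.set_cross_override(
                        g, fsrc[fi], fsrc[fj],
                        fixed(f"x{g}_{fi}", r, role="correlation"),
                    )
                else:
                    model.set_cross_override(
                        g, fsrc[fi], fsrc[fj],
                        free(f"x{g}_{fi}_{fj}" if fi != fj else f"x{g}_{fi}",
                             0.2, lower=-1, upper=1, role="correlation"),
                    )
    model.groups = [GroupSpec.mz_pair(), GroupSpec.dz_pair(), GroupSpec.singleton()]
    model.meta = {"factors": ",".join(names)}
    return model


def build_saturated(variables: list[str], free_means: bool = True) -> PathModel:
    """Saturated single-group MVN model (free mean, free covariance).

    The covariance is parameterized by its Cholesky factor, so the MLE
    matches the closed-form sample mean and 1/n sample covariance.
    """
    model = PathModel("saturated", list(variables), [])
    srcs = [model.add_source(f"u{i}", "E") for i in range(len(variables))]
    for i, v in enumerate(variables):
        for j in range(i + 1):
            if i == j:
                model.set_residual_path(
                    v, srcs[j], free(f"L_{i}_{j}", 1.0, lower=1e-6, upper=100,
                                     role="variance"),
                )
            else:
                model.set_residual_path(
                    v, srcs[j], free(f"L_{i}_{j}", 0.0, lower=-100, upper=100,
                                     role="path"),
                )
        if free_means:
            model.set_mean(v, free(f"mu_{v}", 0.0, role="mean"))
    model.groups = [GroupSpec.singleton()]
    return model


def build_univariate_ace(var: str = "y", components: str = "ace",
                         free_means: bool = False) -> PathModel:
    """Univariate twin-pair ACE model (handy for calibration studies)."""
    model = PathModel(f"ace_{var}", [var], [])
    start = {"a": 0.65, "c": 0.35, "e": 0.55}
    for c in components:
        src = model.add_source(c.upper(), c.upper())
        model.set_residual_path(
            var, src, free(c, start[c], lower=0.0, upper=10.0, role="path")
        )
    if free_means:
        model.set_mean(var, free(f"mu_{var}", 0.0, role="mean"))
    model.groups = list(DEFAULT_GROUPS)
    return model


# -------------------------------------------------------------- decomposition
@dataclass
class CorrelationDecomposition:
    """Split of the implied exposure-outcome factor correlation.

    ``proportions`` are relative to the implied correlation and sum to 1;
    when a ``reference`` (e.g., the observed phenotypic correlation) is
    supplied, ``share_of_reference`` holds each contribution divided by it,
    matching the convention of reporting the causal share of the observed
    correlation.
    """

    implied_correlation: float
    causal: float
    pleiotropic: float
    residual_genetic: float
    residual_shared_env: float = 0.0
    residual_individual_env: float = 0.0
    reference: float | None = None

    @property
    def contributions(self) -> dict[str, float]:
        return {
            "causal": self.causal,
            "pleiotropic": self.pleiotropic,
            "residual_genetic": self.residual_genetic,
            "residual_shared_env": self.residual_shared_env,
            "residual_individual_env": self.residual_individual_env,
        }

    @property
    def proportions(self) -> dict[str, float]:
        if self.implied_correlation == 0.0:
            raise ZeroDivisionError(
                "implied correlation is zero; proportions undefined"
            )
        r = self.implied_correlation
        return {k: v / r for k, v in self.contributions.items()}

    @property
    def share_of_reference(self) -> dict[str, float]:
        if self.reference is None:
            return self.proportions
        return {k: v / self.reference for k, v in self.contributions.items()}


def decompose_correlation(
    std: dict[str, float],
    reference: float | None = None,
) -> CorrelationDecomposition:
    """Path-tracing decomposition from standardized MR-DoC estimates.

    ``std`` maps standardized parameter names to values: ``g1`` (causal),
    ``b1``/``b2`` (instrumental and pleiotropic), ``af1``/``af2`` and
    ``r_a`` (factor genetic paths and their correlation); ``cf*``/``r_c``
    and ``ef*``/``r_e`` default to 0.  With unit-variance factors the
    implied correlation is the exact sum of the terms.
    """
    g = std.get("g1", 0.0)
    causal = g
    pleio = std.get("b1", 0.0) * std.get("b2", 0.0)
    res_a = std.get("af1", 0.0) * std.get("r_a", 0.0) * std.get("af2", 0.0)
    res_c = std.get("cf1", 0.0) * std.get("r_c", 0.0) * std.get("cf2", 0.0)
    res_e = std.get("ef1", 0.0) * std.get("r_e", 0.0) * std.get("ef2", 0.0)
    implied = causal + pleio + res_a + res_c + res_e
    return CorrelationDecomposition(
        implied_correlation=implied,
        causal=causal,
        pleiotropic=pleio,
        residual_genetic=res_a,
        residual_shared_env=res_c,
        residual_individual_env=res_e,
        reference=reference,
    )


def apply_generating_params(model: PathModel, gp, outcome: str = "PD") -> None:
    """Set an MR-DoC model's parameters to a generator's standardized truth.

    The generator scales factors to unit variance; the model scales each
    factor by fixing its first loading to 1, so paths are rescaled by the
    first-indicator loadings.  Only meaningful for forward models built on
    the same variables the generator emits (and with ``b1_rev = 0``: the
    forward model carries no outcome-side instrument).
    """
    lp = gp.score_loadings
    lx = gp.exposure_loadings
    ly = gp.outcome_loadings if outcome == "PD" else (1.0,)
    vals = {
        "sdP": lp[0],
        "b1": gp.b1 * lx[0] / lp[0],
        "g1": gp.g1 * ly[0] / lx[0],
        "b2": gp.b2 * ly[0] / lp[0],
        "af1": gp.af1 * lx[0],
        "ef1": gp.ef1 * lx[0],
        "cf1": gp.cf1 * lx[0],
        "af2": gp.af2 * ly[0],
        "ef2": gp.ef2 * ly[0],
        "cf2": gp.cf2 * ly[0],
        "r_a": gp.r_a,
        "r_c": gp.r_c,
        "r_e": gp.r_e,
    }
    for j, ind in enumerate(("ps_ssi", "ps_ssp")):
        vals[f"l_{ind}"] = lp[j] / lp[0]
        vals[f"es_{ind}"] = math.sqrt(max(1.0 - lp[j] ** 2, 0.0))
    for j, ind in enumerate(("ssi", "ssp")):
        vals[f"l_{ind}"] = lx[j] / lx[0]
    vals["as_SSA"] = gp.exposure_a_s
    vals["es_SSA"] = gp.indicator_e(lx[0], gp.exposure_a_s, gp.exposure_c_s)
    vals["cs_SSA"] = gp.exposure_c_s
    if outcome == "PD":
        for j, ind in enumerate(("dep", "anx")):
            vals[f"l_{ind}"] = ly[j] / ly[0]
        vals["as_PD"] = gp.outcome_a_s
        vals["es_PD"] = gp.indicator_e(ly[0], gp.outcome_a_s, gp.outcome_c_s)
        vals["cs_PD"] = gp.outcome_c_s
    for label, value in vals.items():
        if label in model.parameters:
            model.parameters[label].value = float(value)


def decompose_fit(fit, model: PathModel,
                  reference: float | None = None) -> CorrelationDecomposition:
    """Decomposition straight from a fitted MR-DoC model's standardized table."""
    table = fit.standardized.set_index("label")["standardized"]
    std = {}
    for key in ("g1", "b1", "b2", "af1", "af2", "r_a", "cf1", "cf2",
                "r_c", "ef1", "ef2", "r_e"):
        label = model.meta.get(key, key)
        if label in table.index:
            std[key] = float(table.loc[label])
    return decompose_correlation(std, reference=reference)
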