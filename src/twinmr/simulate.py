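"""Synthetic twin-family data with MR-DoC structure.

The generator draws, for each family, unit-variance latent sources —
additive-genetic (A) sources correlated across members at the pairwise
genetic relatedness (1 for MZ twins, 0.5 for DZ twins and siblings),
shared-environment (C) sources perfectly shared, individual-environment (E)
sources independent, and wholly genetic polygenic-score instrument sources
correlating like A — and propagates them through the structural equations

.. parsed-literal::

    P1 = u_P1                      (instrument for the exposure factor)
    P2 = u_P2                      (instrument for the outcome factor)
    F1 = b1*P1 + af1*A1 + cf1*C1 + ef1*E1
    F2 = g1*F1 + b2*P1 + b1_rev*P2 + af2*A2 + cf2*C2 + ef2*E2
    indicator = loading*factor + a_s*A_s + c_s*C_s + e_s*E_s
    score     = loading*P + es*E_s

with corr(A1, A2) = r_a, corr(C1, C2) = r_c, corr(E1, E2) = r_e within a
person.  Default parameters are standardized and emulate the study
conditions: a weak instrument (about 1% of exposure variance), causal path
0.13, small pleiotropy, exposure/outcome heritabilities near 0.57/0.43,
residual genetic correlation 0.26, and roughly 37% of individuals
genotyped (scores missing completely at random otherwise).

The propagation here is deliberately written as explicit structural
recursion, independent of the matrix path-tracing in
:mod:`twinmr.pathmodel`, so the two can cross-check each other.
"""
from __future__ import annotations

import math
from dataclasses import dataclass, field, asdict, replace

import numpy as np
import pandas as pd

from .families import FamilyTable


class ConfigError(ValueError):
    pass


@dataclass(frozen=True)
class GeneratingParams:
    """Standardized generating values (all factors scaled to unit variance).

    ``ef1`` and ``ef2`` are not specified: they are solved so that the
    exposure and outcome factors have exactly unit variance.
    """

    b1: float = 0.10        # instrument -> exposure
    g1: float = 0.13        # exposure -> outcome causal path
    b2: float = 0.04        # instrument -> outcome (horizontal pleiotropy)
    b1_rev: float = 0.10    # outcome-side instrument -> outcome
    af1: float = 0.75
    cf1: float = 0.0
    af2: float = 0.63
    cf2: float = 0.0
    r_a: float = 0.26
    r_c: float = 0.0
    r_e: float = 0.0
    exposure_loadings: tuple[float, ...] = (0.75, 0.73)
    exposure_a_s: float = 0.29
    exposure_c_s: float = 0.0
    outcome_loadings: tuple[float, ...] = (0.86, 0.76)
    outcome_a_s: float = 0.24
    outcome_c_s: float = 0.0
    score_loadings: tuple[float, ...] = (0.81, 0.99)

    @property
    def ef1(self) -> float:
        v = 1.0 - self.af1**2 - self.cf1**2 - self.b1**2
        if v <= 0:
            raise ConfigError("exposure-factor variance over-allocated")
        return math.sqrt(v)

    @property
    def ef2(self) -> float:
        # Var(F2) = 1 requires the positive root of
        #   ef2^2 + 2 g1 ef1 r_e ef2 + (rest - 1) = 0
        rest = (
            self.g1**2
            + self.b2**2
            + self.b1_rev**2
            + self.af2**2
            + self.cf2**2
            + 2
            * self.g1
            * (self.b2 * self.b1 + self.af2 * self.af1 * self.r_a
               + self.cf2 * self.cf1 * self.r_c)
        )
        b = 2 * self.g1 * self.ef1 * self.r_e
        disc = b**2 - 4 * (rest - 1.0)
        if disc <= 0:
            raise ConfigError("outcome-factor variance over-allocated")
        ef2 = (-b + math.sqrt(disc)) / 2
        if ef2 <= 0:
            raise ConfigError("outcome-factor variance over-allocated")
        return ef2

    def indicator_e(self, loading: float, a_s: float, c_s: float) -> float:
        v = 1.0 - loading**2 - a_s**2 - c_s**2
        if v <= 0:
            raise ConfigError(f"indicator variance over-allocated (loading {loading})")
        return math.sqrt(v)


@dataclass(frozen=True)
class SimulationConfig:
    """Study-condition knobs for one simulated dataset.

    Default sample sizes are a quarter-scale rendition of the cohort
    composition (about 1000 MZ twins, 1900 DZ twins, 1180 twin-sibling
    individuals).
    """

    n_mz_pairs: int = 500
    n_dz_pairs: int = 950
    n_sib_pairs: int = 590
    n_trios: int = 0
    genotyped_fraction: float = 0.37
    family_level_missingness: bool = False
    params: GeneratingParams = field(default_factory=GeneratingParams)
    outcome: str = "PD"  # "PD" (dep+anx) or "RSB" (single indicator)
    age_beta: float = 0.0
    sex_beta: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_mz_pairs, self.n_dz_pairs, self.n_sib_pairs, self.n_trios) < 0:
            raise ConfigError("family counts must be non-negative")
        if not 0.0 <= self.genotyped_fraction <= 1.0:
            raise ConfigError("genotyped_fraction must be in [0, 1]")
        if self.outcome not in ("PD", "RSB"):
            raise ConfigError(f"unknown outcome {self.outcome!r}")

    @property
    def exposure_vars(self) -> tuple[str, ...]:
        return ("ssi", "ssp")

    @property
    def outcome_vars(self) -> tuple[str, ...]:
        return ("dep", "anx") if self.outcome == "PD" else ("rsb",)

    @property
    def exposure_scores(self) -> tuple[str, ...]:
        return ("ps_ssi", "ps_ssp")

    @property
    def outcome_scores(self) -> tuple[str, ...]:
        return ("ps_dep", "ps_anx") if self.outcome == "PD" else ("ps_nsp", "ps_risk")


# --------------------------------------------------------------------- engine
def _source_layout(cfg: SimulationConfig):
    """Ordered per-member sources: (name, kind)."""
    sources = [
        ("uP1", "PS"),
        ("uP2", "PS"),
        ("A1", "A"),
        ("C1", "C"),
        ("E1", "E"),
        ("A2", "A"),
        ("C2", "C"),
        ("E2", "E"),
    ]
    for i, _ in enumerate(cfg.exposure_vars):
        sources += [(f"xA{i}", "A"), (f"xC{i}", "C"), (f"xE{i}", "E")]
    if cfg.outcome == "PD":
        for i, _ in enumerate(cfg.outcome_vars):
            sources += [(f"yA{i}", "A"), (f"yC{i}", "C"), (f"yE{i}", "E")]
    for i, _ in enumerate(cfg.exposure_scores):
        sources += [(f"sE{i}", "E")]
    for i, _ in enumerate(cfg.outcome_scores):
        sources += [(f"tE{i}", "E")]
    return sources


def _within_phi(cfg: SimulationConfig, sources) -> np.ndarray:
    p = cfg.params
    ix = {n: i for i, (n, _) in enumerate(sources)}
    Phi = np.eye(len(sources))
    for a, b, r in (("A1", "A2", p.r_a), ("C1", "C2", p.r_c), ("E1", "E2", p.r_e)):
        Phi[ix[a], ix[b]] = Phi[ix[b], ix[a]] = r
    return Phi


def _joint_chol(cfg: SimulationConfig, sources, R: np.ndarray) -> np.ndarray:
    """Cholesky of the stacked source covariance for one family type."""
    S = len(sources)
    n = R.shape[0]
    Phi = _within_phi(cfg, sources)
    kinds = [k for _, k in sources]
    big = np.zeros((n * S, n * S))
    for m in range(n):
        for mp in range(n):
            if m == mp:
                block = Phi
            else:
                mult = np.array(
                    [
                        R[m, mp] if k in ("A", "PS") else (1.0 if k == "C" else 0.0)
                        for k in kinds
                    ]
                )
                block = Phi * np.minimum.outer(mult, mult)
                np.fill_diagonal(block, mult * np.diag(Phi))
            big[m * S : (m + 1) * S, mp * S : (mp + 1) * S] = block
    try:
        return np.linalg.cholesky(big + 1e-12 * np.eye(n * S))
    except np.linalg.LinAlgError as exc:
        raise ConfigError("generating latent correlation structure not PSD") from exc


def _propagate(cfg: SimulationConfig, draws: np.ndarray, sources) -> dict[str, np.ndarray]:
    """Map unit sources of one member to observed variables (vectorized)."""
    p = cfg.params
    ix = {n: i for i, (n, _) in enumerate(sources)}
    g = lambda n: draws[:, ix[n]]
    P1, P2 = g("uP1"), g("uP2")
    F1 = p.b1 * P1 + p.af1 * g("A1") + p.cf1 * g("C1") + p.ef1 * g("E1")
    F2 = (
        p.g1 * F1
        + p.b2 * P1
        + p.b1_rev * P2
        + p.af2 * g("A2")
        + p.cf2 * g("C2")
        + p.ef2 * g("E2")
    )
    out: dict[str, np.ndarray] = {}
    # specific residuals are equal (unstandardized) across a factor's
    # indicators; the value makes the *first* indicator exactly unit
    # variance, later indicators sit marginally below 1
    e_x = p.indicator_e(p.exposure_loadings[0], p.exposure_a_s, p.exposure_c_s)
    for i, (var, lam) in enumerate(zip(cfg.exposure_vars, p.exposure_loadings)):
        out[var] = (
            lam * F1
            + p.exposure_a_s * g(f"xA{i}")
            + p.exposure_c_s * g(f"xC{i}")
            + e_x * g(f"xE{i}")
        )
    if cfg.outcome == "PD":
        e_y = p.indicator_e(p.outcome_loadings[0], p.outcome_a_s, p.outcome_c_s)
        for i, (var, lam) in enumerate(zip(cfg.outcome_vars, p.outcome_loadings)):
            out[var] = (
                lam * F2
                + p.outcome_a_s * g(f"yA{i}")
                + p.outcome_c_s * g(f"yC{i}")
                + e_y * g(f"yE{i}")
            )
    else:
        out["rsb"] = F2  # single indicator: loading 1, residual 0
    for i, (var, lam) in enumerate(zip(cfg.exposure_scores, p.score_loadings)):
        out[var] = lam * P1 + math.sqrt(1 - lam**2) * g(f"sE{i}")
    for i, (var, lam) in enumerate(zip(cfg.outcome_scores, p.score_loadings)):
        out[var] = lam * P2 + math.sqrt(1 - lam**2) * g(f"tE{i}")
    return out


_FAMILY_TYPES = {
    # type -> (roles, zygosity, relatedness matrix)
    "mz_pair": (("twin1", "twin2"), "MZ", [[1.0, 1.0], [1.0, 1.0]]),
    "dz_pair": (("twin1", "twin2"), "DZ", [[1.0, 0.5], [0.5, 1.0]]),
    "sib_pair": (("twin1", "sibling"), "DZ", [[1.0, 0.5], [0.5, 1.0]]),
    "mz_trio": (
        ("twin1", "twin2", "sibling"),
        "MZ",
        [[1.0, 1.0, 0.5], [1.0, 1.0, 0.5], [0.5, 0.5, 1.0]],
    ),
    "dz_trio": (
        ("twin1", "twin2", "sibling"),
        "DZ",
        [[1.0, 0.5, 0.5], [0.5, 1.0, 0.5], [0.5, 0.5, 1.0]],
    ),
}


def simulate_families(cfg: SimulationConfig) -> FamilyTable:
    """Draw one family table under the configured generating model."""
    rng = np.random.default_rng(cfg.seed)
    sources = _source_layout(cfg)
    S = len(sources)
    counts = [
        ("mz_pair", cfg.n_mz_pairs),
        ("dz_pair", cfg.n_dz_pairs),
        ("sib_pair", cfg.n_sib_pairs),
        ("mz_trio", cfg.n_trios // 2 + cfg.n_trios % 2),
        ("dz_trio", cfg.n_trios // 2),
    ]
    frames = []
    next_fid = 1
    for ftype, n_fam in counts:
        if n_fam == 0:
            continue
        roles, zyg, R = _FAMILY_TYPES[ftype]
        R = np.asarray(R)
        n_members = len(roles)
        L = _joint_chol(cfg, sources, R)
        z = rng.standard_normal((n_fam, n_members * S)) @ L.T
        fam_age = np.clip(rng.normal(26.0, 4.5, n_fam), 18, 45)
        fids = np.arange(next_fid, next_fid + n_fam)
        next_fid += n_fam
        sex_by_role = {r: rng.binomial(1, 0.35, n_fam) for r in roles}
        if zyg == "MZ" and "twin2" in roles:
            sex_by_role["twin2"] = sex_by_role["twin1"]  # MZ twins same-sex
        for m, role in enumerate(roles):
            draws = z[:, m * S : (m + 1) * S]
            obs = _propagate(cfg, draws, sources)
            sex = sex_by_role[role]
            age = fam_age if role != "sibling" else np.clip(
                fam_age + rng.normal(3.0, 2.0, n_fam), 18, 55
            )
            if cfg.age_beta or cfg.sex_beta:
                shift = cfg.age_beta * (age - 26.0) / 4.5 + cfg.sex_beta * sex
                for var in (*cfg.exposure_vars, *cfg.outcome_vars):
                    obs[var] = obs[var] + shift
            frames.append(
                pd.DataFrame(
                    {
                        "family_id": fids,
                        "member_role": role,
                        "zygosity": zyg if role != "sibling" else pd.NA,
                        "sex": sex,
                        "age": np.round(age, 1),
                        **{k: obs[k] for k in (*cfg.exposure_vars, *cfg.outcome_vars)},
                        **{k: obs[k] for k in (*cfg.exposure_scores, *cfg.outcome_scores)},
                    }
                )
            )
    df = pd.concat(frames, ignore_index=True)
    df = df.sort_values(["family_id", "member_role"], kind="stable").reset_index(drop=True)
    # MCAR genotyping mask
    score_cols = [*cfg.exposure_scores, *cfg.outcome_scores]
    if cfg.family_level_missingness:
        fams = df["family_id"].unique()
        geno_fam = set(fams[rng.random(fams.size) < cfg.genotyped_fraction])
        genotyped = df["family_id"].isin(geno_fam).to_numpy()
    else:
        genotyped = rng.random(len(df)) < cfg.genotyped_fraction
    df.loc[~genotyped, score_cols] = np.nan
    return FamilyTable(
        df,
        phenotypes=(*cfg.exposure_vars, *cfg.outcome_vars),
        scores=tuple(score_cols),
    )


def likertize(values: np.ndarray, thresholds) -> np.ndarray:
    """Bin continuous values into ordinal categories by interval membership.

    ``thresholds`` must be strictly increasing; an empty list yields a
    single category 0.  Category frequencies are controlled by placing the
    thresholds at normal quantiles of the latent scale.
    """
    th = np.asarray(list(thresholds), dtype=float)
    if th.size and (np.diff(th) <= 0).any():
        raise ConfigError("thresholds must be strictly increasing")
    return np.digitize(np.asarray(values, dtype=float), th)


SCENARIOS = {
    "paper_like": {},
    "null_g1": {"g1": 0.0},
    "confounded": {"g1": 0.13, "r_a": 0.5, "b2": 0.0},
    "pleiotropic": {"g1": 0.0, "b2": 0.2},
}


def scenario_params(scenario: str, base: GeneratingParams | None = None) -> GeneratingParams:
    if scenario not in SCENARIOS:
        raise ConfigError(f"unknown scenario {scenario!r}")
    return replace(base or GeneratingParams(), **SCENARIOS[scenario])


def simulate_replicates(
    cfg: SimulationConfig, reps: int, scenario: str = "paper_like"
):
    """Yield ``(FamilyTable, manifest)`` for seeded independent replicates.

    Replicate ``i`` uses the seed sequence ``(cfg.seed, i)``; adding more
    replicates never changes earlier ones.
    """
    if reps < 1:
        raise ConfigError("reps must be >= 1")
    params = scenario_params(scenario, cfg.params)
    for i in range(reps):
        rng_seed = int(
            np.random.SeedSequence([int(cfg.seed), i]).generate_state(1)[0] % (2**31)
        )
        rep_cfg = replace(cfg, params=params, seed=rng_seed)
        manifest = {
            "scenario": scenario,
            "replicate": i,
            "seed": rng_seed,
            "generating_parameters": asdict(params),
            "standardized": {
                "g1": params.g1,
                "b1": params.b1,
                "b2": params.b2,
                "af1": params.af1,
                "af2": params.af2,
                "r_a": params.r_a,
                "ef1": params.ef1,
                "ef2": params.ef2,
            },
        }
        yield simulate_families(rep_cfg), manifest
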