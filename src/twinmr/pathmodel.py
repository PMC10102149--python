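"""Structural path models over family-structured (multi-member) data.

A :class:`PathModel` is a latent-variable system

.. math::

    \\eta = B \\eta + \\Gamma u, \\qquad y = \\Lambda \\eta + K s + \\mu,

where the exogenous *sources* ``u`` (factor-level) and ``s``
(variable-specific) have unit variance and correlation matrix ``Phi``.
Every source carries a *kind* tag that determines how it correlates across
the members of a family:

========  =====================================  =======================
kind      meaning                                cross-member multiplier
========  =====================================  =======================
``A``     additive genetic                       genetic relatedness r
``C``     shared environment                     1
``E``     individual-specific environment        0
``PS``    polygenic-score (wholly genetic)       genetic relatedness r
``F``     generic factor (correlational models)  0 unless overridden
========  =====================================  =======================

The within-member covariance is ``T Phi T'`` with total-effect matrix
``T = Lambda (I-B)^{-1} Gamma  |  K``; the cross-member block between
members m and m' multiplies each ``Phi`` entry by the kind multiplier at
relatedness ``R[m, m']``.  MZ pairs have r = 1, DZ and twin-sibling pairs
r = 0.5; mixed 3-member blocks (a twin pair plus a sibling) use the full
pairwise relatedness matrix.  Group-specific free cross-member
correlations (the constrained correlational models) are expressed as
per-group overrides of individual source cross-covariances.
"""
from __future__ import annotations

import json
import math
from dataclasses import dataclass, field

import numpy as np

from .params import ConstraintError, Parameter, ParameterSet

KINDS = ("A", "C", "E", "PS", "F")

#: Generic interior evaluation point per parameter role, used by the local
#: identification check (identification is a generic property; special points
#: such as 0 can hide or create rank deficiencies).
GENERIC_POINT = {
    "loading": 0.8,
    "regression": 0.2,
    "correlation": 0.2,
    "path": 0.6,
    "variance": 0.6,
    "mean": 0.1,
}


class StructureError(ValueError):
    """Model wiring is invalid (cycles, unknown variables, bad kinds)."""


@dataclass(frozen=True)
class GroupSpec:
    """A relatedness class: how many members and how they are related.

    ``relatedness`` is the pairwise genetic-relatedness matrix (diagonal 1);
    shared environment correlates at 1 and individual environment at 0 for
    every pair regardless of zygosity.
    """

    name: str
    relatedness: tuple[tuple[float, ...], ...]

    @property
    def n_members(self) -> int:
        return len(self.relatedness)

    @property
    def R(self) -> np.ndarray:
        return np.asarray(self.relatedness, dtype=float)

    @staticmethod
    def mz_pair() -> "GroupSpec":
        return GroupSpec("MZ", ((1.0, 1.0), (1.0, 1.0)))

    @staticmethod
    def dz_pair() -> "GroupSpec":
        """DZ twin or twin-sibling pair (both share genes at 0.5)."""
        return GroupSpec("DZ", ((1.0, 0.5), (0.5, 1.0)))

    @staticmethod
    def mz_trio() -> "GroupSpec":
        return GroupSpec(
            "trioMZ",
            ((1.0, 1.0, 0.5), (1.0, 1.0, 0.5), (0.5, 0.5, 1.0)),
        )

    @staticmethod
    def dz_trio() -> "GroupSpec":
        return GroupSpec(
            "trioDZ",
            ((1.0, 0.5, 0.5), (0.5, 1.0, 0.5), (0.5, 0.5, 1.0)),
        )

    @staticmethod
    def singleton() -> "GroupSpec":
        return GroupSpec("singleton", ((1.0,),))


def _kind_multiplier(kind: str, r: float) -> float:
    if kind in ("A", "PS"):
        return r
    if kind == "C":
        return 1.0
    return 0.0  # E and F


@dataclass
class IdentificationReport:
    rank: int
    n_free: int
    free_labels: list[str]
    singular_values: np.ndarray
    null_space: np.ndarray  # (n_free, n_deficient)

    @property
    def identified(self) -> bool:
        return self.rank == self.n_free

    def deficient_labels(self, threshold: float = 0.1) -> list[str]:
        """Labels with non-trivial weight in some null-space direction."""
        if self.null_space.shape[1] == 0:
            return []
        weight = np.abs(self.null_space).max(axis=1)
        return [
            lab
            for lab, w in zip(self.free_labels, weight)
            if w > threshold * weight.max()
        ]

    def summary(self) -> str:
        lines = [
            f"free parameters : {self.n_free}",
            f"jacobian rank   : {self.rank}",
            f"identified      : {self.identified}",
        ]
        if not self.identified:
            lines.append("non-identified  : " + ", ".join(self.deficient_labels()))
        return "\n".join(lines)


class PathModel:
    """Sparse structural model; see module docstring for the algebra."""

    def __init__(self, name: str, observed: list[str], latents: list[str]):
        self.name = name
        self.observed = list(observed)
        self.latents = list(latents)
        self.sources: list[tuple[str, str]] = []  # (name, kind)
        self.loadings: dict[tuple[str, str], Parameter] = {}
        self.regressions: dict[tuple[str, str], Parameter] = {}  # (target, source)
        self.latent_paths: dict[tuple[str, str], Parameter] = {}  # (latent, source)
        self.residual_paths: dict[tuple[str, str], Parameter] = {}  # (obs, source)
        self.source_corr: dict[tuple[str, str], Parameter] = {}  # off-diagonal Phi
        self.means: dict[str, Parameter] = {}
        # group name -> {(source, source): Parameter} cross-member covariance
        self.cross_overrides: dict[str, dict[tuple[str, str], Parameter]] = {}
        self.groups: list[GroupSpec] = []
        self.meta: dict[str, str] = {}  # semantic role -> parameter label
        self._registry = ParameterSet()

    # ------------------------------------------------------------------ build
    def add_source(self, name: str, kind: str) -> str:
        if kind not in KINDS:
            raise StructureError(f"unknown source kind {kind!r}")
        if any(s == name for s, _ in self.sources):
            raise StructureError(f"duplicate source {name!r}")
        self.sources.append((name, kind))
        return name

    def _register(self, param: Parameter) -> Parameter:
        return self._registry.add(param)

    def set_loading(self, obs: str, latent: str, param: Parameter) -> None:
        self._check(obs in self.observed, f"unknown observed {obs!r}")
        self._check(latent in self.latents, f"unknown latent {latent!r}")
        self.loadings[(obs, latent)] = self._register(param)

    def set_regression(self, target: str, source: str, param: Parameter) -> None:
        self._check(target in self.latents and source in self.latents, "latents only")
        self.regressions[(target, source)] = self._register(param)

    def set_latent_path(self, latent: str, source: str, param: Parameter) -> None:
        self._check(latent in self.latents, f"unknown latent {latent!r}")
        self._check_source(source)
        self.latent_paths[(latent, source)] = self._register(param)

    def set_residual_path(self, obs: str, source: str, param: Parameter) -> None:
        self._check(obs in self.observed, f"unknown observed {obs!r}")
        self._check_source(source)
        self.residual_paths[(obs, source)] = self._register(param)

    def set_source_corr(self, s1: str, s2: str, param: Parameter) -> None:
        self._check_source(s1)
        self._check_source(s2)
        self._check(s1 != s2, "diagonal of Phi is fixed at 1")
        self.source_corr[tuple(sorted((s1, s2)))] = self._register(param)

    def set_mean(self, obs: str, param: Parameter) -> None:
        self._check(obs in self.observed, f"unknown observed {obs!r}")
        self.means[obs] = self._register(param)

    def set_cross_override(
        self, group: str, s1: str, s2: str, param: Parameter
    ) -> None:
        self._check_source(s1)
        self._check_source(s2)
        self.cross_overrides.setdefault(group, {})[
            tuple(sorted((s1, s2)))
        ] = self._register(param)

    def _check(self, cond: bool, msg: str) -> None:
        if not cond:
            raise StructureError(f"{self.name}: {msg}")

    def _check_source(self, s: str) -> None:
        self._check(any(n == s for n, _ in self.sources), f"unknown source {s!r}")

    # ------------------------------------------------------------- parameters
    @property
    def parameters(self) -> ParameterSet:
        return self._registry

    def free_parameter_vector(self) -> list[str]:
        """Free labels in insertion order, deduplicated by label."""
        return self._registry.free_labels()

    def get_theta(self) -> np.ndarray:
        return np.array(
            [self._registry[lab].value for lab in self.free_parameter_vector()]
        )

    def set_theta(self, theta: np.ndarray) -> None:
        labels = self.free_parameter_vector()
        if len(theta) != len(labels):
            raise ValueError("theta length mismatch")
        for lab, val in zip(labels, theta):
            self._registry[lab].value = float(val)

    def bounds(self) -> list[tuple[float, float]]:
        return [
            (self._registry[lab].lower, self._registry[lab].upper)
            for lab in self.free_parameter_vector()
        ]

    # ---------------------------------------------------------------- algebra
    def _indices(self):
        obs_ix = {v: i for i, v in enumerate(self.observed)}
        lat_ix = {v: i for i, v in enumerate(self.latents)}
        src_ix = {s: i for i, (s, _) in enumerate(self.sources)}
        return obs_ix, lat_ix, src_ix

    def _matrices(self):
        """Dense (Lambda, B, Gamma, K, Phi, mu) at current parameter values."""
        obs_ix, lat_ix, src_ix = self._indices()
        p, L, S = len(self.observed), len(self.latents), len(self.sources)
        Lam = np.zeros((p, L))
        B = np.zeros((L, L))
        Gam = np.zeros((L, S))
        K = np.zeros((p, S))
        Phi = np.eye(S)
        mu = np.zeros(p)
        for (o, l), pm in self.loadings.items():
            Lam[obs_ix[o], lat_ix[l]] = pm.value
        for (t, s), pm in self.regressions.items():
            B[lat_ix[t], lat_ix[s]] = pm.value
        for (l, s), pm in self.latent_paths.items():
            Gam[lat_ix[l], src_ix[s]] = pm.value
        for (o, s), pm in self.residual_paths.items():
            K[obs_ix[o], src_ix[s]] = pm.value
        for (s1, s2), pm in self.source_corr.items():
            Phi[src_ix[s1], src_ix[s2]] = pm.value
            Phi[src_ix[s2], src_ix[s1]] = pm.value
        for o, pm in self.means.items():
            mu[obs_ix[o]] = pm.value
        return Lam, B, Gam, K, Phi, mu

    def total_effects(self):
        """(T_obs, T_lat, Phi): observed- and latent-level source effects."""
        Lam, B, Gam, K, Phi, _ = self._matrices()
        if not np.isfinite(B).all():
            raise FloatingPointError("non-finite regression coefficient")
        IB = np.eye(B.shape[0]) - B
        # acyclicity => (I - B) invertible with determinant 1 for triangular
        # orderings; a genuinely cyclic wiring shows up as near-singularity.
        if abs(np.linalg.det(IB)) < 1e-12:
            raise StructureError(f"{self.name}: cyclic latent regression")
        T_lat = np.linalg.solve(IB, Gam)
        T_obs = Lam @ T_lat + K
        return T_obs, T_lat, Phi

    def _cross_source_cov(self, Phi: np.ndarray, group: GroupSpec, r: float):
        """Cross-member source covariance at pairwise relatedness r."""
        kinds = [k for _, k in self.sources]
        mult = np.array([_kind_multiplier(k, r) for k in kinds])
        # same-kind sources scale by the kind multiplier; Phi is zero across
        # kinds by construction, so the outer minimum is never exercised.
        M = np.minimum.outer(mult, mult)
        np.fill_diagonal(M, mult)
        C = Phi * M
        overrides = self.cross_overrides.get(group.name, {})
        if overrides:
            _, _, src_ix = self._indices()
            for (s1, s2), pm in overrides.items():
                i, j = src_ix[s1], src_ix[s2]
                C[i, j] = pm.value
                C[j, i] = pm.value
        return C

    def implied_moments(self, group: GroupSpec):
        """Stacked implied mean vector and covariance for one group.

        Variable order is member-major: all observed variables of member 1,
        then member 2, ...  Returns ``(mu, Sigma)`` with shapes
        ``(n*p,)`` and ``(n*p, n*p)``.
        """
        T, _, Phi = self.total_effects()
        if not np.isfinite(T).all() or not np.isfinite(Phi).all():
            raise FloatingPointError("non-finite parameter in implied moments")
        p = len(self.observed)
        n = group.n_members
        R = group.R
        Sigma = np.zeros((n * p, n * p))
        within = T @ Phi @ T.T
        for m in range(n):
            Sigma[m * p : (m + 1) * p, m * p : (m + 1) * p] = within
            for mp in range(m + 1, n):
                C = self._cross_source_cov(Phi, group, R[m, mp])
                block = T @ C @ T.T
                Sigma[m * p : (m + 1) * p, mp * p : (mp + 1) * p] = block
                Sigma[mp * p : (mp + 1) * p, m * p : (m + 1) * p] = block.T
        _, _, _, _, _, mu1 = self._matrices()
        mu = np.tile(mu1, n)
        return mu, Sigma

    def latent_moments(self):
        """Within-member latent covariance (latents x latents)."""
        _, T_lat, Phi = self.total_effects()
        return T_lat @ Phi @ T_lat.T

    # ----------------------------------------------------- variance by source
    def variance_components(self):
        """Within-member variance of each observed/latent split by kind.

        Returns a dict ``{variable: {kind: variance}}``; kinds are
        independent of each other, so the per-kind entries sum exactly to the
        total implied variance.
        """
        T_obs, T_lat, Phi = self.total_effects()
        kinds = np.array([k for _, k in self.sources])
        out: dict[str, dict[str, float]] = {}
        for names, T in ((self.observed, T_obs), (self.latents, T_lat)):
            for i, v in enumerate(names):
                row = {}
                for k in KINDS:
                    sel = kinds == k
                    if not sel.any():
                        continue
                    t = T[i, sel]
                    row[k] = float(t @ Phi[np.ix_(sel, sel)] @ t)
                out[v] = row
        return out

    # --------------------------------------------------------- identification
    def check_identification(
        self,
        groups: list[GroupSpec] | None = None,
        at: str = "generic",
        step: float = 1e-6,
    ) -> IdentificationReport:
        """Local identification via the rank of the moment Jacobian.

        Stacks the unique implied moments (means and the lower triangle of
        each group covariance) across ``groups`` and differentiates with
        respect to the free parameters by central finite differences at a
        generic interior point (or the current values with ``at="current"``).
        """
        groups = groups if groups is not None else self.groups
        if not groups:
            raise StructureError("no groups supplied for identification check")
        labels = self.free_parameter_vector()
        if not labels:
            raise StructureError("model has no free parameters")
        saved = self.get_theta()
        if at == "generic":
            theta0 = np.array(
                [GENERIC_POINT[self._registry[lab].role] for lab in labels]
            )
            # respect bounds
            lo, hi = zip(*self.bounds())
            theta0 = np.clip(theta0, np.array(lo) + 1e-3, np.array(hi) - 1e-3)
        else:
            theta0 = saved.copy()

        def stacked(theta):
            self.set_theta(theta)
            parts = []
            for g in groups:
                mu, Sig = self.implied_moments(g)
                tri = np.tril_indices(Sig.shape[0])
                parts.append(mu)
                parts.append(Sig[tri])
            return np.concatenate(parts)

        try:
            f0 = stacked(theta0)
            J = np.empty((f0.size, len(labels)))
            for k in range(len(labels)):
                h = step * max(1.0, abs(theta0[k]))
                tp = theta0.copy()
                tp[k] += h
                tm = theta0.copy()
                tm[k] -= h
                J[:, k] = (stacked(tp) - stacked(tm)) / (2 * h)
        finally:
            self.set_theta(saved)
        if not np.isfinite(J).all():
            raise FloatingPointError("Jacobian evaluation produced non-finite values")
        U, sv, Vt = np.linalg.svd(J)
        # the Jacobian is finite-differenced, so structural zeros surface at
        # the differencing noise level, far above machine epsilon
        tol = max(J.shape) * math.sqrt(np.finfo(float).eps) * (sv[0] if sv.size else 0.0)
        rank = int((sv > tol).sum())
        null = Vt[rank:].T  # (n_free, deficiency)
        return IdentificationReport(rank, len(labels), labels, sv, null)

    # ------------------------------------------------------------- serialize
    def to_dict(self) -> dict:
        def cells(d):
            return [
                {"at": list(k) if isinstance(k, tuple) else k, "label": p.label}
                for k, p in d.items()
            ]

        return {
            "name": self.name,
            "observed": self.observed,
            "latents": self.latents,
            "sources": [{"name": n, "kind": k} for n, k in self.sources],
            "loadings": cells(self.loadings),
            "regressions": cells(self.regressions),
            "latent_paths": cells(self.latent_paths),
            "residual_paths": cells(self.residual_paths),
            "source_corr": cells(self.source_corr),
            "means": cells(self.means),
            "cross_overrides": {
                g: cells(d) for g, d in self.cross_overrides.items()
            },
            "meta": dict(self.meta),
            "parameters": [
                {
                    "label": p.label,
                    "value": p.value,
                    "free": p.free,
                    "lower": None if np.isinf(p.lower) else p.lower,
                    "upper": None if np.isinf(p.upper) else p.upper,
                    "role": p.role,
                }
                for p in self._registry
            ],
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), indent=2, **kw)
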