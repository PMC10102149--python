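"""Ingestion and preprocessing of family-structured phenotype/score tables.

One row per individual; families are identified by ``family_id`` and members
by ``member_role`` (twin1 / twin2 / sibling).  Twin pairs carry a zygosity
(MZ / DZ); siblings are related to twins, and to each other, like DZ twins.
Polygenic-score columns may be missing for non-genotyped members; missing
values are masked (NaN) rather than dropped so partially genotyped families
still contribute to the likelihood.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .pathmodel import GroupSpec

ROLES = ("twin1", "twin2", "sibling")
ZYGOSITIES = ("MZ", "DZ")

#: Declared scale bounds for the study phenotypes (summed Likert scores).
DEFAULT_SCALE_BOUNDS = {
    "ssi": (0, 6),
    "ssp": (1, 6),
    "dep": (0, 24),
    "anx": (0, 24),
    "rsb": (0, 24),
}


class SchemaError(ValueError):
    """Input file lacks mandatory columns or declares unknown ones."""


class IntegrityError(ValueError):
    """Rows violate family-structure invariants."""


@dataclass
class ColumnSchema:
    """Maps file columns onto the roles the analysis expects."""

    family_id: str = "family_id"
    member_role: str = "member_role"
    zygosity: str = "zygosity"
    sex: str = "sex"
    age: str = "age"
    phenotypes: tuple[str, ...] = ("ssi", "ssp", "dep", "anx", "rsb")
    scores: tuple[str, ...] = ("ps_ssi", "ps_ssp", "ps_dep", "ps_anx", "ps_nsp", "ps_risk")

    @property
    def mandatory(self) -> tuple[str, ...]:
        return (self.family_id, self.member_role, self.zygosity, self.sex, self.age)


@dataclass
class FamilyTable:
    """Validated tidy table plus variable-role bookkeeping."""

    data: pd.DataFrame
    phenotypes: tuple[str, ...]
    scores: tuple[str, ...]

    def __post_init__(self) -> None:
        self.data = self.data.reset_index(drop=True)

    @property
    def n_individuals(self) -> int:
        return len(self.data)

    @property
    def n_families(self) -> int:
        return self.data["family_id"].nunique()

    def copy(self) -> "FamilyTable":
        return FamilyTable(self.data.copy(), self.phenotypes, self.scores)

    def to_csv(self, path, **kw) -> None:
        self.data.to_csv(path, index=False, **kw)


def validate_family_table(
    df: pd.DataFrame,
    phenotypes: tuple[str, ...],
    scores: tuple[str, ...],
    scale_bounds: dict[str, tuple[float, float]] | None = None,
) -> None:
    """Raise IntegrityError listing offending row numbers (0-based)."""
    bad: list[str] = []
    roles = df["member_role"]
    unknown = ~roles.isin(ROLES)
    if unknown.any():
        bad.append(f"unknown member_role at rows {list(df.index[unknown])}")
    dup = df.duplicated(subset=["family_id", "member_role"], keep=False)
    if dup.any():
        bad.append(
            "duplicate (family_id, member_role) at rows "
            f"{list(df.index[dup])}"
        )
    twins = df[roles.isin(("twin1", "twin2"))]
    zyg_ok = twins["zygosity"].isin(ZYGOSITIES)
    if (~zyg_ok).any():
        bad.append(f"twin rows without MZ/DZ zygosity: {list(twins.index[~zyg_ok])}")
    nzyg = twins.groupby("family_id")["zygosity"].nunique()
    mixed = nzyg[nzyg > 1].index.tolist()
    if mixed:
        rows = df.index[df["family_id"].isin(mixed) & roles.isin(("twin1", "twin2"))]
        bad.append(f"inconsistent zygosity within families {mixed} (rows {list(rows)})")
    if scale_bounds:
        for var, (lo, hi) in scale_bounds.items():
            if var not in df.columns:
                continue
            v = df[var]
            out = v.notna() & ((v < lo) | (v > hi))
            if out.any():
                bad.append(
                    f"{var} outside [{lo}, {hi}] at rows {list(df.index[out])}"
                )
    if bad:
        raise IntegrityError("; ".join(bad))


def load_family_table(
    path,
    schema: ColumnSchema | None = None,
    sep: str = ",",
    scale_bounds: dict[str, tuple[float, float]] | None = None,
) -> FamilyTable:
    """Read and validate a delimited family file.

    ``schema`` maps file columns to analysis roles; columns are renamed to
    the canonical names on load.  Structural violations raise with the
    offending 0-based data row numbers.
    """
    schema = schema or ColumnSchema()
    # round_trip parsing: simulator output must reload bit-identically
    df = pd.read_csv(path, sep=sep, float_precision="round_trip")
    missing = [c for c in schema.mandatory if c not in df.columns]
    if missing:
        raise SchemaError(f"missing mandatory columns: {missing}")
    rename = {
        schema.family_id: "family_id",
        schema.member_role: "member_role",
        schema.zygosity: "zygosity",
        schema.sex: "sex",
        schema.age: "age",
    }
    df = df.rename(columns=rename)
    present_ph = tuple(v for v in schema.phenotypes if v in df.columns)
    present_sc = tuple(v for v in schema.scores if v in df.columns)
    if not present_ph:
        raise SchemaError("no phenotype columns found")
    for col in present_ph + present_sc + ("age",):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    validate_family_table(df, present_ph, present_sc, scale_bounds)
    return FamilyTable(df, present_ph, present_sc)


# --------------------------------------------------------------- preprocessing
def residualize(
    table: FamilyTable,
    variables: list[str],
    covariates: list[str] = ("age", "sex"),
) -> FamilyTable:
    """Regress the mean effects of the covariates out of each variable.

    Ordinary least squares with intercept, pooled over all non-missing
    individuals (family clustering is ignored deliberately: only mean
    effects are removed).  Missing entries stay missing.
    """
    out = table.copy()
    df = out.data
    for cov in covariates:
        v = df[cov].astype(float)
        if np.nanstd(v.to_numpy()) == 0:
            raise ValueError(f"degenerate design: covariate {cov!r} has zero variance")
    X_all = df[list(covariates)].astype(float).to_numpy()
    for var in variables:
        y = df[var].astype(float).to_numpy()
        ok = ~np.isnan(y) & ~np.isnan(X_all).any(axis=1)
        X = np.column_stack([np.ones(ok.sum()), X_all[ok]])
        beta, *_ = np.linalg.lstsq(X, y[ok], rcond=None)
        resid = np.full_like(y, np.nan)
        resid[ok] = y[ok] - X @ beta
        df[var] = resid
    return out


def inverse_normal(values: np.ndarray, offset: float = 3.0 / 8.0) -> np.ndarray:
    """Rank-based inverse-normal transform (Blom offset), NaN-preserving.

    Ties get the average rank, hence identical transformed values.
    """
    v = np.asarray(values, dtype=float)
    out = np.full(v.shape, np.nan)
    ok = ~np.isnan(v)
    n = int(ok.sum())
    if n < 3:
        raise ValueError("need at least 3 non-missing values")
    if np.nanstd(v[ok]) == 0:
        raise ValueError("degenerate distribution: all values identical")
    ranks = stats.rankdata(v[ok], method="average")
    out[ok] = stats.norm.ppf((ranks - offset) / (n + 1 - 2 * offset))
    return out


def normalize(
    table: FamilyTable, variables: list[str], method: str = "blom"
) -> FamilyTable:
    """Normalize each variable in place (``blom`` rank-INT or ``zscore``)."""
    out = table.copy()
    for var in variables:
        v = out.data[var].astype(float).to_numpy()
        if method == "blom":
            out.data[var] = inverse_normal(v)
        elif method == "zscore":
            out.data[var] = (v - np.nanmean(v)) / np.nanstd(v)
        else:
            raise ValueError(f"unknown normalization method {method!r}")
    return out


def cronbach_alpha(items: pd.DataFrame) -> float:
    """Standardized Cronbach's alpha: k r̄ / (1 + (k-1) r̄)."""
    k = items.shape[1]
    if k < 2:
        raise ValueError("alpha needs at least 2 items")
    corr = items.corr().to_numpy()
    iu = np.triu_indices(k, 1)
    rbar = float(np.mean(corr[iu]))
    return k * rbar / (1 + (k - 1) * rbar)


def descriptives(
    table: FamilyTable,
    categorical: list[str] | None = None,
    item_sets: dict[str, list[str]] | None = None,
) -> dict[str, pd.DataFrame]:
    """Per-zygosity-group and total summaries plus standardized alphas.

    Returns ``{"continuous": ..., "categorical": ..., "alpha": ...}``.
    Group membership follows the individual's own status: MZ twin, DZ twin,
    or sibling.
    """
    df = table.data
    group = np.where(
        df["member_role"].eq("sibling"),
        "sibling",
        df["zygosity"].astype(str),
    )
    df = df.assign(_group=group)
    continuous = ["age", *table.phenotypes, *table.scores]
    cont_rows = []
    for g, sub in [*df.groupby("_group"), ("total", df)]:
        if len(sub) == 0:
            warnings.warn(f"empty group {g!r} omitted from descriptives")
            continue
        for var in continuous:
            v = sub[var].astype(float)
            cont_rows.append(
                {
                    "group": g,
                    "variable": var,
                    "n": int(v.notna().sum()),
                    "mean": v.mean(),
                    "sd": v.std(),
                }
            )
    cat_rows = []
    for var in categorical or ["sex"]:
        for g, sub in [*df.groupby("_group"), ("total", df)]:
            counts = sub[var].value_counts(dropna=True).sort_index()
            for level, n in counts.items():
                cat_rows.append(
                    {
                        "group": g,
                        "variable": var,
                        "level": level,
                        "n": int(n),
                        "percent": 100.0 * n / counts.sum(),
                    }
                )
    alpha_rows = []
    for name, items in (item_sets or {}).items():
        alpha_rows.append(
            {"scale": name, "alpha": cronbach_alpha(df[items].dropna())}
        )
    return {
        "continuous": pd.DataFrame(cont_rows),
        "categorical": pd.DataFrame(cat_rows),
        "alpha": pd.DataFrame(alpha_rows),
    }


# ------------------------------------------------------------------- assembly
@dataclass
class GroupData:
    """Stacked observations for one relatedness class.

    ``data`` is (n_units, n_members * p) member-major, NaN for missing.
    """

    spec: GroupSpec
    data: np.ndarray
    family_ids: list = field(default_factory=list)

    @property
    def n_units(self) -> int:
        return self.data.shape[0]


@dataclass
class AnalysisDataset:
    variables: list[str]
    groups: dict[str, GroupData]

    @property
    def n_individuals(self) -> int:
        return sum(g.n_units * g.spec.n_members for g in self.groups.values())

    def subset(self, names: list[str]) -> "AnalysisDataset":
        return AnalysisDataset(
            self.variables, {n: self.groups[n] for n in names if n in self.groups}
        )


def assemble_analysis_dataset(
    table: FamilyTable,
    variables: list[str],
    mode: str = "blocks",
) -> AnalysisDataset:
    """Group families into relatedness classes for the FIML likelihood.

    ``mode="blocks"`` (default) keeps twin+sibling trios as 3-member blocks
    with pairwise relatedness; ``mode="pairs"`` extracts the twin pair and
    keeps the sibling as a singleton; ``mode="individuals"`` treats everyone
    as a singleton (phenotypic, non-family models).  Missing entries are
    masked, never dropped, so a family missing the score columns still
    contributes its phenotypes.  Fully vectorized: comfortable with
    hundreds of thousands of families.
    """
    if mode not in ("blocks", "pairs", "individuals"):
        raise ValueError(f"unknown assembly mode {mode!r}")
    missing = [v for v in variables if v not in table.data.columns]
    if missing:
        raise ValueError(f"variables not in table: {missing}")
    df = table.data
    variables = list(variables)

    groups: dict[str, GroupData] = {}

    def put(key: str, spec: GroupSpec, arr: np.ndarray, ids) -> None:
        if arr.shape[0]:
            groups[key] = GroupData(spec, arr, list(ids))

    if mode == "individuals":
        put(
            "singleton",
            GroupSpec.singleton(),
            df[variables].to_numpy(dtype=float),
            df["family_id"],
        )
        return AnalysisDataset(variables, groups)

    piv = df.pivot(index="family_id", columns="member_role", values=variables)
    fam_ids = piv.index.to_numpy()
    member = {}
    present = {}
    for role in ROLES:
        cols = [(v, role) for v in variables]
        if all(c in piv.columns for c in cols):
            member[role] = piv[cols].to_numpy(dtype=float)
        else:
            member[role] = np.full((len(piv), len(variables)), np.nan)
        role_rows = df.loc[df["member_role"] == role, "family_id"]
        present[role] = np.isin(fam_ids, role_rows.to_numpy())
    zyg = (
        df[df["member_role"].isin(("twin1", "twin2"))]
        .groupby("family_id")["zygosity"]
        .first()
        .reindex(piv.index)
    )
    is_mz = (zyg == "MZ").to_numpy()
    t1, t2, sib = present["twin1"], present["twin2"], present["sibling"]

    both = t1 & t2
    trio = both & sib & (mode == "blocks")
    pair = both & ~trio
    twin_sib = (t1 ^ t2) & sib  # one twin + sibling: DZ-equivalent pair
    lone = ~both & ~twin_sib

    def stack(sel, roles):
        return np.hstack([member[r][sel] for r in roles]), fam_ids[sel]

    put("MZ", GroupSpec.mz_pair(), *stack(pair & is_mz, ("twin1", "twin2")))
    dz_arr, dz_ids = stack(pair & ~is_mz, ("twin1", "twin2"))
    # one-twin + sibling families join the DZ-relatedness group
    ts_arr = np.where(
        t1[twin_sib][:, None], member["twin1"][twin_sib], member["twin2"][twin_sib]
    )
    ts_arr = np.hstack([ts_arr, member["sibling"][twin_sib]])
    put(
        "DZ",
        GroupSpec.dz_pair(),
        np.vstack([dz_arr, ts_arr]),
        list(dz_ids) + list(fam_ids[twin_sib]),
    )
    put("trioMZ", GroupSpec.mz_trio(), *stack(trio & is_mz, ROLES))
    put("trioDZ", GroupSpec.dz_trio(), *stack(trio & ~is_mz, ROLES))

    single_rows, single_ids = [], []
    for role in ROLES:
        if role == "sibling":
            sel = present[role] & (lone | (pair & sib))
        else:
            sel = present[role] & lone & ~twin_sib
        single_rows.append(member[role][sel])
        single_ids.extend(fam_ids[sel])
    put("singleton", GroupSpec.singleton(), np.vstack(single_rows), single_ids)
    return AnalysisDataset(variables, groups)
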