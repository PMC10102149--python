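"""End-to-end orchestration: preprocess, correlations, ACE, MR-DoC, report.

The pipeline mirrors the analysis order of the study design: residualize
age/sex and rank-normalize the phenotypes; fit the constrained correlational
model; fit the bivariate common-pathway ACE model and test whether shared
environment can be dropped; fit forward and reverse MR-DoC models (AE
parameterized when the C-drop test does not reject); fit the phenotypic MR
model; and decompose the exposure-outcome correlation into causal,
pleiotropic and residual-genetic parts.

Every stage writes CSV/JSON artifacts into the output directory and records
itself in a run manifest, so a rerun with the same config and seed
reproduces every table byte for byte.
"""
from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .builders import (
    PD,
    PS_PD,
    PS_RSB,
    PS_SSA,
    RSB,
    SSA,
    Factor,
    MrdocSpec,
    build_biometric_factor_model,
    build_constrained_correlation_model,
    build_mrdoc,
    build_phenotypic_mr,
    decompose_fit,
)
from .families import (
    ColumnSchema,
    FamilyTable,
    assemble_analysis_dataset,
    descriptives,
    load_family_table,
    normalize,
    residualize,
)
from .fiml import FitOptions, fit_fiml, likelihood_ratio_test, profile_ci, wald_se
from .simulate import SimulationConfig, simulate_families

log = logging.getLogger("twinmr.pipeline")


@dataclass
class PipelineConfig:
    """Everything one run needs; loadable from YAML."""

    input_path: str | None = None  # CSV of families; None -> simulate
    simulation: dict = field(default_factory=dict)  # SimulationConfig kwargs
    outcome: str = "PD"  # "PD" or "RSB"
    output_dir: str = "twinmr_run"
    seed: int = 0
    ci_level: float = 0.95
    compute_ci: bool = False  # profile CI for the causal paths
    normalize_method: str = "blom"
    covariates: tuple[str, ...] = ("age", "sex")
    c_drop_alpha: float = 0.05
    force_ace: bool = False  # override the automated C drop
    models: tuple[str, ...] = (
        "corr",
        "ace-factor",
        "mrdoc-forward",
        "mrdoc-reverse",
        "phenotypic-mr",
    )
    n_starts: int = 2

    @staticmethod
    def from_yaml(path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f for f in PipelineConfig.__dataclass_fields__}
        unknown = set(raw) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for key in ("covariates", "models"):
            if key in raw and isinstance(raw[key], list):
                raw[key] = tuple(raw[key])
        return PipelineConfig(**raw)


def _parameter_table(fit, model, ds, level: float = 0.95) -> pd.DataFrame:
    """Standardized table with Wald CI columns for every free parameter."""
    from scipy.stats import norm

    table = fit.standardized.copy()
    try:
        se = wald_se(model, ds, fit)
    except Exception:  # noqa: BLE001  (singular information: leave CIs blank)
        se = {}
    z = norm.ppf(0.5 + level / 2)
    lows, highs, ses = [], [], []
    for _, row in table.iterrows():
        s = se.get(row["label"]) if row["free"] else None
        ses.append(s)
        lows.append(row["raw"] - z * s if s is not None else None)
        highs.append(row["raw"] + z * s if s is not None else None)
    table["se"] = ses
    table["ci_lower"] = lows
    table["ci_upper"] = highs
    return table


def _measurement_table(model) -> pd.DataFrame:
    """Per-indicator standardized loadings and A/C/E specifics.

    Single-indicator factors show the identification constants (loading 1,
    specifics 0) and are marked fixed.
    """
    from .pathmodel import GroupSpec

    _, Sig = model.implied_moments(GroupSpec.singleton())
    sd = {v: float(np.sqrt(Sig[i, i])) for i, v in enumerate(model.observed)}
    _, T_lat, Phi = model.total_effects()
    lat_sd = {
        v: float(np.sqrt((T_lat @ Phi @ T_lat.T)[i, i]))
        for i, v in enumerate(model.latents)
    }
    kinds = dict(model.sources)
    rows = []
    for obs in model.observed:
        loading = next(
            (p, l) for (o, l), p in model.loadings.items() if o == obs
        )
        par, factor = loading
        specs = {"A": 0.0, "C": 0.0, "E": 0.0}
        has_specifics = False
        for (o, s), p in model.residual_paths.items():
            if o == obs and kinds[s] in specs:
                specs[kinds[s]] = p.value / sd[obs]
                has_specifics = True
        rows.append(
            {
                "indicator": obs,
                "loading": par.value * lat_sd[factor] / sd[obs],
                "a_s": specs["A"],
                "c_s": specs["C"],
                "e_s": specs["E"],
                "fixed": (not par.free) and not has_specifics,
            }
        )
    return pd.DataFrame(rows)


def _factors(outcome: str) -> tuple[Factor, Factor, Factor, Factor]:
    if outcome == "PD":
        return SSA, PD, PS_SSA, PS_PD
    if outcome == "RSB":
        return SSA, RSB, PS_SSA, PS_RSB
    raise ValueError(f"unknown outcome {outcome!r}")


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all configured stages; returns (and writes) the run manifest."""
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest: dict = {
        "config": {k: (list(v) if isinstance(v, tuple) else v)
                   for k, v in asdict(config).items()},
        "stages": [],
    }
    opts = FitOptions(n_starts=config.n_starts, seed=config.seed)
    exposure, outcome_f, instrument, rev_instrument = _factors(config.outcome)
    variables = [
        *instrument.indicators,
        *rev_instrument.indicators,
        *exposure.indicators,
        *outcome_f.indicators,
    ]

    def stage(name: str, **info):
        entry = {"name": name, "status": "ok", **info}
        manifest["stages"].append(entry)
        log.info("stage %s: %s", name, info.get("note", "done"))
        return entry

    def fail(name: str, err: Exception):
        manifest["stages"].append({"name": name, "status": "failed",
                                   "error": str(err)})
        manifest["halted_at"] = name
        _write_manifest(out, manifest)
        raise err

    # ------------------------------------------------------------ input data
    if config.input_path:
        table = load_family_table(config.input_path, ColumnSchema())
        source = {"input_path": str(config.input_path)}
    else:
        sim_cfg = SimulationConfig(
            seed=config.seed, outcome=config.outcome, **config.simulation
        )
        table = simulate_families(sim_cfg)
        source = {"simulation": json.loads(json.dumps(asdict(sim_cfg), default=str))}
        table.to_csv(out / "simulated_families.csv")
    missing_vars = [v for v in variables if v not in table.data.columns]
    if missing_vars:
        fail("validate", ValueError(f"variables missing from input: {missing_vars}"))
    stage("load", n_individuals=table.n_individuals,
          n_families=table.n_families, **source)

    # ------------------------------------------------------------ preprocess
    try:
        table = residualize(table, list(table.phenotypes), list(config.covariates))
        table = normalize(table, list(table.phenotypes), config.normalize_method)
        desc = descriptives(table)
        desc["continuous"].to_csv(out / "descriptives_continuous.csv", index=False)
        table.to_csv(out / "preprocessed.csv")
        stage("preprocess", outputs=["preprocessed.csv",
                                     "descriptives_continuous.csv"])
    except Exception as err:  # noqa: BLE001
        fail("preprocess", err)

    results: dict[str, object] = {}
    observed_r: float | None = None
    use_ae = False

    # ----------------------------------------------------------- correlations
    if "corr" in config.models:
        try:
            model = build_constrained_correlation_model(
                [exposure, outcome_f], instrument=instrument
            )
            ds = assemble_analysis_dataset(table, list(model.observed), mode="pairs")
            fit = fit_fiml(model, ds, opts)
            _parameter_table(fit, model, ds).to_csv(
                out / "corr_parameters.csv", index=False
            )
            observed_r = fit.estimates[f"r_{exposure.name}_{outcome_f.name}"]
            results["corr"] = fit
            stage(
                "corr",
                minus2lnL=fit.minus2lnL,
                converged=fit.converged,
                r_exposure_outcome=observed_r,
                r_instrument_exposure=fit.estimates[
                    f"r_{instrument.name}_{exposure.name}"
                ],
                outputs=["corr_parameters.csv"],
            )
        except Exception as err:  # noqa: BLE001
            fail("corr", err)

    # ------------------------------------------------------------ ACE factor
    if "ace-factor" in config.models:
        try:
            ds = assemble_analysis_dataset(
                table, [*exposure.indicators, *outcome_f.indicators]
            )
            m_ace = build_biometric_factor_model(exposure, outcome_f)
            fit_ace = fit_fiml(m_ace, ds, opts)
            m_ae = build_biometric_factor_model(exposure, outcome_f, drop_c=True)
            fit_ae = fit_fiml(m_ae, ds, opts)
            lrt = likelihood_ratio_test(fit_ace, fit_ae)
            use_ae = (lrt.p_value >= config.c_drop_alpha) and not config.force_ace
            chosen = fit_ae if use_ae else fit_ace
            chosen_model = m_ae if use_ae else m_ace
            _parameter_table(chosen, chosen_model, ds).to_csv(
                out / "ace_parameters.csv", index=False
            )
            _measurement_table(chosen_model).to_csv(
                out / "ace_measurement.csv", index=False
            )
            chosen.variance_proportions.to_csv(
                out / "ace_variance_components.csv", index=False
            )
            results["ace"] = chosen
            stage(
                "ace-factor",
                minus2lnL=chosen.minus2lnL,
                converged=chosen.converged,
                c_drop_chi2=lrt.chi_square,
                c_drop_df=lrt.df,
                c_drop_p=lrt.p_value,
                ae_parameterization=use_ae,
                outputs=["ace_parameters.csv", "ace_measurement.csv",
                         "ace_variance_components.csv"],
            )
        except Exception as err:  # noqa: BLE001
            fail("ace-factor", err)

    # ------------------------------------------------------------ MR-DoC x2
    mrdoc_defs = []
    if "mrdoc-forward" in config.models:
        mrdoc_defs.append(
            ("mrdoc-forward",
             MrdocSpec(instrument=instrument, exposure=exposure,
                       outcome=outcome_f, direction="forward",
                       ae_only=use_ae or "ace-factor" not in config.models))
        )
    if "mrdoc-reverse" in config.models:
        mrdoc_defs.append(
            ("mrdoc-reverse",
             MrdocSpec(instrument=rev_instrument, exposure=exposure,
                       outcome=outcome_f, direction="reverse",
                       ae_only=use_ae or "ace-factor" not in config.models))
        )
    for name, spec in mrdoc_defs:
        try:
            model = build_mrdoc(spec)
            ident = model.check_identification()
            ds = assemble_analysis_dataset(table, list(model.observed))
            fit = fit_fiml(model, ds, opts)
            if not fit.converged:
                raise RuntimeError(f"{name} did not converge "
                                   f"(gradient norm {fit.grad_norm:.2g})")
            if config.compute_ci:
                lo, hi, flag = profile_ci(model, ds, fit, "g1", config.ci_level)
                fit.ci["g1"] = (lo, hi, config.ci_level)
                fit.ci_flags["g1"] = flag
            dec = decompose_fit(fit, model, reference=observed_r)
            g1_std = float(
                fit.standardized.set_index("label").loc["g1", "standardized"]
            )
            _parameter_table(fit, model, ds).to_csv(
                out / f"{name}_parameters.csv", index=False
            )
            (out / f"{name}_identification.txt").write_text(ident.summary() + "\n")
            dec_row = {
                "model": name,
                "implied_correlation": dec.implied_correlation,
                **dec.contributions,
                **{f"share_{k}": v for k, v in dec.share_of_reference.items()},
                "reference_correlation": observed_r,
            }
            pd.DataFrame([dec_row]).to_csv(out / f"{name}_decomposition.csv",
                                           index=False)
            results[name] = (fit, dec)
            stage(
                name,
                minus2lnL=fit.minus2lnL,
                converged=fit.converged,
                g1_standardized=g1_std,
                g1_ci=list(fit.ci.get("g1", ())),
                identified=ident.identified,
                causal_share=dec.share_of_reference["causal"]
                if observed_r else None,
                outputs=[f"{name}_parameters.csv", f"{name}_decomposition.csv",
                         f"{name}_identification.txt"],
            )
        except Exception as err:  # noqa: BLE001
            fail(name, err)

    # -------------------------------------------------------- phenotypic MR
    if "phenotypic-mr" in config.models:
        try:
            spec = MrdocSpec(instrument=instrument, exposure=exposure,
                             outcome=outcome_f)
            model = build_phenotypic_mr(spec)
            ds = assemble_analysis_dataset(table, list(model.observed),
                                           mode="individuals")
            fit = fit_fiml(model, ds, opts)
            g1_std = float(
                fit.standardized.set_index("label").loc["g1", "standardized"]
            )
            _parameter_table(fit, model, ds).to_csv(
                out / "phenotypic_mr_parameters.csv", index=False
            )
            results["phenotypic-mr"] = fit
            stage(
                "phenotypic-mr",
                minus2lnL=fit.minus2lnL,
                converged=fit.converged,
                g1_standardized=g1_std,
                outputs=["phenotypic_mr_parameters.csv"],
            )
        except Exception as err:  # noqa: BLE001
            fail("phenotypic-mr", err)

    _write_manifest(out, manifest)
    return manifest


def _write_manifest(out: Path, manifest: dict) -> None:
    (out / "manifest.json").write_text(
        json.dumps(manifest, indent=2, default=float) + "\n"
    )


# ----------------------------------------------------------------- reporting
def render_tables(run_dir) -> str:
    """Plain-text summary tables from a completed run directory."""
    run_dir = Path(run_dir)
    manifest = json.loads((run_dir / "manifest.json").read_text())
    lines = ["twinmr run report", "=" * 60]
    by_name = {s["name"]: s for s in manifest["stages"]}
    if "corr" in by_name:
        s = by_name["corr"]
        lines += [
            "",
            "Constrained correlational model",
            f"  r(exposure, outcome)  = {s['r_exposure_outcome']:+.3f}",
            f"  r(instrument, exposure) = {s['r_instrument_exposure']:+.3f}",
        ]
    if "ace-factor" in by_name:
        s = by_name["ace-factor"]
        lines += [
            "",
            "Biometric common-pathway model",
            f"  C-drop LRT: chi2[{s['c_drop_df']}] = {s['c_drop_chi2']:.3f}, "
            f"p = {s['c_drop_p']:.3f} -> "
            + ("AE" if s["ae_parameterization"] else "ACE"),
        ]
        vc = pd.read_csv(run_dir / "ace_variance_components.csv")
        factors = vc[~vc["variable"].str.islower()]
        for _, row in factors.iterrows():
            parts = "  ".join(
                f"{c.removeprefix('prop_')}2={row[c]:.2f}"
                for c in vc.columns
                if c.startswith("prop_")
            )
            lines.append(f"  {row['variable']:<8} {parts}")
        meas = pd.read_csv(run_dir / "ace_measurement.csv")
        lines += ["", "Measurement model (standardized loadings / specifics)"]
        for _, row in meas.iterrows():
            mark = " (fixed)" if row["fixed"] else ""
            lines.append(
                f"  {row['indicator']:<8} loading={row['loading']:.2f}"
                f"  a_s={row['a_s']:.2f}  c_s={row['c_s']:.2f}"
                f"  e_s={row['e_s']:.2f}{mark}"
            )
    for name in ("mrdoc-forward", "mrdoc-reverse"):
        if name not in by_name:
            continue
        s = by_name[name]
        lines += ["", f"{name} model",
                  f"  standardized causal path g1 = {s['g1_standardized']:+.3f}"]
        if s.get("g1_ci"):
            lo, hi, lvl = s["g1_ci"]
            lines.append(f"  {int(lvl * 100)}% profile CI: ({lo:+.3f}, {hi:+.3f})")
        dec = pd.read_csv(run_dir / f"{name}_decomposition.csv").iloc[0]
        if pd.notna(dec.get("reference_correlation")):
            rows = [
                ("causal", dec["share_causal"]),
                ("residual genetic", dec["share_residual_genetic"]),
                ("pleiotropic", dec["share_pleiotropic"]),
            ]
            lines.append(
                "  share of observed correlation "
                f"r = {dec['reference_correlation']:.2f}:"
            )
            for label, v in rows:
                lines.append(f"    {label:<18} {100 * v:5.0f}%")
    if "phenotypic-mr" in by_name:
        s = by_name["phenotypic-mr"]
        lines += ["", "Phenotypic MR model",
                  f"  standardized causal path g1 = {s['g1_standardized']:+.3f}"]
    text = "\n".join(lines) + "\n"
    (run_dir / "report.txt").write_text(text)
    return text
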