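"""Monte-Carlo experiments: empirical vs oracle vs approximation tables.

Reproduces the structure of the simulation study: for a named setting
(A-D presets, or a custom configuration) simulate R retrospective datasets,
fit the misspecified clinical logistic model to each, and tabulate the
empirical average/SD next to the pseudo-true oracle and both closed-form
approximations.  A separate misspecification study recomputes the oracle
and approximations under shifted contamination rates while the generative
truth stays fixed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .bias_approx import approx_gamma_for_model, approx_gamma_model1
from .pseudo_true import PseudoTrueProblem, pseudo_true_gamma, sensitivity_sweep
from .risk_models import (
    ContaminationSpec,
    CovariateDistribution,
    DiseaseModel,
    GammaVector,
    GenotypeModel,
    RiskCoefficients,
    StudyDesign,
)
from .simulate import SimulatedDataset, simulate_dataset

__all__ = [
    "FitResult",
    "fit_clinical_logistic",
    "setting_preset",
    "run_setting",
    "misspecification_study",
    "plot_setting_table",
]

#: shared covariate law of the simulation study: SNP carrier 0.10,
#: ApoE-e4-like environment 0.14, age/sex-like covariates 0.50 / 0.52
SIMULATION_COVARIATES = CovariateDistribution(
    genotype=GenotypeModel(theta=0.10, coding="raw_bernoulli"),
    env_freq=0.14,
    covariate_freqs=(0.50, 0.52),
)

#: canonical contamination rates: 36% of clinically diagnosed noncarriers
#: and 6% of carriers lack the pathology of interest
CANONICAL_CONTAMINATION = ContaminationSpec(S0=0.36, S1=0.06)


@dataclass(frozen=True)
class FitResult:
    """Maximum-likelihood clinical-model fit with standard errors."""

    gamma: GammaVector
    se: dict[str, float]
    converged: bool
    n_obs: int


def _term_columns(df: pd.DataFrame, terms: Sequence[str]) -> np.ndarray:
    cols = []
    for t in terms:
        if t == "intercept":
            cols.append(np.ones(len(df)))
        elif t == "gxx":
            cols.append((df["g"] * df["x"]).to_numpy(dtype=float))
        else:
            cols.append(df[t].to_numpy(dtype=float))
    return np.column_stack(cols)


def fit_clinical_logistic(
    data: SimulatedDataset | pd.DataFrame,
    fitted_terms: Sequence[str] | None = None,
) -> FitResult:
    """Fit the clinical-label logistic model, ignoring the latent true state.

    The fit is computed on cell-grouped binomial counts (all covariates are
    binary), which is exact ML for the row-level logistic model and far
    faster for replicated simulation runs.

    Raises
    ------
    ValueError
        If the data are degenerate in the outcome (all cases or all controls).
    """
    df = data.data if isinstance(data, SimulatedDataset) else data
    z_cols = sorted(c for c in df.columns if c.startswith("z"))
    terms = tuple(fitted_terms) if fitted_terms is not None else (
        "intercept",
        "g",
        "x",
        "gxx",
        *z_cols,
    )
    if df["dcl"].nunique() < 2:
        raise ValueError("degenerate outcome: need both cases and controls")

    cov_cols = ["g", "x", *z_cols]
    grouped = (
        df.groupby(cov_cols)["dcl"].agg(successes="sum", trials="count").reset_index()
    )
    exog = _term_columns(grouped, terms)
    endog = np.column_stack(
        [grouped["successes"], grouped["trials"] - grouped["successes"]]
    )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        model = sm.GLM(endog, exog, family=sm.families.Binomial())
        try:
            res = model.fit(maxiter=200, tol=1e-10)
            converged = bool(res.converged)
        except Exception:  # perfect separation and friends
            res = None
            converged = False
    if res is None:
        params = np.full(len(terms), np.nan)
        bse = params
    else:
        params, bse = np.asarray(res.params), np.asarray(res.bse)
        if not np.all(np.isfinite(params)) or np.any(np.abs(params) > 30):
            converged = False

    values = dict.fromkeys(("intercept", "g", "x", "gxx", *z_cols), 0.0)
    ses = dict.fromkeys(values, float("nan"))
    for t, p, s in zip(terms, params, bse):
        values[t], ses[t] = float(p), float(s)
    name_map = {"intercept": "gamma0", "g": "gammaG", "x": "gammaX", "gxx": "gammaGxX"}
    gamma = GammaVector(
        gamma0=values["intercept"] if converged else 0.0,
        gammaG=values["g"] if converged else 0.0,
        gammaX=values["x"] if converged else 0.0,
        gammaGxX=values["gxx"] if converged else 0.0,
        gammaZ=tuple(values[c] if converged else 0.0 for c in z_cols),
        provenance="mle",
    )
    se = {name_map.get(k, f"gammaZ{k[1:]}"): v for k, v in ses.items()}
    return FitResult(gamma=gamma, se=se, converged=converged, n_obs=len(df))


# ---------------------------------------------------------------------------
# setting presets
# ---------------------------------------------------------------------------


def setting_preset(name: str) -> dict:
    """Built-in simulation settings.

    A: contamination model, strong environment effect (log 8), null
       interaction by default.
    B: trinomial model with distinct nuisance-state coefficients.
    C: Setting B with 1,000 controls / 2,000 cases.
    D: misspecification scenarios around the canonical contamination rates
       (used by :func:`misspecification_study`).
    """
    name = name.upper()
    if name == "A":
        model = DiseaseModel(
            kind="binary_with_contamination",
            B=RiskCoefficients(
                beta0=-1.0, betaG=-0.41, betaX=math.log(8.0), betaGxX=0.0
            ),
            Z_effects=(0.0, -0.08),
            contamination=CANONICAL_CONTAMINATION,
        )
        design = StudyDesign(n_controls=3000, n_cases=3000, replicates=500, seed=0)
    elif name in ("B", "C", "D"):
        model = DiseaseModel(
            kind="trinomial",
            B=RiskCoefficients(beta0=-1.0, betaG=-0.69, betaX=1.3, betaGxX=1.099),
            B_star=RiskCoefficients(beta0=-1.7, betaG=0.0, betaX=0.5, betaGxX=0.0),
            Z_effects=(0.10, -0.083),
        )
        if name == "B":
            design = StudyDesign(n_controls=3000, n_cases=3000, replicates=500, seed=0)
        else:
            design = StudyDesign(n_controls=1000, n_cases=2000, replicates=500, seed=0)
    else:
        raise ValueError(f"unknown preset {name!r}; expected one of A, B, C, D")
    return {"setting": name, "model": model, "covariates": SIMULATION_COVARIATES,
            "design": design, "grid": [{}]}


def _apply_overrides(model: DiseaseModel, overrides: Mapping[str, float]) -> DiseaseModel:
    """Rebuild a model with named coefficients replaced.

    Recognized keys: beta0/betaG/betaX/betaGxX, the same with a ``_star``
    suffix, and betaZ1/betaZ2/... for the shared covariate effects.
    """
    b = dict(model.B.as_dict())
    bs = dict(model.B_star.as_dict()) if model.B_star is not None else None
    z = list(model.Z_effects)
    for key, value in overrides.items():
        if key.endswith("_star"):
            if bs is None:
                raise ValueError(f"{key} override on a model without B_star")
            bs[key[: -len("_star")]] = float(value)
        elif key.startswith("betaZ"):
            z[int(key[len("betaZ"):]) - 1] = float(value)
        elif key in b:
            b[key] = float(value)
        else:
            raise ValueError(f"unknown coefficient override {key!r}")
    return replace(
        model,
        B=RiskCoefficients(**b),
        B_star=RiskCoefficients(**bs) if bs is not None else None,
        Z_effects=tuple(z),
    )


_COEF_NAMES = ("gamma0", "gammaG", "gammaX", "gammaGxX")


def _true_beta_map(model: DiseaseModel) -> dict[str, float]:
    out = dict(zip(_COEF_NAMES, model.B.as_array()))
    for k, bz in enumerate(model.Z_effects):
        out[f"gammaZ{k + 1}"] = bz
    return out


def run_setting(
    setting_config: str | dict,
    replicates: int | None = None,
    seed: int | None = None,
    fitted_terms: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Run one simulation setting and tabulate AVE/SD vs oracle vs approximations.

    Parameters
    ----------
    setting_config : str or dict
        A preset name (``"A"``..``"D"``) or a dict with keys ``model``,
        ``covariates``, ``design`` and optionally ``grid`` (a list of
        coefficient-override dicts, one table block per grid point).
    replicates, seed : optional
        Override the design's replicate count / seed (quick runs).
    fitted_terms : optional
        Terms of the misspecified fit; defaults to intercept, G, X, GxX and
        every Z present in the covariate distribution.

    Returns
    -------
    pandas.DataFrame
        Tidy rows keyed by (setting, grid point, coefficient) with columns
        ``empirical_mean``, ``empirical_sd``, ``oracle``, ``theoretical``,
        ``linearized``, ``n0``, ``n1``, ``R``, ``n_dropped``.

    Raises
    ------
    RuntimeError
        If more than 1% of replicates fail to converge.
    """
    config = setting_preset(setting_config) if isinstance(setting_config, str) else dict(
        setting_config
    )
    base_model: DiseaseModel = config["model"]
    cov: CovariateDistribution = config["covariates"]
    design: StudyDesign = config["design"]
    grid = config.get("grid", [{}])
    setting = config.get("setting", "custom")
    if replicates is not None or seed is not None:
        design = StudyDesign(
            n_controls=design.n_controls,
            n_cases=design.n_cases,
            replicates=replicates if replicates is not None else design.replicates,
            seed=seed if seed is not None else design.seed,
        )

    blocks = []
    for point_index, overrides in enumerate(grid):
        model = _apply_overrides(base_model, overrides)
        theo, lin = approx_gamma_for_model(model)
        oracle = pseudo_true_gamma(
            PseudoTrueProblem(
                model=model,
                cov=cov,
                case_fraction=design.case_fraction,
                fitted_terms=tuple(fitted_terms) if fitted_terms else (),
            )
        )

        estimates = []
        n_dropped = 0
        for r in range(design.replicates):
            dataset = simulate_dataset(model, cov, design, replicate_index=r)
            fit = fit_clinical_logistic(dataset, fitted_terms)
            if not fit.converged:
                n_dropped += 1
                continue
            estimates.append(fit.gamma.as_array())
        if n_dropped > 0.01 * design.replicates:
            raise RuntimeError(
                f"{n_dropped}/{design.replicates} replicates failed to converge"
            )
        est = np.array(estimates)
        means, sds = est.mean(axis=0), est.std(axis=0, ddof=1)

        truth = _true_beta_map(model)
        names = list(truth)
        for i, name in enumerate(names):
            blocks.append(
                {
                    "setting": setting,
                    "grid_point": point_index,
                    **{f"override_{k}": v for k, v in overrides.items()},
                    "coefficient": name,
                    "true_beta": truth[name],
                    "empirical_mean": means[i],
                    "empirical_sd": sds[i],
                    "oracle": oracle.as_dict()[name],
                    "theoretical": theo.as_dict()[name],
                    "linearized": lin.as_dict()[name],
                    "n0": design.n_controls,
                    "n1": design.n_cases,
                    "R": design.replicates,
                    "n_dropped": n_dropped,
                }
            )
    return pd.DataFrame(blocks)


# ---------------------------------------------------------------------------
# contamination misspecification study
# ---------------------------------------------------------------------------

#: the three printed scenarios: equal over-/under-statement preserves the
#: differential degree; the third widens it
MISSPEC_SCENARIOS = {
    "both_plus_5": (0.05, 0.05),
    "both_minus_5": (-0.05, -0.05),
    "differential_5": (0.05, -0.05),
}


def misspecification_study(
    setting_config: str | dict | None = None,
    offset_spec: Mapping[str, tuple[float, float]] | None = None,
) -> pd.DataFrame:
    """Recompute oracle and approximations under misspecified contamination rates.

    The generative truth is held fixed; what shifts is the contamination
    assumption fed to the oracle and to the closed-form approximations.
    The preset uses the trinomial simulation coefficients recast as a
    contamination model at the canonical rates with the Setting-C design,
    since the rates are free parameters only in that parameterization.

    Returns a tidy frame with one row per (scenario, coefficient) carrying
    the shifted oracle/theoretical/linearized values and their deltas from
    the unshifted reference.
    """
    if setting_config is None or setting_config == "D":
        preset = setting_preset("C")
        base = preset["model"]
        model = DiseaseModel(
            kind="binary_with_contamination",
            B=base.B,
            Z_effects=base.Z_effects,
            contamination=CANONICAL_CONTAMINATION,
        )
        config = {
            "setting": "D",
            "model": model,
            "covariates": preset["covariates"],
            "design": preset["design"],
        }
    else:
        config = (
            setting_preset(setting_config)
            if isinstance(setting_config, str)
            else dict(setting_config)
        )
    model = config["model"]
    if model.kind != "binary_with_contamination":
        raise ValueError("misspecification_study requires a contamination model")
    cov = config["covariates"]
    design = config["design"]
    scenarios = dict(offset_spec) if offset_spec is not None else dict(MISSPEC_SCENARIOS)

    problem = PseudoTrueProblem(
        model=model, cov=cov, case_fraction=design.case_fraction
    )
    sweep = sensitivity_sweep(problem, list(scenarios.values()))
    ref_theo, ref_lin = approx_gamma_model1(
        model.B, model.contamination, model.Z_effects
    )

    rows = []
    for scenario, (dS0, dS1) in scenarios.items():
        shifted = model.contamination.shifted(dS0, dS1)
        theo, lin = approx_gamma_model1(model.B, shifted, model.Z_effects)
        sub = sweep[(sweep["dS0"] == dS0) & (sweep["dS1"] == dS1)]
        oracle = dict(zip(sub["coefficient"], sub["gamma"]))
        odelta = dict(zip(sub["coefficient"], sub["delta"]))
        for name in theo.as_dict():
            rows.append(
                {
                    "setting": config.get("setting", "custom"),
                    "scenario": scenario,
                    "dS0": dS0,
                    "dS1": dS1,
                    "coefficient": name,
                    "oracle": oracle[name],
                    "oracle_delta": odelta[name],
                    "theoretical": theo.as_dict()[name],
                    "theoretical_delta": theo.as_dict()[name] - ref_theo.as_dict()[name],
                    "linearized": lin.as_dict()[name],
                    "linearized_delta": lin.as_dict()[name] - ref_lin.as_dict()[name],
                }
            )
    return pd.DataFrame(rows)


def plot_setting_table(table: pd.DataFrame, path: str) -> None:
    """Plot AVE / oracle / theoretical / linearized per coefficient (one panel each)."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    coefs = table["coefficient"].unique()
    fig, axes = plt.subplots(1, len(coefs), figsize=(3.2 * len(coefs), 3.2), squeeze=False)
    for ax, coef in zip(axes[0], coefs):
        sub = table[table["coefficient"] == coef]
        xs = sub["grid_point"]
        ax.errorbar(xs, sub["empirical_mean"], yerr=sub["empirical_sd"], fmt="o",
                    label="AVE", capsize=3)
        ax.plot(xs, sub["oracle"], "s--", label="oracle")
        ax.plot(xs, sub["theoretical"], "^:", label="TH")
        ax.plot(xs, sub["linearized"], "v:", label="APX")
        ax.axhline(0.0, color="grey", lw=0.5)
        ax.set_title(coef)
        ax.set_xlabel("grid point")
    axes[0][0].set_ylabel("coefficient")
    axes[0][-1].legend(fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
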