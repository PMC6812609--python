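"""Per-SNP bias screening of fitted clinical-model coefficient tables.

Given a table of per-SNP logistic fits (clinical label as outcome), the
screen evaluates -- SNP by SNP -- how far each coefficient is expected to sit
from its true-risk-scale counterpart under an assumed contamination
configuration.  Two corrections are reported per assumption set:

* ``corrected_*``: the inverse of the linearized approximation map
  (:func:`gxebias.bias_approx.invert_bias`), i.e. the B solving
  gamma(B) = gamma_hat; ``bias_* = gamma_hat - corrected``.
* ``plugin_bias_*``: the approximation evaluated at gamma_hat directly,
  minus gamma_hat.  The two agree to first order; disagreement flags SNPs
  where the linearization is stressed.

Bonferroni flags use the number of screened SNPs as the multiplicity.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .bias_approx import invert_bias
from .risk_models import ContaminationSpec, GammaVector, RiskCoefficients

__all__ = ["ScreenReport", "screen", "REQUIRED_COLUMNS"]

REQUIRED_COLUMNS = ("snp_id", "gamma0_hat", "gammaG_hat", "gammaX_hat", "gammaGxX_hat")

_COEFS = ("gamma0", "gammaG", "gammaX", "gammaGxX")


@dataclass(frozen=True)
class ScreenReport:
    """Screen output: one row per SNP x assumption set."""

    table: pd.DataFrame
    alpha: float
    n_snps: int

    @property
    def bonferroni_threshold(self) -> float:
        return self.alpha / self.n_snps

    def to_csv(self, path: str) -> None:
        self.table.to_csv(path, index=False)


def _validate(fits: pd.DataFrame) -> list[str]:
    missing = [c for c in REQUIRED_COLUMNS if c not in fits.columns]
    if missing:
        raise ValueError(f"fit table is missing required columns: {missing}")
    if fits["snp_id"].duplicated().any():
        dupes = fits.loc[fits["snp_id"].duplicated(), "snp_id"].tolist()
        raise ValueError(f"duplicate snp_id values: {dupes}")
    z_cols = sorted(
        (c for c in fits.columns if c.startswith("gammaZ") and c.endswith("_hat")),
        key=lambda c: int(c[len("gammaZ"):-len("_hat")]),
    )
    for col in fits.columns:
        if col.startswith("p_"):
            vals = fits[col].dropna()
            if ((vals < 0) | (vals > 1)).any():
                raise ValueError(f"p-values in column {col!r} outside [0, 1]")
    return z_cols


def _gamma_from_row(row: pd.Series, z_cols: Sequence[str]) -> GammaVector:
    return GammaVector(
        gamma0=float(row["gamma0_hat"]),
        gammaG=float(row["gammaG_hat"]),
        gammaX=float(row["gammaX_hat"]),
        gammaGxX=float(row["gammaGxX_hat"]),
        gammaZ=tuple(float(row[c]) for c in z_cols),
        provenance="mle",
    )


def screen(
    fits: pd.DataFrame,
    contamination: ContaminationSpec,
    model2_assumptions: RiskCoefficients | Mapping[str, float] | None = None,
    alpha: float = 0.05,
) -> ScreenReport:
    """Screen a per-SNP fit table for contamination bias.

    Parameters
    ----------
    fits : pandas.DataFrame
        Required columns: ``snp_id``, ``gamma0_hat``, ``gammaG_hat``,
        ``gammaX_hat``, ``gammaGxX_hat``.  Optional: ``gammaZk_hat`` columns
        and ``p_<coefficient>`` p-value columns.
    contamination : ContaminationSpec
        Contamination rates for the model-1 assumption set.
    model2_assumptions : RiskCoefficients or mapping, optional
        Nuisance-state coefficients (beta0*, betaG*, betaX*, betaGxX*) to add
        a trinomial assumption set.  No defaults are invented: omit to skip.
    alpha : float
        Familywise level for the Bonferroni flags (threshold alpha / n SNPs).

    Returns
    -------
    ScreenReport
        ``table`` has ``len(fits) * n_assumption_sets`` rows with corrected
        estimates, inversion bias, plug-in bias, and per-coefficient
        Bonferroni significance flags wherever a p-value column is present.
    """
    z_cols = _validate(fits)
    if isinstance(model2_assumptions, Mapping):
        model2_assumptions = RiskCoefficients(
            beta0=float(model2_assumptions["beta0"]),
            betaG=float(model2_assumptions["betaG"]),
            betaX=float(model2_assumptions["betaX"]),
            betaGxX=float(model2_assumptions["betaGxX"]),
        )
    assumption_sets: list[tuple[str, ContaminationSpec | RiskCoefficients]] = [
        ("model1", contamination)
    ]
    if model2_assumptions is not None:
        assumption_sets.append(("model2", model2_assumptions))

    m = len(fits)
    threshold = alpha / m
    p_cols = {c[len("p_"):]: c for c in fits.columns if c.startswith("p_")}
    coef_names = list(_COEFS) + [c[: -len("_hat")] for c in z_cols]

    rows = []
    for _, fit_row in fits.iterrows():
        gamma_hat = _gamma_from_row(fit_row, z_cols)
        for assumption, spec in assumption_sets:
            out = {"snp_id": fit_row["snp_id"], "assumption": assumption}
            try:
                inv = invert_bias(gamma_hat, spec)
                corrected = dict(zip(coef_names, inv.corrected.as_array()))
                converged = inv.converged
                plugin = inv.plugin_bias
            except RuntimeError:
                corrected = dict.fromkeys(coef_names, float("nan"))
                converged = False
                plugin = dict.fromkeys(coef_names, float("nan"))
            hat = gamma_hat.as_dict()
            for name in coef_names:
                out[f"{name}_hat"] = hat[name]
                out[f"corrected_{name}"] = corrected[name]
                out[f"bias_{name}"] = hat[name] - corrected[name]
                out[f"plugin_bias_{name}"] = plugin.get(name, float("nan"))
            for name, col in p_cols.items():
                p = fit_row[col]
                out[f"significant_{name}"] = bool(p < threshold) if np.isfinite(p) else False
            out["inversion_converged"] = converged
            rows.append(out)
    return ScreenReport(table=pd.DataFrame(rows), alpha=alpha, n_snps=m)
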