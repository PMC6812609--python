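"""Exact pseudo-true coefficients of the misspecified clinical logistic fit.

The clinical-label logistic model is generally misspecified for both
generative settings; its maximum-likelihood estimator nevertheless converges
to a well-defined pseudo-true parameter, the minimizer of the expected
negative log-likelihood under the retrospective sampling law.  Because every
covariate is binary, the expectation is a finite sum over enumerated cells
and the minimizer is found exactly by Newton iteration on a convex
objective -- no simulation involved.

The sampling law fixes ``pr(DCL=1) = case_fraction`` and draws covariates
from the population conditionals ``pr(cell | DCL=c)``; for a fit that is
saturated in the covariates driving the misspecification, retrospective
sampling shifts only the intercept.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .risk_models import (
    CovariateDistribution,
    DiseaseModel,
    GammaVector,
    cell_probabilities,
)

__all__ = [
    "PseudoTrueProblem",
    "pseudo_true_gamma",
    "sensitivity_sweep",
    "default_fitted_terms",
]


def default_fitted_terms(cov: CovariateDistribution) -> tuple[str, ...]:
    """Intercept, G, X, GxX and every Z main effect present in the distribution."""
    return ("intercept", "g", "x", "gxx", *cov.z_columns)


@dataclass(frozen=True)
class PseudoTrueProblem:
    """A misspecified-fit limit problem: truth, sampling ratio, fitted terms."""

    model: DiseaseModel
    cov: CovariateDistribution
    case_fraction: float = 0.5
    fitted_terms: tuple[str, ...] = ()

    def __post_init__(self) -> None:
        if not 0.0 < self.case_fraction < 1.0:
            raise ValueError(f"case_fraction must lie in (0, 1), got {self.case_fraction}")
        terms = tuple(self.fitted_terms) or default_fitted_terms(self.cov)
        if "intercept" not in terms:
            raise ValueError("fitted_terms must include the intercept")
        object.__setattr__(self, "fitted_terms", terms)


def _design_columns(cells: pd.DataFrame, terms: Sequence[str]) -> np.ndarray:
    cols = []
    for t in terms:
        if t == "intercept":
            cols.append(np.ones(len(cells)))
        elif t == "gxx":
            cols.append((cells["g"] * cells["x"]).to_numpy(dtype=float))
        elif t in cells.columns:
            cols.append(cells[t].to_numpy(dtype=float))
        else:
            raise ValueError(f"unknown fitted term {t!r}")
    return np.column_stack(cols)


def _solve_weighted_logistic(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    tol: float = 1e-12,
    max_iter: int = 200,
) -> tuple[np.ndarray, bool]:
    """Minimize sum w_i * nll(y_i, expit(X_i gamma)) by damped Newton from 0."""

    def nll(gamma: np.ndarray) -> float:
        eta = X @ gamma
        # -y*eta + log(1+e^eta), numerically stable
        return float(np.sum(w * (np.logaddexp(0.0, eta) - y * eta)))

    gamma = np.zeros(X.shape[1])
    value = nll(gamma)
    converged = False
    for _ in range(max_iter):
        p = expit(X @ gamma)
        grad = X.T @ (w * (p - y))
        if np.linalg.norm(grad) <= tol:
            converged = True
            break
        H = X.T @ (X * (w * p * (1.0 - p))[:, None])
        try:
            step = np.linalg.solve(H, -grad)
        except np.linalg.LinAlgError:
            step = -grad  # gradient fallback on a degenerate Hessian
        lam = 1.0
        for _ in range(50):
            candidate = gamma + lam * step
            new_value = nll(candidate)
            if new_value <= value + 1e-15:
                gamma, value = candidate, new_value
                break
            lam *= 0.5
        else:
            break
    return gamma, converged


def pseudo_true_gamma(problem: PseudoTrueProblem) -> GammaVector:
    """Large-sample limit of the clinical logistic fit under case-control sampling.

    Returns
    -------
    GammaVector
        Provenance ``oracle``.  Terms not included in ``fitted_terms`` are
        reported as 0.

    Raises
    ------
    ValueError
        If the clinical-label prevalence is degenerate (0 or 1).
    """
    table = cell_probabilities(problem.model, problem.cov)
    mass = table["mass"].to_numpy()
    p1 = table["p_dcl1"].to_numpy()
    pi1 = float(mass @ p1)
    if not 0.0 < pi1 < 1.0:
        raise ValueError(f"degenerate clinical prevalence pi_dcl(1)={pi1}")

    cf = problem.case_fraction
    # sampling joint law over (cell, DCL): pr(DCL=1)=cf, cells drawn from
    # the population conditional given the label
    w_case = cf * mass * p1 / pi1
    w_ctrl = (1.0 - cf) * mass * (1.0 - p1) / (1.0 - pi1)

    Xmat = _design_columns(table, problem.fitted_terms)
    X = np.vstack([Xmat, Xmat])
    y = np.concatenate([np.ones(len(table)), np.zeros(len(table))])
    w = np.concatenate([w_case, w_ctrl])
    keep = w > 0
    X, y, w = X[keep], y[keep], w[keep]

    gamma, converged = _solve_weighted_logistic(X, y, w)
    if not converged:
        warnings.warn(
            "pseudo-true Newton solve stopped before reaching the gradient "
            "tolerance (possible separation); returning the last iterate",
            RuntimeWarning,
            stacklevel=2,
        )

    values = dict.fromkeys(
        ("intercept", "g", "x", "gxx", *problem.cov.z_columns), 0.0
    )
    values.update(zip(problem.fitted_terms, gamma))
    return GammaVector(
        gamma0=values["intercept"],
        gammaG=values["g"],
        gammaX=values["x"],
        gammaGxX=values["gxx"],
        gammaZ=tuple(values[c] for c in problem.cov.z_columns),
        provenance="oracle",
    )


def sensitivity_sweep(
    problem: PseudoTrueProblem,
    offsets: Sequence[tuple[float, float]],
) -> pd.DataFrame:
    """Oracle coefficients across a grid of contamination-rate offsets.

    Each offset ``(dS0, dS1)`` is added to the model's contamination rates
    and the oracle re-solved; deltas are reported relative to the unshifted
    model (solved whether or not ``(0, 0)`` is on the grid).

    Only meaningful for ``binary_with_contamination`` models, where the
    rates are free parameters.
    """
    if problem.model.kind != "binary_with_contamination":
        raise ValueError("sensitivity_sweep requires a contamination model")

    reference = pseudo_true_gamma(problem).as_dict()
    rows = []
    for dS0, dS1 in offsets:
        shifted = problem.model.with_contamination(
            problem.model.contamination.shifted(dS0, dS1)
        )
        gamma = pseudo_true_gamma(
            PseudoTrueProblem(
                model=shifted,
                cov=problem.cov,
                case_fraction=problem.case_fraction,
                fitted_terms=problem.fitted_terms,
            )
        ).as_dict()
        for name, value in gamma.items():
            rows.append(
                {
                    "dS0": dS0,
                    "dS1": dS1,
                    "coefficient": name,
                    "gamma": value,
                    "delta": value - reference[name],
                }
            )
    return pd.DataFrame(rows)
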