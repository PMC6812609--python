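"""Closed-form approximations to clinical-model coefficients and their bias.

For each true-risk configuration two approximations to the coefficients
``Gamma`` of the misspecified clinical logistic fit are produced:

``theoretical``
    Exact log-contrast expressions.  For the contamination model these are
    contrasts of ``log{(e^eta + S(x)) / (1 - S(x))}`` across the four
    (g, x) cells; for the trinomial model they are contrasts of
    ``log(e^eta + e^eta*)``, which coincide with the exact population
    log-odds of the clinical label.

``linearized``
    The first-order-in-beta working forms: each target coefficient enters
    only through a multiplicative attenuation weight, with the remaining
    log terms evaluated at a zero value of that coefficient.

Non-interacting covariates Z are handled by applying the same linearization
pattern coefficient-wise (the exact enumerated-support oracle in
:mod:`gxebias.pseudo_true` is the normative cross-check for that extension).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit

from .risk_models import (
    MAX_ABS_COEF,
    ContaminationSpec,
    DiseaseModel,
    GammaVector,
    RiskCoefficients,
)

__all__ = [
    "BiasReport",
    "approx_gamma_model1",
    "approx_gamma_model2",
    "approx_gamma_for_model",
    "make_bias_report",
    "remarks_predicates",
    "RemarkResult",
    "invert_bias",
    "BiasInversionResult",
]


def _log_exp_plus(a: float, c: float) -> float:
    """log(e**a + c) for c >= 0, stable for large |a|."""
    if c == 0.0:
        return a
    return float(np.logaddexp(a, math.log(c)))


def _check_coeffs(*arrays: Sequence[float]) -> None:
    for arr in arrays:
        for v in arr:
            if not np.isfinite(v):
                raise ValueError("coefficients must be finite")
            if abs(v) > MAX_ABS_COEF:
                raise ValueError(f"|coefficient| > {MAX_ABS_COEF} is unphysical: {v}")


# ---------------------------------------------------------------------------
# contamination model (binary true state + per-stratum label contamination)
# ---------------------------------------------------------------------------


def _gamma_model1_arrays(
    b: np.ndarray, s0: float, s1: float, bz: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(theoretical, linearized) gamma for the contamination model.

    ``b = (beta0, betaG, betaX, betaGxX)``; returns arrays of length 4+K in
    the order (gamma0, gammaG, gammaX, gammaGxX, gammaZ1..).
    """
    b0, bg, bx, bgx = (float(v) for v in b)

    def lo(g: int, x: int) -> float:
        # population log-odds of the clinical label in cell (g, x), Z at 0
        s = s1 if x == 1 else s0
        eta = b0 + bg * g + bx * x + bgx * g * x
        return _log_exp_plus(eta, s) - math.log1p(-s)

    theo = [
        lo(0, 0),
        lo(1, 0) - lo(0, 0),
        lo(0, 1) - lo(0, 0),
        lo(1, 1) - lo(1, 0) - lo(0, 1) + lo(0, 0),
    ]
    theo += [_log_exp_plus(b0 + bzk, s0) - _log_exp_plus(b0, s0) for bzk in bz]

    # attenuation weight e**a / (e**a + s)
    def w(a: float, s: float) -> float:
        if s == 0.0:
            return 1.0
        return float(expit(a - math.log(s)))

    g0 = math.log((1.0 + s0) / (1.0 - s0)) + b0 / (1.0 + s0)
    gG = w(b0, s0) * bg
    gX = (
        _log_exp_plus(b0, s1)
        - math.log1p(-s1)
        - _log_exp_plus(b0, s0)
        + math.log1p(-s0)
        + w(b0, s1) * bx
    )
    a = b0 + bg + bx  # interaction linearization point (betaGxX = 0)
    gGX = (
        _log_exp_plus(a, s1)
        - _log_exp_plus(b0 + bg, s0)
        - _log_exp_plus(b0 + bx, s1)
        + _log_exp_plus(b0, s0)
        + w(a, s1) * bgx
    )
    lin = [g0, gG, gX, gGX] + [w(b0, s0) * bzk for bzk in bz]
    return np.array(theo), np.array(lin)


def approx_gamma_model1(
    B: RiskCoefficients,
    S: ContaminationSpec,
    Z_effects: Sequence[float] = (),
) -> tuple[GammaVector, GammaVector]:
    """Approximate clinical-model coefficients for the contamination setting.

    Parameters
    ----------
    B : RiskCoefficients
        True-risk coefficients of the D=1-vs-rest logistic model.
    S : ContaminationSpec
        Contamination rates S(0), S(1) in ``[0, 1)``.
    Z_effects : sequence of float, optional
        Non-interacting covariate effects.

    Returns
    -------
    (theoretical, linearized) : tuple of GammaVector
        With S(0)=S(1)=0 both equal ``B`` exactly.
    """
    bz = np.asarray(tuple(Z_effects), dtype=float)
    _check_coeffs(B.as_array(), bz)
    theo, lin = _gamma_model1_arrays(B.as_array(), S.S0, S.S1, bz)
    return (
        GammaVector(*theo[:4], gammaZ=tuple(theo[4:]), provenance="theoretical"),
        GammaVector(*lin[:4], gammaZ=tuple(lin[4:]), provenance="linearized"),
    )


# ---------------------------------------------------------------------------
# trinomial model (separate contrasts for the two pathologic states)
# ---------------------------------------------------------------------------


def _gamma_model2_arrays(
    b: np.ndarray, bs: np.ndarray, bz: np.ndarray, bzs: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """(theoretical, linearized) gamma for the trinomial model."""
    b0, bg, bx, bgx = (float(v) for v in b)
    c0, cg, cx, cgx = (float(v) for v in bs)
    lse = np.logaddexp

    theo = [
        float(lse(b0, c0)),
        float(lse(b0 + bg, c0 + cg) - lse(b0, c0)),
        float(lse(b0 + bx, c0 + cx) - lse(b0, c0)),
        float(
            lse(b0 + bg + bx + bgx, c0 + cg + cx + cgx)
            - lse(b0 + bx, c0 + cx)
            - lse(b0 + bg, c0 + cg)
            + lse(b0, c0)
        ),
    ]
    theo += [
        float(lse(b0 + z, c0 + zs) - lse(b0, c0)) for z, zs in zip(bz, bzs, strict=True)
    ]

    # expit(a - b) = e**a / (e**a + e**b)
    g0 = c0 + b0 / (1.0 + math.exp(c0))
    gG = float(expit(b0 - (c0 + cg))) * bg
    gX = float(expit(b0 - (c0 + cx))) * bx
    a = b0 + bg + bx  # interaction linearization point (betaGxX = 0 in state 1)
    gGX = float(
        lse(a, c0 + cg + cx + cgx)
        - lse(b0 + bx, c0 + cx)
        - lse(b0 + bg, c0 + cg)
        + lse(b0, c0)
        + expit(a - (c0 + cg + cx + cgx)) * bgx
    )
    lin = [g0, gG, gX, gGX] + [
        float(expit(b0 - (c0 + zs))) * z for z, zs in zip(bz, bzs, strict=True)
    ]
    return np.array(theo), np.array(lin)


def approx_gamma_model2(
    B: RiskCoefficients,
    B_star: RiskCoefficients,
    Z_effects: Sequence[float] = (),
    Z_effects_star: Sequence[float] | None = None,
) -> tuple[GammaVector, GammaVector]:
    """Approximate clinical-model coefficients for the trinomial setting.

    The theoretical form is the exact population log-odds contrast of the
    clinical label (the clinical odds in a cell equal ``e^eta + e^eta*``),
    so it agrees with the pseudo-true oracle for saturated fits.
    """
    bz = np.asarray(tuple(Z_effects), dtype=float)
    bzs = bz if Z_effects_star is None else np.asarray(tuple(Z_effects_star), dtype=float)
    _check_coeffs(B.as_array(), B_star.as_array(), bz, bzs)
    theo, lin = _gamma_model2_arrays(B.as_array(), B_star.as_array(), bz, bzs)
    return (
        GammaVector(*theo[:4], gammaZ=tuple(theo[4:]), provenance="theoretical"),
        GammaVector(*lin[:4], gammaZ=tuple(lin[4:]), provenance="linearized"),
    )


def approx_gamma_for_model(model: DiseaseModel) -> tuple[GammaVector, GammaVector]:
    """Dispatch to the approximation matching the model kind."""
    if model.kind == "binary_with_contamination":
        return approx_gamma_model1(model.B, model.contamination, model.Z_effects)
    return approx_gamma_model2(
        model.B, model.B_star, model.Z_effects, model.Z_effects_star
    )


# ---------------------------------------------------------------------------
# bias report
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BiasReport:
    """Per-coefficient true value, both approximations, and bias Gamma - B."""

    table: pd.DataFrame

    def to_csv(self, path: str) -> None:
        self.table.to_csv(path, index=False)


def make_bias_report(model: DiseaseModel) -> BiasReport:
    theo, lin = approx_gamma_for_model(model)
    names = ["gamma0", "gammaG", "gammaX", "gammaGxX"] + [
        f"gammaZ{k + 1}" for k in range(len(model.Z_effects))
    ]
    truth = np.concatenate([model.B.as_array(), np.asarray(model.Z_effects)])
    rows = []
    for name, b, t, l in zip(names, truth, theo.as_array(), lin.as_array()):
        rows.append(
            {
                "coefficient": name,
                "true_beta": b,
                "gamma_theoretical": t,
                "gamma_linearized": l,
                "bias_theoretical": t - b,
                "bias_linearized": l - b,
            }
        )
    return BiasReport(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# remark predicates
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class RemarkResult:
    remark_id: str
    kind: Literal["implication", "caution"]
    applicable: bool
    holds: bool
    detail: str = ""


def remarks_predicates(
    model_kind: Literal["model1", "model2"],
    B: RiskCoefficients,
    B_star_or_S: RiskCoefficients | ContaminationSpec,
    atol: float = 1e-12,
) -> list[RemarkResult]:
    """Evaluate the printed remarks as predicates on the linearized formulas.

    ``implication`` remarks assert a null coefficient is preserved; they are
    vacuously satisfied when the premise does not apply.  ``caution`` remarks
    assert a null coefficient *might not* be preserved; for those ``holds``
    records whether a nonzero value was in fact observed.
    """
    results: list[RemarkResult] = []

    def add(remark_id, kind, applicable, conclusion, detail=""):
        results.append(
            RemarkResult(
                remark_id=remark_id,
                kind=kind,
                applicable=applicable,
                holds=(conclusion if applicable else True)
                if kind == "implication"
                else (applicable and conclusion),
                detail=detail,
            )
        )

    near = lambda v: abs(v) <= atol  # noqa: E731

    if model_kind == "model1":
        if not isinstance(B_star_or_S, ContaminationSpec):
            raise TypeError("model1 remarks need a ContaminationSpec")
        S = B_star_or_S
        theo, lin = approx_gamma_model1(B, S)
        no_contam = S.S0 == 0.0 and S.S1 == 0.0
        nondiff = S.S0 == S.S1
        add(
            "m1_no_contamination_unbiased",
            "implication",
            no_contam,
            bool(
                np.allclose(theo.as_array(), B.as_array(), atol=atol)
                and np.allclose(lin.as_array(), B.as_array(), atol=atol)
            ),
        )
        add("m1_null_G_preserved", "implication", B.betaG == 0.0, near(lin.gammaG))
        add(
            "m1_null_G_not_null_intercept",
            "caution",
            B.betaG == 0.0,
            not near(lin.gamma0 - B.beta0),
            f"gamma0={lin.gamma0:.6g}",
        )
        add(
            "m1_null_X_not_preserved",
            "caution",
            B.betaX == 0.0,
            not near(lin.gammaX),
            f"gammaX={lin.gammaX:.6g}",
        )
        add(
            "m1_null_GxX_not_preserved",
            "caution",
            B.betaGxX == 0.0,
            not near(lin.gammaGxX),
            f"gammaGxX={lin.gammaGxX:.6g}",
        )
        add(
            "m1_null_G_and_GxX_preserved",
            "implication",
            B.betaG == 0.0 and B.betaGxX == 0.0,
            near(lin.gammaG) and near(lin.gammaGxX),
        )
        add(
            "m1_nondifferential_null_X_preserved",
            "implication",
            nondiff and B.betaX == 0.0,
            near(lin.gammaX),
        )
        add(
            "m1_nondifferential_all_null_GxX_preserved",
            "implication",
            nondiff
            and B.beta0 == 0.0
            and B.betaX == 0.0
            and B.betaG == 0.0
            and B.betaGxX == 0.0,
            near(lin.gammaGxX),
        )
        return results

    if model_kind == "model2":
        if not isinstance(B_star_or_S, RiskCoefficients):
            raise TypeError("model2 remarks need the nuisance-state RiskCoefficients")
        Bs = B_star_or_S
        theo, lin = approx_gamma_model2(B, Bs)
        add(
            "m2_null_intercepts_preserved",
            "implication",
            B.beta0 == 0.0 and Bs.beta0 == 0.0,
            near(lin.gamma0),
            # the log-form gives log(2) here; the remark holds for the
            # linearized form only (recorded for transparency)
            f"log-form gamma0={theo.gamma0:.6g}",
        )
        add(
            "m2_null_G_preserved",
            "implication",
            B.betaG == 0.0 and Bs.betaG == 0.0,
            near(lin.gammaG) and near(theo.gammaG),
        )
        add(
            "m2_null_X_preserved",
            "implication",
            B.betaX == 0.0 and Bs.betaX == 0.0,
            near(lin.gammaX) and near(theo.gammaX),
        )
        add(
            "m2_null_G_and_GxX_preserved",
            "implication",
            B.betaG == 0.0
            and B.betaGxX == 0.0
            and Bs.betaG == 0.0
            and Bs.betaGxX == 0.0,
            near(lin.gammaG) and near(lin.gammaGxX),
        )
        add(
            "m2_all_null_GxX_preserved",
            "implication",
            B.betaG == 0.0
            and Bs.betaG == 0.0
            and B.betaX == 0.0
            and Bs.betaX == 0.0
            and B.betaGxX == 0.0
            and Bs.betaGxX == 0.0,
            near(lin.gammaGxX),
        )
        return results

    raise ValueError(f"unknown model_kind {model_kind!r}")


# ---------------------------------------------------------------------------
# bias inversion (correction)
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class BiasInversionResult:
    """Outcome of solving the linearized map gamma(B) = gamma_hat for B."""

    corrected: GammaVector  # provenance 'linearized' map inverse; B-scale values
    converged: bool
    n_iter: int
    residual_norm: float
    plugin_bias: dict[str, float]  # approximation evaluated at gamma_hat, minus gamma_hat


def _linearized_map(
    b_full: np.ndarray,
    model_kind: str,
    S: ContaminationSpec | None,
    B_star: RiskCoefficients | None,
    Z_effects_star: np.ndarray | None,
) -> np.ndarray:
    b, bz = b_full[:4], b_full[4:]
    if model_kind == "model1":
        _, lin = _gamma_model1_arrays(b, S.S0, S.S1, bz)
    else:
        bzs = Z_effects_star if Z_effects_star is not None else bz
        _, lin = _gamma_model2_arrays(b, B_star.as_array(), bz, bzs)
    return lin


def invert_bias(
    gamma_hat: GammaVector,
    assumptions: ContaminationSpec | RiskCoefficients,
    Z_effects_star: Sequence[float] | None = None,
    tol: float = 1e-10,
    max_iter: int = 100,
) -> BiasInversionResult:
    """Correct fitted clinical-model coefficients for contamination bias.

    Solves the linearized approximation map ``gamma(B) = gamma_hat`` for the
    true-scale coefficients ``B`` by a damped Newton iteration (numerical
    Jacobian) started at ``B = gamma_hat``.  With no contamination the map is
    the identity and the input is returned unchanged.

    Parameters
    ----------
    gamma_hat : GammaVector
        Fitted clinical-model coefficients.
    assumptions : ContaminationSpec or RiskCoefficients
        A contamination spec selects the contamination-model map; a
        nuisance-state coefficient vector selects the trinomial map.
    Z_effects_star : sequence of float, optional
        Nuisance-state Z effects for the trinomial map (defaults to shared).

    Raises
    ------
    RuntimeError
        If the iteration has not reduced the residual below ``tol`` after
        ``max_iter`` steps.
    """
    if isinstance(assumptions, ContaminationSpec):
        model_kind, S, B_star = "model1", assumptions, None
    elif isinstance(assumptions, RiskCoefficients):
        model_kind, S, B_star = "model2", None, assumptions
    else:
        raise TypeError("assumptions must be ContaminationSpec or RiskCoefficients")
    bzs = (
        np.asarray(tuple(Z_effects_star), dtype=float)
        if Z_effects_star is not None
        else None
    )

    target = gamma_hat.as_array()
    b = target.copy()
    fun = lambda v: _linearized_map(v, model_kind, S, B_star, bzs) - target  # noqa: E731

    resid = fun(b)
    n_iter = 0
    for n_iter in range(1, max_iter + 1):
        norm = float(np.linalg.norm(resid))
        if norm <= tol:
            break
        # numerical Jacobian: the system is tiny (4+K unknowns)
        eps = 1e-7
        J = np.empty((b.size, b.size))
        for j in range(b.size):
            bp = b.copy()
            bp[j] += eps
            J[:, j] = (fun(bp) - resid) / eps
        try:
            step = np.linalg.solve(J, -resid)
        except np.linalg.LinAlgError:
            step = -resid  # fixed-point fallback
        # damping: halve the step until the residual decreases
        lam = 1.0
        for _ in range(30):
            candidate = b + lam * step
            new_resid = fun(candidate)
            if np.linalg.norm(new_resid) < norm:
                b, resid = candidate, new_resid
                break
            lam *= 0.5
        else:
            break  # no progress possible

    residual_norm = float(np.linalg.norm(resid))
    converged = residual_norm <= tol
    if not converged:
        raise RuntimeError(
            f"bias inversion did not converge after {n_iter} iterations "
            f"(residual norm {residual_norm:.3e})"
        )

    # plug-in bias: approximation evaluated at gamma_hat as if it were B
    plugin_gamma = _linearized_map(target, model_kind, S, B_star, bzs)
    names = ["gamma0", "gammaG", "gammaX", "gammaGxX"] + [
        f"gammaZ{k + 1}" for k in range(target.size - 4)
    ]
    plugin_bias = dict(zip(names, plugin_gamma - target))

    corrected = GammaVector(
        *b[:4], gammaZ=tuple(b[4:]), provenance="linearized"
    )
    return BiasInversionResult(
        corrected=corrected,
        converged=converged,
        n_iter=n_iter,
        residual_norm=residual_norm,
        plugin_bias=plugin_bias,
    )
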