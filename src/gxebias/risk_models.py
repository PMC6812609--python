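"""Domain types and exact probability computations for the two generative settings.

Two true-risk configurations are supported:

``binary_with_contamination``
    A logistic model for the pathologic state of interest (D=1) against
    everything else, together with per-environment-stratum contamination
    rates ``S(x) = pr(D=0 | DCL=1, X=x)`` describing how often a clinically
    labelled case is not a true case.  The clinical label has perfect
    sensitivity (every true case is clinically diagnosed) and the per-cell
    false-positive mass is calibrated so that ``S(x)`` holds exactly within
    every covariate cell, not just marginally.

``trinomial``
    A three-state multinomial-logit model with separate logistic contrasts
    for the disease of interest (D=1) and the nuisance state (D=1*) against
    healthy (D=0).  The clinical label is ``DCL=1`` iff ``D in {1, 1*}``;
    contamination rates are induced rather than specified.

All covariates are binary with independent components, so every probability
is computed exactly by enumerating the finite covariate support.
"""

from __future__ import annotations

import hashlib
import itertools
import json
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
import pandas as pd
import yaml

__all__ = [
    "GenotypeModel",
    "CovariateDistribution",
    "RiskCoefficients",
    "ContaminationSpec",
    "DiseaseModel",
    "StudyDesign",
    "GammaVector",
    "PopulationRates",
    "InfeasibleContaminationError",
    "hwe_probabilities",
    "cell_probabilities",
    "derive_population_rates",
    "load_config",
    "model_config_hash",
]

#: maximum |coefficient| accepted anywhere; larger values are unphysical on
#: the log-odds scale and break the numerics of exp().
MAX_ABS_COEF = 20.0


class InfeasibleContaminationError(ValueError):
    """Raised when a covariate cell cannot support the requested contamination.

    Under perfect sensitivity the clinical-case probability in a cell is
    ``p1 / (1 - S(x))``; if the true-case probability ``p1`` exceeds
    ``1 - S(x)`` no false-positive rate can realize ``S(x)`` in that cell.
    """


def hwe_probabilities(theta: float) -> tuple[float, float, float]:
    """Genotype frequencies (AA, Aa, aa) under Hardy-Weinberg equilibrium.

    Parameters
    ----------
    theta : float
        Minor-allele frequency in ``[0, 1]``.

    Returns
    -------
    tuple of float
        ``((1-theta)**2, 2*theta*(1-theta), theta**2)``.
    """
    if not 0.0 <= theta <= 1.0:
        raise ValueError(f"allele frequency must lie in [0, 1], got {theta}")
    return ((1.0 - theta) ** 2, 2.0 * theta * (1.0 - theta), theta**2)


@dataclass(frozen=True)
class GenotypeModel:
    """Genotype indicator model: allele frequency plus indicator coding."""

    theta: float
    coding: Literal["raw_bernoulli", "dominant_carrier", "recessive"] = "raw_bernoulli"

    def __post_init__(self) -> None:
        if not 0.0 <= self.theta <= 1.0:
            raise ValueError(f"theta must lie in [0, 1], got {self.theta}")
        if self.coding not in ("raw_bernoulli", "dominant_carrier", "recessive"):
            raise ValueError(f"unknown genotype coding {self.coding!r}")

    @property
    def indicator_frequency(self) -> float:
        """Frequency of the binary genotype indicator G=1."""
        if self.coding == "raw_bernoulli":
            return self.theta
        p_aa, p_het, p_hom = hwe_probabilities(self.theta)
        if self.coding == "dominant_carrier":
            return p_het + p_hom  # 1 - (1-theta)^2
        return p_hom  # recessive: theta^2


@dataclass(frozen=True)
class CovariateDistribution:
    """Joint law of (G, X, Z1..ZK) as independent binary components."""

    genotype: GenotypeModel
    env_freq: float
    covariate_freqs: tuple[float, ...] = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "covariate_freqs", tuple(self.covariate_freqs))
        if not 0.0 <= self.env_freq <= 1.0:
            raise ValueError(f"env_freq must lie in [0, 1], got {self.env_freq}")
        for f in self.covariate_freqs:
            if not 0.0 <= f <= 1.0:
                raise ValueError(f"covariate frequency must lie in [0, 1], got {f}")

    @property
    def n_covariates(self) -> int:
        return len(self.covariate_freqs)

    @property
    def z_columns(self) -> list[str]:
        return [f"z{k + 1}" for k in range(self.n_covariates)]

    def cells(self) -> pd.DataFrame:
        """Enumerate the 2**(2+K) support cells with their masses.

        Returns a frame with columns ``g``, ``x``, ``z1``..``zK`` and ``mass``;
        masses sum to 1 exactly up to float rounding.
        """
        pg = self.genotype.indicator_frequency
        freqs = [pg, self.env_freq, *self.covariate_freqs]
        names = ["g", "x", *self.z_columns]
        rows = []
        for values in itertools.product((0, 1), repeat=len(freqs)):
            mass = 1.0
            for v, f in zip(values, freqs):
                mass *= f if v == 1 else 1.0 - f
            rows.append(dict(zip(names, values), mass=mass))
        return pd.DataFrame(rows)


@dataclass(frozen=True)
class RiskCoefficients:
    """Log-odds coefficients (intercept, G, X, GxX) of one logistic contrast."""

    beta0: float
    betaG: float
    betaX: float
    betaGxX: float

    def __post_init__(self) -> None:
        for name, value in self.as_dict().items():
            if not np.isfinite(value):
                raise ValueError(f"{name} must be finite, got {value}")
            if abs(value) > MAX_ABS_COEF:
                raise ValueError(f"|{name}| > {MAX_ABS_COEF} is unphysical, got {value}")

    def as_dict(self) -> dict[str, float]:
        return {
            "beta0": self.beta0,
            "betaG": self.betaG,
            "betaX": self.betaX,
            "betaGxX": self.betaGxX,
        }

    def as_array(self) -> np.ndarray:
        return np.array([self.beta0, self.betaG, self.betaX, self.betaGxX])

    def linear_predictor(
        self,
        g: np.ndarray | float,
        x: np.ndarray | float,
        z: Sequence[np.ndarray | float] = (),
        z_effects: Sequence[float] = (),
    ) -> np.ndarray | float:
        eta = self.beta0 + self.betaG * g + self.betaX * x + self.betaGxX * g * x
        for zk, bz in zip(z, z_effects, strict=True):
            eta = eta + bz * zk
        return eta


@dataclass(frozen=True)
class ContaminationSpec:
    """Per-stratum contamination rates S(x) = pr(D=0 | DCL=1, X=x)."""

    S0: float
    S1: float

    def __post_init__(self) -> None:
        for name, s in (("S0", self.S0), ("S1", self.S1)):
            if not 0.0 <= s < 1.0:
                raise ValueError(
                    f"{name} must lie in [0, 1): S(x)=1 means every clinical case "
                    f"is the nuisance state; got {s}"
                )

    def s(self, x: np.ndarray | int) -> np.ndarray | float:
        return np.where(np.asarray(x) == 1, self.S1, self.S0)[()]

    def tau(self, x: np.ndarray | int) -> np.ndarray | float:
        """tau(x) = 1 - S(x) = pr(D=1 | DCL=1, X=x)."""
        return 1.0 - self.s(x)

    def shifted(self, dS0: float = 0.0, dS1: float = 0.0) -> "ContaminationSpec":
        return ContaminationSpec(self.S0 + dS0, self.S1 + dS1)


@dataclass(frozen=True)
class DiseaseModel:
    """True-risk model: coefficients plus either contamination spec or nuisance contrast.

    ``Z_effects`` are shared between the two contrasts of the trinomial model
    unless ``Z_effects_star`` is given explicitly.
    """

    kind: Literal["binary_with_contamination", "trinomial"]
    B: RiskCoefficients
    B_star: RiskCoefficients | None = None
    Z_effects: tuple[float, ...] = ()
    Z_effects_star: tuple[float, ...] | None = None
    contamination: ContaminationSpec | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "Z_effects", tuple(self.Z_effects))
        if self.Z_effects_star is not None:
            object.__setattr__(self, "Z_effects_star", tuple(self.Z_effects_star))
        if self.kind == "binary_with_contamination":
            if self.contamination is None:
                raise ValueError("binary_with_contamination requires a ContaminationSpec")
            if self.B_star is not None:
                raise ValueError("binary_with_contamination does not take B_star")
        elif self.kind == "trinomial":
            if self.B_star is None:
                raise ValueError("trinomial requires B_star")
            if self.contamination is not None:
                raise ValueError("trinomial induces contamination; do not specify it")
            if self.Z_effects_star is not None and len(self.Z_effects_star) != len(
                self.Z_effects
            ):
                raise ValueError("Z_effects_star length must match Z_effects")
        else:
            raise ValueError(f"unknown model kind {self.kind!r}")

    @property
    def z_effects_star(self) -> tuple[float, ...]:
        """Nuisance-state Z effects (defaults to the shared Z effects)."""
        if self.Z_effects_star is not None:
            return self.Z_effects_star
        return self.Z_effects

    def with_contamination(self, spec: ContaminationSpec) -> "DiseaseModel":
        if self.kind != "binary_with_contamination":
            raise ValueError("only contamination models can swap contamination specs")
        return DiseaseModel(
            kind=self.kind, B=self.B, Z_effects=self.Z_effects, contamination=spec
        )


@dataclass(frozen=True)
class StudyDesign:
    """Retrospective case-control design: fixed control/case counts, replicates, seed."""

    n_controls: int
    n_cases: int
    replicates: int = 1
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_controls < 1 or self.n_cases < 1 or self.replicates < 1:
            raise ValueError("n_controls, n_cases and replicates must all be >= 1")

    @property
    def case_fraction(self) -> float:
        return self.n_cases / (self.n_cases + self.n_controls)


@dataclass(frozen=True)
class GammaVector:
    """Clinical-model coefficients with a record of how they were obtained."""

    gamma0: float
    gammaG: float
    gammaX: float
    gammaGxX: float
    gammaZ: tuple[float, ...] = ()
    provenance: Literal["linearized", "theoretical", "oracle", "mle"] = "theoretical"

    def __post_init__(self) -> None:
        object.__setattr__(self, "gammaZ", tuple(self.gammaZ))
        if not all(np.isfinite(v) for v in self.as_array()):
            raise ValueError("GammaVector entries must be finite")

    def as_array(self) -> np.ndarray:
        return np.array([self.gamma0, self.gammaG, self.gammaX, self.gammaGxX, *self.gammaZ])

    def as_dict(self) -> dict[str, float]:
        out = {
            "gamma0": self.gamma0,
            "gammaG": self.gammaG,
            "gammaX": self.gammaX,
            "gammaGxX": self.gammaGxX,
        }
        for k, v in enumerate(self.gammaZ):
            out[f"gammaZ{k + 1}"] = v
        return out

    def main_slopes(self) -> np.ndarray:
        return np.array([self.gammaG, self.gammaX, self.gammaGxX])


# ---------------------------------------------------------------------------
# exact probability tables
# ---------------------------------------------------------------------------


def _check_consistency(model: DiseaseModel, cov: CovariateDistribution) -> None:
    if len(model.Z_effects) != cov.n_covariates:
        raise ValueError(
            f"model has {len(model.Z_effects)} Z effects but the covariate "
            f"distribution has {cov.n_covariates} Z components"
        )


def cell_probabilities(model: DiseaseModel, cov: CovariateDistribution) -> pd.DataFrame:
    """Exact per-cell state probabilities for a disease model.

    Returns one row per covariate cell with columns

    ``g, x, z1..zK, mass`` -- the cell and its population mass;
    ``p_d0, p_d1, p_d1star`` -- true-state probabilities (``p_d1star`` is 0
    for the binary model);
    ``p_dcl1, p_dcl0`` -- clinical-label probabilities;
    ``p_d1_dcl1, p_d1star_dcl1, p_d0_dcl1, p_d0_dcl0`` -- joint
    (state, label) probabilities used by the simulator.

    Raises
    ------
    InfeasibleContaminationError
        If, for the contamination model, some cell has
        ``p_d1 > 1 - S(x)`` so that ``pr(DCL=1 | cell)`` would exceed 1.
    """
    _check_consistency(model, cov)
    cells = cov.cells()
    g = cells["g"].to_numpy(dtype=float)
    x = cells["x"].to_numpy(dtype=float)
    z = [cells[c].to_numpy(dtype=float) for c in cov.z_columns]

    eta = model.B.linear_predictor(g, x, z, model.Z_effects)
    if model.kind == "trinomial":
        eta_star = model.B_star.linear_predictor(g, x, z, model.z_effects_star)
        # softmax over {0, 1, 1*} with baseline state 0
        denom = 1.0 + np.exp(eta) + np.exp(eta_star)
        p1 = np.exp(eta) / denom
        p1s = np.exp(eta_star) / denom
        p0 = 1.0 / denom
        out = cells.assign(
            p_d0=p0,
            p_d1=p1,
            p_d1star=p1s,
            p_dcl1=p1 + p1s,
            p_dcl0=p0,
            p_d1_dcl1=p1,
            p_d1star_dcl1=p1s,
            p_d0_dcl1=0.0,
            p_d0_dcl0=p0,
        )
    else:
        s = np.asarray(model.contamination.s(cells["x"].to_numpy()), dtype=float)
        p1 = 1.0 / (1.0 + np.exp(-eta))
        p_dcl1 = p1 / (1.0 - s)
        bad = p_dcl1 > 1.0 + 1e-12
        if np.any(bad):
            i = int(np.argmax(bad))
            cell_desc = ", ".join(
                f"{c}={int(cells.iloc[i][c])}" for c in ["g", "x", *cov.z_columns]
            )
            raise InfeasibleContaminationError(
                f"cell ({cell_desc}): pr(D=1)={p1[i]:.4f} exceeds 1-S(x)={1 - s[i]:.4f}; "
                "the requested contamination rate cannot be realized"
            )
        p_dcl1 = np.minimum(p_dcl1, 1.0)
        out = cells.assign(
            p_d0=1.0 - p1,
            p_d1=p1,
            p_d1star=0.0,
            p_dcl1=p_dcl1,
            p_dcl0=1.0 - p_dcl1,
            p_d1_dcl1=p1,
            p_d1star_dcl1=0.0,
            p_d0_dcl1=s * p_dcl1,
            p_d0_dcl0=1.0 - p_dcl1,
        )
    return out


@dataclass(frozen=True)
class PopulationRates:
    """Marginal rates induced by a disease model over a covariate distribution."""

    pi_dcl: dict[int, float]
    pi_d: dict[str, float]
    pr_d_given_x: pd.DataFrame
    induced_S: dict[int, float]
    induced_tau: dict[int, float]

    def as_dict(self) -> dict:
        return {
            "pi_dcl": {str(k): v for k, v in self.pi_dcl.items()},
            "pi_d": dict(self.pi_d),
            "pr_d_given_x": self.pr_d_given_x.to_dict(orient="records"),
            "induced_S": {str(k): v for k, v in self.induced_S.items()},
            "induced_tau": {str(k): v for k, v in self.induced_tau.items()},
        }


def derive_population_rates(
    model: DiseaseModel, cov: CovariateDistribution
) -> PopulationRates:
    """Population marginals: label rates, state rates and induced contamination.

    The induced ``S(x) = pr(D=0 or D=1* | DCL=1, X=x)`` equals the specified
    rates exactly for the contamination model (by the per-cell calibration)
    and is a genuine derived quantity for the trinomial model.
    """
    table = cell_probabilities(model, cov)
    mass = table["mass"].to_numpy()

    pi_dcl1 = float(mass @ table["p_dcl1"])
    pi_d = {
        "0": float(mass @ table["p_d0"]),
        "1": float(mass @ table["p_d1"]),
        "1*": float(mass @ table["p_d1star"]),
    }

    rows = []
    induced_S: dict[int, float] = {}
    induced_tau: dict[int, float] = {}
    for xv, sub in table.groupby("x"):
        m = sub["mass"].to_numpy()
        mx = m.sum()
        p_dcl1_x = float(m @ sub["p_dcl1"]) / mx
        # nuisance-or-healthy mass inside the clinical diagnosis
        not_true = float(m @ (sub["p_d1star_dcl1"] + sub["p_d0_dcl1"])) / mx
        true_in = float(m @ sub["p_d1_dcl1"]) / mx
        s_x = not_true / p_dcl1_x if p_dcl1_x > 0 else float("nan")
        induced_S[int(xv)] = s_x
        induced_tau[int(xv)] = true_in / p_dcl1_x if p_dcl1_x > 0 else float("nan")
        rows.append(
            {
                "x": int(xv),
                "pr_d0": float(m @ sub["p_d0"]) / mx,
                "pr_d1": float(m @ sub["p_d1"]) / mx,
                "pr_d1star": float(m @ sub["p_d1star"]) / mx,
                "pr_dcl1": p_dcl1_x,
            }
        )

    return PopulationRates(
        pi_dcl={0: 1.0 - pi_dcl1, 1: pi_dcl1},
        pi_d=pi_d,
        pr_d_given_x=pd.DataFrame(rows).sort_values("x").reset_index(drop=True),
        induced_S=induced_S,
        induced_tau=induced_tau,
    )


# ---------------------------------------------------------------------------
# configuration (de)serialization
# ---------------------------------------------------------------------------


def _coeffs_from_dict(d: dict) -> RiskCoefficients:
    return RiskCoefficients(
        beta0=float(d["beta0"]),
        betaG=float(d["betaG"]),
        betaX=float(d["betaX"]),
        betaGxX=float(d.get("betaGxX", 0.0)),
    )


def disease_model_from_dict(d: dict) -> DiseaseModel:
    kind = d["kind"]
    contamination = None
    b_star = None
    if "contamination" in d and d["contamination"] is not None:
        c = d["contamination"]
        contamination = ContaminationSpec(S0=float(c["S0"]), S1=float(c["S1"]))
    if "B_star" in d and d["B_star"] is not None:
        b_star = _coeffs_from_dict(d["B_star"])
    return DiseaseModel(
        kind=kind,
        B=_coeffs_from_dict(d["B"]),
        B_star=b_star,
        Z_effects=tuple(float(v) for v in d.get("Z_effects", ())),
        Z_effects_star=(
            tuple(float(v) for v in d["Z_effects_star"])
            if d.get("Z_effects_star") is not None
            else None
        ),
        contamination=contamination,
    )


def covariates_from_dict(d: dict) -> CovariateDistribution:
    geno = d["genotype"]
    return CovariateDistribution(
        genotype=GenotypeModel(
            theta=float(geno["theta"]), coding=geno.get("coding", "raw_bernoulli")
        ),
        env_freq=float(d["env_freq"]),
        covariate_freqs=tuple(float(v) for v in d.get("covariate_freqs", ())),
    )


def design_from_dict(d: dict) -> StudyDesign:
    return StudyDesign(
        n_controls=int(d["n_controls"]),
        n_cases=int(d["n_cases"]),
        replicates=int(d.get("replicates", 1)),
        seed=int(d.get("seed", 0)),
    )


def load_config(path: str) -> dict:
    """Load a YAML/JSON config into instantiated model/covariates/design objects.

    Recognized top-level keys: ``model``, ``covariates``, ``design`` (each
    optional); anything else is passed through untouched.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh)
    out = dict(raw)
    if "model" in raw:
        out["model"] = disease_model_from_dict(raw["model"])
    if "covariates" in raw:
        out["covariates"] = covariates_from_dict(raw["covariates"])
    if "design" in raw:
        out["design"] = design_from_dict(raw["design"])
    return out


def model_config_hash(model: DiseaseModel, cov: CovariateDistribution) -> str:
    """Stable short hash of a (model, covariates) configuration."""
    payload = {
        "kind": model.kind,
        "B": model.B.as_dict(),
        "B_star": model.B_star.as_dict() if model.B_star is not None else None,
        "Z_effects": list(model.Z_effects),
        "Z_effects_star": (
            list(model.Z_effects_star) if model.Z_effects_star is not None else None
        ),
        "contamination": (
            {"S0": model.contamination.S0, "S1": model.contamination.S1}
            if model.contamination is not None
            else None
        ),
        "genotype": {"theta": cov.genotype.theta, "coding": cov.genotype.coding},
        "env_freq": cov.env_freq,
        "covariate_freqs": list(cov.covariate_freqs),
    }
    return hashlib.sha256(json.dumps(payload, sort_keys=True).encode()).hexdigest()[:16]
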