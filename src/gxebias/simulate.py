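"""Retrospective case-control simulator with latent pathologic state.

Sampling is exact: the joint law of (covariate cell, true state, clinical
label) is enumerated, conditioned on the label, and the fixed numbers of
cases and controls are drawn by a single multinomial per arm -- no rejection
sampling, and the case/control counts are met exactly.  The latent true
state is kept in the output (coded 0 = healthy, 1 = disease of interest,
2 = nuisance state) so tests can verify contamination rates; estimation
routines must ignore it.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Mapping

import json
import numpy as np
import pandas as pd

from .risk_models import (
    CovariateDistribution,
    DiseaseModel,
    RiskCoefficients,
    StudyDesign,
    cell_probabilities,
    model_config_hash,
)

__all__ = [
    "SimulatedDataset",
    "simulate_dataset",
    "SnpEffectSpec",
    "SnpScreenFixture",
    "make_snp_screen_fixture",
]

#: integer coding of the latent state in the output table
D_TRUE_CODES = {"healthy": 0, "disease": 1, "nuisance": 2}


@dataclass(frozen=True)
class SimulatedDataset:
    """One simulated case-control dataset plus provenance metadata."""

    data: pd.DataFrame  # columns: dcl, d_true, g, x, z1..zK
    meta: dict

    @property
    def n_cases(self) -> int:
        return int(self.meta["n_cases"])

    @property
    def n_controls(self) -> int:
        return int(self.meta["n_controls"])

    @property
    def z_columns(self) -> list[str]:
        return [c for c in self.data.columns if c.startswith("z")]

    def to_csv(self, path: str, sidecar: str | None = None) -> None:
        """Write rows as CSV; optionally write metadata as a JSON sidecar."""
        self.data.to_csv(path, index=False)
        if sidecar is not None:
            with open(sidecar, "w") as fh:
                json.dump({**self.meta, "d_true_codes": D_TRUE_CODES}, fh, indent=2)


def _rng_for_replicate(design: StudyDesign, replicate_index: int) -> np.random.Generator:
    # per-replicate stream derived deterministically from (seed, index)
    return np.random.default_rng(
        np.random.SeedSequence(entropy=design.seed, spawn_key=(replicate_index,))
    )


def simulate_dataset(
    model: DiseaseModel,
    cov: CovariateDistribution,
    design: StudyDesign,
    replicate_index: int = 0,
) -> SimulatedDataset:
    """Draw one retrospective case-control dataset.

    Exactly ``design.n_cases`` rows have ``dcl=1`` and ``design.n_controls``
    have ``dcl=0``; controls are always ``d_true=0``.  The generator state is
    a deterministic function of ``(design.seed, replicate_index)``.
    """
    if not 0 <= replicate_index < design.replicates:
        raise ValueError(
            f"replicate_index {replicate_index} outside [0, {design.replicates})"
        )
    table = cell_probabilities(model, cov)
    mass = table["mass"].to_numpy()
    covariate_cols = ["g", "x", *cov.z_columns]

    # joint atoms (cell, d_true, dcl): stack the three possible latent states
    joints = []
    for code, col, dcl in (
        (D_TRUE_CODES["disease"], "p_d1_dcl1", 1),
        (D_TRUE_CODES["nuisance"], "p_d1star_dcl1", 1),
        (D_TRUE_CODES["healthy"], "p_d0_dcl1", 1),
        (D_TRUE_CODES["healthy"], "p_d0_dcl0", 0),
    ):
        prob = mass * table[col].to_numpy()
        sub = table[covariate_cols].assign(d_true=code, dcl=dcl, prob=prob)
        joints.append(sub)
    atoms = pd.concat(joints, ignore_index=True)
    atoms = atoms[atoms["prob"] > 0].reset_index(drop=True)

    rng = _rng_for_replicate(design, replicate_index)
    parts = []
    for dcl_value, n_draw in ((1, design.n_cases), (0, design.n_controls)):
        arm = atoms[atoms["dcl"] == dcl_value]
        if arm.empty:
            raise ValueError(f"zero-mass conditional law for dcl={dcl_value}")
        p = arm["prob"].to_numpy()
        counts = rng.multinomial(n_draw, p / p.sum())
        expanded = arm.loc[arm.index.repeat(counts)].drop(columns="prob")
        parts.append(expanded)
    data = pd.concat(parts, ignore_index=True)
    # deterministic shuffle so row order carries no arm/cell structure
    data = data.sample(frac=1.0, random_state=np.random.RandomState(rng.integers(2**31)))
    data = data[["dcl", "d_true", *covariate_cols]].reset_index(drop=True)

    meta = {
        "seed": design.seed,
        "replicate_index": replicate_index,
        "model_config_hash": model_config_hash(model, cov),
        "n_controls": design.n_controls,
        "n_cases": design.n_cases,
    }
    return SimulatedDataset(data=data, meta=meta)


# ---------------------------------------------------------------------------
# SNP-screen fixture
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class SnpEffectSpec:
    """Effect layout for a synthetic multi-SNP screen.

    ``base_model`` supplies intercepts, environment and covariate effects
    shared by all SNPs; by default every SNP is null (betaG = betaGxX = 0)
    and ``nonnull`` maps SNP indices to (betaG, betaGxX) overrides.
    """

    base_model: DiseaseModel
    nonnull: Mapping[int, tuple[float, float]] = None  # type: ignore[assignment]

    def __post_init__(self) -> None:
        object.__setattr__(self, "nonnull", dict(self.nonnull or {}))

    def model_for_snp(self, index: int) -> DiseaseModel:
        betaG, betaGxX = self.nonnull.get(index, (0.0, 0.0))
        base = self.base_model
        B = RiskCoefficients(
            beta0=base.B.beta0, betaG=betaG, betaX=base.B.betaX, betaGxX=betaGxX
        )
        return replace(base, B=B)


@dataclass(frozen=True)
class SnpScreenFixture:
    """Per-SNP simulated datasets plus the generating truth table."""

    datasets: list[SimulatedDataset]
    truth: pd.DataFrame

    @property
    def n_snps(self) -> int:
        return len(self.datasets)


def make_snp_screen_fixture(
    n_snps: int,
    cov: CovariateDistribution,
    design: StudyDesign,
    effect_spec: SnpEffectSpec,
) -> SnpScreenFixture:
    """Generate a synthetic multi-SNP screen with a known truth table.

    Each SNP gets an independent dataset drawn under its own true model
    (replicate index = SNP index), sharing the environment/covariate
    distribution; the truth table records the generating coefficients.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    if design.replicates < n_snps:
        design = StudyDesign(
            n_controls=design.n_controls,
            n_cases=design.n_cases,
            replicates=n_snps,
            seed=design.seed,
        )
    datasets = []
    rows = []
    for j in range(n_snps):
        model = effect_spec.model_for_snp(j)
        datasets.append(simulate_dataset(model, cov, design, replicate_index=j))
        row = {"snp_id": f"snp{j:04d}", "kind": model.kind, **model.B.as_dict()}
        if model.B_star is not None:
            row.update({f"{k}_star": v for k, v in model.B_star.as_dict().items()})
        for k, bz in enumerate(model.Z_effects):
            row[f"betaZ{k + 1}"] = bz
        rows.append(row)
    return SnpScreenFixture(datasets=datasets, truth=pd.DataFrame(rows))
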