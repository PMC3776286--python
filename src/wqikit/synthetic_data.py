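"""Synthetic drinking-water datasets with block correlation and missingness.

The generator emulates the structure a national drinking-water survey
exhibits: groups of parameters that co-vary because they share a
hydrochemical driver.  Latent standard normals are drawn with an
equicorrelated block structure — a salinity block (magnesium, chloride,
TDS, fluoride, sulfate, sodium) reflecting the groundwater mineralization
gradient, a calcium + manganese block (carbonate alkalinity), a nitrate +
turbidity block (domestic/agricultural surface impact) and independent
ammonium, iron and pH — then mapped through exp() to strictly positive
lognormal concentrations.  pH is drawn from a normal truncated to (0, 14].
Missingness is MCAR, independent per cell, which is the weakest mechanism
that still exercises the dynamic-weight renormalization downstream.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .dataset_io import Dataset
from .wqi_core import MISSING, CriteriaSet, SampleRecord, default_criteria

__all__ = ["Block", "SyntheticConfig", "default_config", "generate"]


@dataclass(frozen=True)
class Block:
    """A group of parameters sharing one equicorrelation coefficient."""

    parameters: tuple[str, ...]
    rho: float

    def __post_init__(self) -> None:
        if not 0 <= self.rho < 1:
            raise ValueError(f"block correlation must be in [0, 1), got {self.rho}")
        if len(self.parameters) == 0:
            raise ValueError("block needs at least one parameter")


@dataclass(frozen=True)
class SyntheticConfig:
    """Full recipe for one synthetic dataset.

    ``marginal_log_mean`` / ``marginal_log_sd`` give each non-pH
    parameter's lognormal marginal on the log-concentration scale; pH has
    its own (truncated-normal) mean and sd in pH units.  ``missing_rate``
    is the per-cell MCAR probability, either one number for all parameters
    or a per-parameter mapping.
    """

    n: int
    seed: int
    blocks: Mapping[str, Block]
    marginal_log_mean: Mapping[str, float]
    marginal_log_sd: Mapping[str, float]
    ph_mean: float = 7.5
    ph_sd: float = 0.5
    ph_name: str = "pH"
    missing_rate: float | Mapping[str, float] = 0.0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be >= 1")
        names: list[str] = []
        for block in self.blocks.values():
            names.extend(block.parameters)
        if len(set(names)) != len(names):
            raise ValueError("block parameter lists must be disjoint")
        for name in names:
            if name == self.ph_name:
                continue
            if name not in self.marginal_log_mean or name not in self.marginal_log_sd:
                raise ValueError(f"parameter {name!r} lacks marginal log mean/sd")
        for name, rate in self._rates().items():
            if not 0 <= rate < 1:
                raise ValueError(f"missing rate for {name!r} must be in [0, 1)")

    @property
    def parameter_names(self) -> tuple[str, ...]:
        names: list[str] = []
        for block in self.blocks.values():
            names.extend(block.parameters)
        return tuple(names)

    def _rates(self) -> dict[str, float]:
        if isinstance(self.missing_rate, Mapping):
            return {n: float(self.missing_rate.get(n, 0.0)) for n in self.parameter_names}
        return {n: float(self.missing_rate) for n in self.parameter_names}

    def ph_is_correlated(self) -> bool:
        for block in self.blocks.values():
            if self.ph_name in block.parameters and len(block.parameters) > 1 and block.rho > 0:
                return True
        return False


def default_config(n: int = 735, seed: int = 1, missing_rate: float = 0.05) -> SyntheticConfig:
    """Study-condition defaults for the 13 bundled criteria parameters.

    Lognormal medians sit near half the guideline limits, so most samples
    score below 100 (predominantly excellent/good water) with a right tail
    of degraded samples; n defaults to 735 samples, matching a national
    survey scale.
    """
    criteria = default_criteria()
    limits = {p.name: p.limit for p in criteria if p.limit_kind == "upper_limit" and p.included}
    log_sd = 0.6  # right-skewed, ~95% of samples within a factor ~3.2 of the median
    return SyntheticConfig(
        n=n,
        seed=seed,
        blocks={
            "salinity": Block(
                ("magnesium", "chloride", "tds", "fluoride", "sulfate", "sodium"), 0.85
            ),
            "alkalinity": Block(("calcium", "manganese"), 0.6),
            "surface_impact": Block(("nitrate", "turbidity"), 0.6),
            "ammonium": Block(("ammonium",), 0.0),
            "iron": Block(("iron",), 0.0),
            "ph": Block(("pH",), 0.0),
        },
        marginal_log_mean={n_: math.log(lim / 2) for n_, lim in limits.items()},
        marginal_log_sd={n_: log_sd for n_ in limits},
        ph_mean=7.5,
        ph_sd=0.5,
        missing_rate=missing_rate,
    )


def _correlation_matrix(config: SyntheticConfig) -> np.ndarray:
    names = config.parameter_names
    idx = {name: i for i, name in enumerate(names)}
    R = np.eye(len(names))
    for block in config.blocks.values():
        for a in block.parameters:
            for b in block.parameters:
                if a != b:
                    R[idx[a], idx[b]] = block.rho
    return R


def _truncated_normal(
    rng: np.random.Generator, mean: float, sd: float, low: float, high: float, size: int
) -> np.ndarray:
    """Rejection-sample a truncated normal; fine for mild truncation."""
    out = rng.normal(mean, sd, size)
    bad = (out <= low) | (out > high)
    while bad.any():
        out[bad] = rng.normal(mean, sd, int(bad.sum()))
        bad = (out <= low) | (out > high)
    return out


def generate(config: SyntheticConfig, criteria: CriteriaSet | None = None) -> Dataset:
    """Draw one synthetic dataset; byte-identical for identical (config, seed).

    Raises before sampling if the implied block correlation matrix is not
    positive definite.
    """
    names = config.parameter_names
    R = _correlation_matrix(config)
    try:
        chol = np.linalg.cholesky(R)
    except np.linalg.LinAlgError as exc:
        raise ValueError("implied correlation matrix is not positive definite") from exc

    if config.ph_is_correlated():
        # correlated pH would need a copula map onto the truncated-normal
        # marginal; keep pH in a singleton block instead
        raise ValueError("pH must be in a singleton block")

    rng = np.random.default_rng(config.seed)
    Z = rng.standard_normal((config.n, len(names))) @ chol.T

    data = np.empty_like(Z)
    for j, name in enumerate(names):
        if name == config.ph_name:
            data[:, j] = _truncated_normal(
                rng, config.ph_mean, config.ph_sd, 0.0, 14.0, config.n
            )
        else:
            mu = config.marginal_log_mean[name]
            sd = config.marginal_log_sd[name]
            data[:, j] = np.exp(mu + sd * Z[:, j])

    rates = config._rates()
    mask = np.zeros_like(data, dtype=bool)
    for j, name in enumerate(names):
        if rates[name] > 0:
            mask[:, j] = rng.random(config.n) < rates[name]

    width = len(str(config.n))
    records = []
    for i in range(config.n):
        values = {
            name: (MISSING if mask[i, j] else float(data[i, j]))
            for j, name in enumerate(names)
        }
        records.append(SampleRecord(sample_id=f"S{i + 1:0{width}d}", values=values))

    return Dataset(
        criteria=criteria or default_criteria(),
        records=records,
        provenance={"source": "synthetic", "seed": config.seed, "n": config.n},
    )
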