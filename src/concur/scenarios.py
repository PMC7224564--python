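"""Replicated simulation scenarios: type-I error and power pipelines.

Each replicate generates a synthetic population, draws a case-control
phenotype from the logistic segment model, samples the requested numbers of
cases and controls, and runs the CONCUR test adjusting for the simulated
binary covariate.  All randomness flows through per-replicate substreams
spawned from one seed, so scenarios are reproducible and individual
replicates are independent.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence

import numpy as np
from scipy.special import expit

from .assoc import PhenotypeTable, concur_test
from .cnv_io import CNVDataset
from .curves import DosageTransform
from .simulate import (
    CausalAssignment,
    EffectConfig,
    TGPParams,
    TWBParams,
    build_segments,
    case_control_sample,
    design_matrices,
    generate_tgp_like,
    generate_twb_like,
    linear_predictor,
    null_disease_rate,
    select_causal,
    simulate_phenotype,
)

__all__ = ["ScenarioConfig", "null_pvalues", "power_curve", "rejection_rates"]


@dataclass
class ScenarioConfig:
    """One simulation scenario (a row of a scenario table).

    ``style`` picks the cohort generator; ``causal_counts`` and ``dp_mix``
    configure the causal-segment draw; ``effect_sizes`` is the grid of
    causal log-OR magnitudes (per kb for a dosage-x-length signal).  The
    population size per replicate is derived from the case/control quotas
    and the baseline disease rate, with head-room for sampling noise.
    """

    style: Literal["tgp", "twb"] = "tgp"
    n_case: int = 250
    n_control: int = 250
    n_replicates: int = 1000
    gamma0: float = -2.0
    beta_x: float = math.log(1.1)
    causal_counts: tuple[int, int] = (20, 20)
    dp_mix: tuple[float, float, float, float] = (90.0, 10.0, 90.0, 10.0)
    signal: Literal["dosage", "dosage_x_length"] = "dosage_x_length"
    effect_sizes: tuple[float, ...] = ()
    coding: Literal["categorical", "continuous"] = "categorical"
    seed: int = 0
    generator_params: TGPParams | TWBParams | None = None

    def population_size(self) -> int:
        rate = null_disease_rate(self.gamma0, self.beta_x)
        need = max(self.n_case / rate, self.n_control / (1.0 - rate))
        return int(need * 1.4) + 200

    def generate(self, n: int, rng: np.random.Generator) -> CNVDataset:
        if self.style == "tgp":
            return generate_tgp_like(n, self.generator_params, rng)
        return generate_twb_like(n, self.generator_params, rng)


def _null_replicate(config: ScenarioConfig, rng: np.random.Generator) -> float:
    """One null replicate: covariate-only phenotype, no CNV effect."""
    n_pop = config.population_size()
    for attempt in range(3):
        dataset = config.generate(n_pop, rng)
        X = rng.binomial(1, 0.5, size=n_pop).astype(float)
        eta = config.gamma0 + config.beta_x * X
        Y = rng.binomial(1, expit(eta)).astype(float)
        try:
            idx = case_control_sample(Y, config.n_case, config.n_control, rng)
            break
        except ValueError:
            n_pop *= 2
    else:  # pragma: no cover
        raise RuntimeError("could not meet case-control quotas")
    sample_ids = [dataset.roster[i] for i in idx]
    sub = dataset.subset_samples(sample_ids)
    phen = PhenotypeTable(sample_ids, Y[idx], "binary", X[idx], ["x"])
    return concur_test(sub, phen, DosageTransform.from_mode(dataset.mode)).p_value


def null_pvalues(config: ScenarioConfig) -> np.ndarray:
    """P-values from ``n_replicates`` independent null simulations."""
    streams = np.random.SeedSequence(config.seed).spawn(config.n_replicates)
    return np.array(
        [_null_replicate(config, np.random.default_rng(s)) for s in streams]
    )


def _power_replicate(
    config: ScenarioConfig, effect_size: float, rng: np.random.Generator
) -> float:
    """One alternative replicate: causal segments drawn afresh, phenotype
    from the segment model, case-control sampling, then the test."""
    n_pop = config.population_size()
    for attempt in range(3):
        dataset = config.generate(n_pop, rng)
        segments = build_segments(dataset)
        design = design_matrices(segments, config.coding)
        causal = select_causal(
            segments, config.causal_counts, config.dp_mix, seed=rng
        )
        effect = EffectConfig(
            gamma0=config.gamma0,
            beta_x=config.beta_x,
            effect_size=effect_size,
            signal=config.signal,
        )
        Y, X = simulate_phenotype(design, causal, effect, rng)
        try:
            idx = case_control_sample(Y, config.n_case, config.n_control, rng)
            break
        except ValueError:
            n_pop *= 2
    else:  # pragma: no cover
        raise RuntimeError("could not meet case-control quotas")
    sample_ids = [dataset.roster[i] for i in idx]
    sub = dataset.subset_samples(sample_ids)
    phen = PhenotypeTable(sample_ids, Y[idx], "binary", X[idx], ["x"])
    return concur_test(sub, phen, DosageTransform.from_mode(dataset.mode)).p_value


def power_curve(
    config: ScenarioConfig, alpha: float = 0.05
) -> dict[float, float]:
    """Empirical rejection rate at each effect size in the grid."""
    out: dict[float, float] = {}
    root = np.random.SeedSequence(config.seed)
    grids = root.spawn(len(config.effect_sizes))
    for effect_size, grid_seed in zip(config.effect_sizes, grids):
        streams = grid_seed.spawn(config.n_replicates)
        pvals = np.array(
            [
                _power_replicate(config, effect_size, np.random.default_rng(s))
                for s in streams
            ]
        )
        out[effect_size] = float(np.mean(pvals < alpha))
    return out


def rejection_rates(pvalues: np.ndarray, alphas: Sequence[float]) -> dict[float, float]:
    """Fraction of p-values below each nominal level."""
    p = np.asarray(pvalues)
    return {a: float(np.mean(p < a)) for a in alphas}
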