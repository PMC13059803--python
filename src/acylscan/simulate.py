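"""Synthetic LFQ experiments with known ground truth.

The generator emulates the shape of a bait-versus-empty-vector acylation
screen: log-normally distributed protein abundances, a minority "prey"
subset whose intensity is multiplied by ``2**log2fc`` in the baits that
acylate it, multiplicative replicate noise, and intensity-dependent
(left-censored) missingness — detection probability is logistic in log2
intensity, so low-abundance measurements are preferentially lost, which is
the premise of bottom-decile imputation downstream.

Generation is a pure function of (config, seed): identical inputs give
bit-identical matrices.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy.special import expit

from .matrix import DEFAULT_CONTROL_LABEL, LFQMatrix, SampleDescriptor

DEFAULT_BAITS = ("IcsB", "H1", "H2", "H3", "H4", "H5", "H6", "H7")


@dataclass(frozen=True)
class SimConfig:
    """Parameters of the synthetic acylation screen.

    Defaults mirror the study shape: 8 baits plus the empty-vector control,
    4 biological replicates per condition with 3 for one designated bait,
    ~1,500 quantified proteins, ~5% prey with a mean effect of 2 on the
    log2 scale.
    """

    n_proteins: int = 1500
    baits: tuple[str, ...] = DEFAULT_BAITS
    reps_per_condition: int = 4
    short_rep_bait: str | None = "IcsB"  # this bait gets one replicate fewer
    log2_abundance_mean: float = 23.0
    log2_abundance_sd: float = 2.0
    noise_sd_log2: float = 0.3
    prey_fraction: float = 0.05
    prey_log2fc_mean: float = 2.0
    prey_log2fc_sd: float = 0.5
    shared_prey_fraction: float = 0.3
    censor_midpoint_log2: float = 19.5
    censor_steepness: float = 1.0
    control_label: str = DEFAULT_CONTROL_LABEL
    seed: int = 0

    def __post_init__(self) -> None:
        if not self.baits:
            raise ValueError("baits list must be non-empty")
        if self.n_proteins <= 0:
            raise ValueError("n_proteins must be positive")
        if self.reps_per_condition < 2:
            raise ValueError("need at least 2 replicates per condition")
        if not 0.0 <= self.prey_fraction <= 1.0:
            raise ValueError("prey_fraction must lie in [0, 1]")
        if not 0.0 <= self.shared_prey_fraction <= 1.0:
            raise ValueError("shared_prey_fraction must lie in [0, 1]")
        for name in ("log2_abundance_sd", "censor_steepness"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be positive")
        if self.noise_sd_log2 < 0 or self.prey_log2fc_sd < 0:
            raise ValueError("noise/effect sds must be non-negative")
        if self.control_label in self.baits:
            raise ValueError("control label cannot also be a bait name")


@dataclass
class SimTruth:
    """Ground truth of a simulated experiment.

    ``is_prey`` and ``true_log2fc`` are protein x bait DataFrames; non-prey
    entries carry a true log2 fold change of 0. ``is_shared_prey`` marks
    proteins that are prey in every bait.
    """

    is_prey: pd.DataFrame
    true_log2fc: pd.DataFrame
    is_shared_prey: pd.Series

    def prey_of(self, bait: str) -> set[str]:
        col = self.is_prey[bait]
        return set(col.index[col])

    @property
    def shared_prey_ids(self) -> set[str]:
        return set(self.is_shared_prey.index[self.is_shared_prey])

    def to_table(self) -> pd.DataFrame:
        """Long-format truth table (protein, bait, is_prey, true_log2fc)."""
        rows = []
        for bait in self.is_prey.columns:
            for protein in self.is_prey.index:
                rows.append(
                    (
                        protein,
                        bait,
                        bool(self.is_prey.at[protein, bait]),
                        float(self.true_log2fc.at[protein, bait]),
                        bool(self.is_shared_prey[protein]),
                    )
                )
        return pd.DataFrame(
            rows, columns=["protein", "bait", "is_prey", "true_log2fc", "is_shared_prey"]
        )


def simulate_experiment(config: SimConfig) -> tuple[LFQMatrix, SimTruth]:
    """Draw one synthetic LFQ experiment.

    Per protein: base log2 abundance ~ Normal(mean, sd). Prey proteins get a
    per-protein log2 effect ~ Normal(prey_log2fc_mean, prey_log2fc_sd),
    applied in each bait where they are prey. Per cell: replicate noise
    ~ Normal(0, noise_sd_log2) on the log2 scale, then the cell is retained
    with probability ``expit(steepness * (log2_intensity - midpoint))``;
    censored cells are set to 0. The control condition carries no effects.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_proteins
    proteins = [f"P{i:04d}" for i in range(1, n + 1)]
    baits = list(config.baits)

    base = rng.normal(config.log2_abundance_mean, config.log2_abundance_sd, n)

    n_prey = int(round(config.prey_fraction * n))
    prey_idx = rng.choice(n, size=n_prey, replace=False)
    n_shared = int(round(config.shared_prey_fraction * n_prey))
    shared_idx = prey_idx[:n_shared]

    is_prey = pd.DataFrame(False, index=proteins, columns=baits)
    effects = rng.normal(config.prey_log2fc_mean, config.prey_log2fc_sd, n)
    for i in prey_idx:
        if i in set(shared_idx):
            member = np.ones(len(baits), dtype=bool)
        else:
            # bait-specific prey hit each bait independently; at least one
            member = rng.random(len(baits)) < 0.5
            if not member.any():
                member[rng.integers(len(baits))] = True
        is_prey.iloc[i] = member
    true_log2fc = is_prey.astype(float).mul(effects, axis=0)
    is_shared_prey = pd.Series(False, index=proteins)
    is_shared_prey.iloc[shared_idx] = True

    samples: list[SampleDescriptor] = []
    columns: list[np.ndarray] = []
    for condition in baits + [config.control_label]:
        reps = config.reps_per_condition
        if condition == config.short_rep_bait:
            reps = max(2, config.reps_per_condition - 1)
        effect = (
            true_log2fc[condition].to_numpy()
            if condition in true_log2fc.columns
            else np.zeros(n)
        )
        for r in range(1, reps + 1):
            log2_int = base + effect + rng.normal(0.0, config.noise_sd_log2, n)
            p_detect = expit(config.censor_steepness * (log2_int - config.censor_midpoint_log2))
            detected = rng.random(n) < p_detect
            intensity = np.where(detected, np.exp2(log2_int), 0.0)
            samples.append(SampleDescriptor(f"{condition}_{r}", condition, r))
            columns.append(intensity)

    values = pd.DataFrame(
        np.column_stack(columns), index=proteins, columns=[s.sample_id for s in samples]
    )
    values.index.name = "protein"
    matrix = LFQMatrix(values=values, samples=tuple(samples), control_label=config.control_label)
    truth = SimTruth(is_prey=is_prey, true_log2fc=true_log2fc, is_shared_prey=is_shared_prey)
    return matrix, truth


def null_config(**overrides) -> SimConfig:
    """A no-prey configuration, handy for calibration studies."""
    base = SimConfig(prey_fraction=0.0, shared_prey_fraction=0.0)
    return replace(base, **overrides)
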