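"""Monte-Carlo calibration and recovery benchmarks.

Each function runs the pipeline (or one of its stages) on simulated data
with known ground truth and returns the measured operating characteristic:
the Grubbs false-flag rate under homogeneous replicates, the distribution of
imputed draws, the type-I error of the differential stage under a no-prey
null, prey-recovery sensitivity/FDR and shared-prey Jaccard under the
default spiked design, and the worst-case disagreement of the hypergeometric
tail with exhaustive enumeration.

These are the quantitative claims the package makes about itself; the test
suite asserts them and the acceptance script reports them.
"""

from __future__ import annotations

import math

import numpy as np

from .differential import call_prey, differential_table, Thresholds
from .enrichment import EnrichmentInput, hypergeom_upper_tail
from .impute import ImputationConfig, impute_missing
from .qc import drop_outlier_replicates, grubbs_test
from .simulate import SimConfig, simulate_experiment
from .conservation import PreyMembership, shared_prey


def grubbs_null_flag_rate(
    n_trials: int = 1000, n_replicates: int = 4, alpha: float = 0.05, seed: int = 0
) -> float:
    """Fraction of homogeneous (pure-noise) conditions with a flagged outlier.

    Under the null this should sit near ``alpha``.
    """
    rng = np.random.default_rng(seed)
    flags = 0
    for _ in range(n_trials):
        values = rng.normal(size=n_replicates)
        if grubbs_test(values, alpha=alpha).outlier_index is not None:
            flags += 1
    return flags / n_trials


def imputation_draw_stats(n_draws: int = 10000, seed: int = 0) -> dict:
    """Moments and bounds of many imputed draws against the uniform-over-pool law.

    Builds a matrix whose nonzero intensities are an even multiset over
    {1..100} (bottom-decile pool {1..10}, expected draw mean 5.5) with one
    missing cell per protein, imputes, and summarises the draws.
    """
    from .matrix import LFQMatrix, SampleDescriptor
    import pandas as pd

    block = np.tile(np.arange(1, 101.0), max(1, n_draws // 100))[:n_draws]
    full = np.column_stack([block, np.zeros(n_draws), block, block])
    samples = (
        SampleDescriptor("A_1", "A", 1),
        SampleDescriptor("A_2", "A", 2),
        SampleDescriptor("EV_1", "EV", 1),
        SampleDescriptor("EV_2", "EV", 2),
    )
    values = pd.DataFrame(
        full, index=[f"P{i}" for i in range(n_draws)], columns=[s.sample_id for s in samples]
    )
    matrix = LFQMatrix(values=values, samples=samples)
    out = impute_missing(matrix, ImputationConfig(fraction=0.10, seed=seed))
    draws = out.values.to_numpy()[:, 1][out.imputed_mask.to_numpy()[:, 1]]
    pool = np.arange(1.0, 11.0)
    return {
        "n_draws": int(draws.size),
        "mean": float(draws.mean()),
        "expected_mean": float(pool.mean()),
        "standard_error": float(pool.std(ddof=1) / math.sqrt(draws.size)),
        "min": float(draws.min()),
        "max": float(draws.max()),
        "pool_bounds": [float(out.pool_bounds[0]), float(out.pool_bounds[1])],
        "within_bounds": bool((draws >= out.pool_bounds[0]).all() and (draws <= out.pool_bounds[1]).all()),
    }


def null_type_one_error_rate(
    seed: int = 0, n_proteins: int = 1500, alpha: float = 0.05
) -> dict:
    """P(p <= alpha) over all tested (protein, bait) rows of a no-prey screen.

    The simulation keeps the generator's default left-censoring and the
    bottom-decile imputation, so the measurement covers the differential
    stage as it actually runs — including the mild conservatism of a
    one-tailed t-test on raw-scale log-normal intensities and the detection
    artifacts that imputation introduces.
    """
    config = SimConfig(
        n_proteins=n_proteins,
        prey_fraction=0.0,
        shared_prey_fraction=0.0,
        seed=seed,
    )
    matrix, _ = simulate_experiment(config)
    imputed = impute_missing(matrix, ImputationConfig(seed=seed))
    diff = differential_table(imputed)
    p = diff.loc[diff["tested"], "p_value"].to_numpy()
    return {
        "rate": float((p <= alpha).mean()),
        "alpha": alpha,
        "n_tests": int(p.size),
        "band_3sd": float(3 * math.sqrt(alpha * (1 - alpha) / p.size)),
    }


def prey_recovery(
    seed: int = 0, n_replicates: int = 3, thresholds: Thresholds = Thresholds()
) -> dict:
    """Sensitivity/FDR of prey calling and shared-prey Jaccard on the default
    spiked design, averaged over ``n_replicates`` independent simulations.

    Sensitivity and FDR are computed over (protein, bait) pairs: a call is a
    protein in a bait's fold-change membership that also passes the global
    adjusted-P gate. The Jaccard index compares the recovered all-bait shared
    set with the simulated shared prey.
    """
    sens, fdr, jac = [], [], []
    for r in range(n_replicates):
        run_seed = seed + r
        config = SimConfig(seed=run_seed)
        matrix, truth = simulate_experiment(config)
        cleaned, _ = drop_outlier_replicates(matrix, alpha=0.05)
        imputed = impute_missing(cleaned, ImputationConfig(seed=run_seed))
        diff = differential_table(imputed)
        membership, gate, _ = call_prey(diff, thresholds)
        called = {(p, b) for b, s in membership.items() for p in s if p in gate}
        true_pairs = {
            (p, b)
            for b in truth.is_prey.columns
            for p in truth.is_prey.index[truth.is_prey[b]]
        }
        tp = len(called & true_pairs)
        sens.append(tp / len(true_pairs))
        fdr.append((len(called) - tp) / max(1, len(called)))
        pm = PreyMembership.from_differential(diff, thresholds)
        recovered = shared_prey(pm, len(matrix.baits))
        true_shared = truth.shared_prey_ids
        union = recovered | true_shared
        jac.append(len(recovered & true_shared) / len(union) if union else 1.0)
    return {
        "sensitivity": float(np.mean(sens)),
        "fdr": float(np.mean(fdr)),
        "shared_prey_jaccard_all_baits": float(np.mean(jac)),
        "n_simulations": n_replicates,
    }


def _enumerated_upper_tail(x: int, population: int, successes: int, draws: int) -> float:
    total = 0
    for j in range(x, min(successes, draws) + 1):
        if draws - j <= population - successes:
            total += math.comb(successes, j) * math.comb(population - successes, draws - j)
    return total / math.comb(population, draws)


def hypergeom_enumeration_error(
    n_configs: int = 200, max_population: int = 15, seed: int = 0
) -> dict:
    """Worst relative disagreement between the hypergeometric upper tail and
    exhaustive enumeration over random small-count configurations."""
    rng = np.random.default_rng(seed)
    worst = 0.0
    for _ in range(n_configs):
        population = int(rng.integers(1, max_population + 1))
        successes = int(rng.integers(0, population + 1))
        draws = int(rng.integers(0, population + 1))
        x_min = max(0, draws - (population - successes))
        x = int(rng.integers(x_min, min(successes, draws) + 1))
        inp = EnrichmentInput(x, successes, population - successes, draws)
        got = hypergeom_upper_tail(inp)
        want = 1.0 if x == 0 else _enumerated_upper_tail(x, population, successes, draws)
        denom = max(abs(want), 1e-300)
        worst = max(worst, abs(got - want) / denom)
    return {"max_relative_error": float(worst), "n_configs": n_configs}
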