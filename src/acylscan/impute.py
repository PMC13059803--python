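"""Bottom-decile imputation of undetected intensities.

A protein detected in at least one replicate of a condition but undetected
(LFQ = 0) in others gets its zeros replaced by values picked uniformly at
random from the lowest 10% of all observed LFQ intensities — resampling the
observed low-intensity values rather than drawing from a fitted
distribution. Proteins undetected in every replicate of a condition are
left at 0 there: absence of evidence across the whole condition is not
imputed over.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .matrix import LFQMatrix, ValidationError

MIN_POOL_SIZE = 10


@dataclass(frozen=True)
class ImputationConfig:
    fraction: float = 0.10
    pool_scope: str = "whole_dataset"  # or "per_condition"
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.fraction < 1.0:
            raise ValueError("fraction must lie strictly between 0 and 1")
        if self.pool_scope not in ("whole_dataset", "per_condition"):
            raise ValueError(f"unknown pool_scope {self.pool_scope!r}")


@dataclass
class ImputedMatrix:
    """An LFQ matrix after imputation, with provenance of every filled cell."""

    matrix: LFQMatrix
    imputed_mask: pd.DataFrame
    pool_bounds: tuple[float, float]
    detected_pre_imputation: pd.DataFrame
    """Boolean protein x sample grid: True where the input had intensity > 0."""

    @property
    def values(self) -> pd.DataFrame:
        return self.matrix.values

    def n_imputed(self) -> int:
        return int(self.imputed_mask.to_numpy().sum())

    def detected_in_condition(self, condition: str) -> pd.Series:
        """Per protein: was it detected (pre-imputation) in >= 1 replicate?"""
        ids = [s.sample_id for s in self.matrix.samples_for(condition)]
        return self.detected_pre_imputation[ids].any(axis=1)


def bottom_fraction_pool(
    matrix: LFQMatrix, fraction: float = 0.10
) -> tuple[np.ndarray, tuple[float, float]]:
    """All nonzero intensities at or below the ``fraction`` quantile of the
    nonzero intensities (linear-interpolation quantile, inclusive threshold).

    Returns the pooled values and their (min, max). Requires at least
    ``MIN_POOL_SIZE`` nonzero values.
    """
    arr = matrix.values.to_numpy(dtype=float)
    nonzero = arr[arr > 0]
    if nonzero.size < MIN_POOL_SIZE:
        raise ValidationError(
            f"pool too small: {nonzero.size} nonzero values (< {MIN_POOL_SIZE})"
        )
    threshold = float(np.quantile(nonzero, fraction))
    pool = np.sort(nonzero[nonzero <= threshold])
    return pool, (float(pool[0]), float(pool[-1]))


def impute_missing(matrix: LFQMatrix, config: ImputationConfig) -> ImputedMatrix:
    """Fill partially-detected zeros with uniform draws from the bottom pool.

    With ``pool_scope='whole_dataset'`` one pool is built from the whole
    matrix; with ``'per_condition'`` each condition uses its own pool.
    Draws are a pure function of (matrix, config): identical inputs give
    identical imputed values.
    """
    rng = np.random.default_rng(config.seed)
    values = matrix.values.copy()
    detected = matrix.values > 0
    mask = pd.DataFrame(False, index=values.index, columns=values.columns)

    if config.pool_scope == "whole_dataset":
        global_pool, global_bounds = bottom_fraction_pool(matrix, config.fraction)

    bounds: tuple[float, float] | None = None
    for condition in matrix.conditions:
        ids = [s.sample_id for s in matrix.samples_for(condition)]
        block = matrix.values[ids]
        if config.pool_scope == "per_condition":
            sub = LFQMatrix(
                values=block,
                samples=tuple(matrix.samples_for(condition)),
                control_label=condition,
            )
            pool, pool_bounds = bottom_fraction_pool(sub, config.fraction)
        else:
            pool, pool_bounds = global_pool, global_bounds
        bounds = pool_bounds if bounds is None else (
            min(bounds[0], pool_bounds[0]),
            max(bounds[1], pool_bounds[1]),
        )
        detected_any = (block > 0).any(axis=1)
        eligible = (block == 0).to_numpy() & detected_any.to_numpy()[:, None]
        n_fill = int(eligible.sum())
        if n_fill:
            draws = rng.choice(pool, size=n_fill, replace=True)
            filled = block.to_numpy(dtype=float, copy=True)
            filled[eligible] = draws
            values[ids] = filled
            mask[ids] = eligible

    out = LFQMatrix(values=values, samples=matrix.samples, control_label=matrix.control_label)
    return ImputedMatrix(
        matrix=out,
        imputed_mask=mask,
        pool_bounds=bounds,
        detected_pre_imputation=detected,
    )
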