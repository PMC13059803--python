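"""Per-protein, per-bait differential enrichment versus the empty-vector control.

For every protein detected in a bait (>= 1 nonzero replicate before
imputation), the imputed intensities are compared with the control by

* fold change FC = mean(bait) / mean(control),
* a one-tailed (greater) Welch t-test on the intensities, and
* Benjamini-Hochberg FDR adjustment within each bait's tested family.

After the per-bait tables are merged, a protein absent from a bait's tested
set carries an adjusted P of 1 there. Prey are then called with the
inclusive filters FC >= 2 and adjusted P <= 0.1 in at least one bait.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .impute import ImputedMatrix

FLAG_OK = "ok"
FLAG_CONTROL_ALL_MISSING = "control_all_missing"

DIFFERENTIAL_COLUMNS = [
    "protein",
    "bait",
    "fc",
    "log2fc",
    "t_stat",
    "df",
    "p_value",
    "adj_p",
    "n_bait",
    "n_control",
    "tested",
    "denominator_flag",
]


@dataclass(frozen=True)
class Thresholds:
    """Prey-calling filters; both comparisons are inclusive."""

    fc_min: float = 2.0
    adjp_max: float = 0.1

    def __post_init__(self) -> None:
        if self.fc_min <= 0:
            raise ValueError("fc_min must be positive")
        if not 0.0 < self.adjp_max <= 1.0:
            raise ValueError("adjp_max must lie in (0, 1]")


def fold_change(
    bait_values, control_values, denominator_floor: float | None = None
) -> tuple[float, str]:
    """FC = mean(bait) / mean(control).

    If the protein is undetected in every control replicate (control mean 0),
    the ratio is taken against ``denominator_floor`` (the imputation pool's
    lower bound) and flagged ``control_all_missing``.
    """
    bait = np.asarray(bait_values, dtype=float)
    control = np.asarray(control_values, dtype=float)
    if bait.size == 0:
        raise ValueError("bait vector must be non-empty")
    m_control = control.mean() if control.size else 0.0
    if m_control > 0:
        return float(bait.mean() / m_control), FLAG_OK
    if denominator_floor is None or denominator_floor <= 0:
        raise ValueError(
            "control mean is 0 and no positive denominator floor was supplied"
        )
    return float(bait.mean() / denominator_floor), FLAG_CONTROL_ALL_MISSING


def welch_one_tailed_greater(bait_values, control_values) -> tuple[float, float, float]:
    """Welch unequal-variance t-test, alternative: bait mean > control mean.

    Returns (t, Welch-Satterthwaite df, upper-tail p). When both samples have
    zero variance: p = 0.5 if the means are equal (documented convention),
    else 0.0 or 1.0 according to the sign of the difference.
    """
    x = np.asarray(bait_values, dtype=float)
    y = np.asarray(control_values, dtype=float)
    if x.size < 2 or y.size < 2:
        raise ValueError("both samples need length >= 2")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    nx, ny = x.size, y.size
    se2 = vx / nx + vy / ny
    diff = x.mean() - y.mean()
    if se2 == 0.0:
        if diff == 0.0:
            return 0.0, float(nx + ny - 2), 0.5
        return (np.inf if diff > 0 else -np.inf), float(nx + ny - 2), (0.0 if diff > 0 else 1.0)
    t = diff / np.sqrt(se2)
    df = se2**2 / ((vx / nx) ** 2 / (nx - 1) + (vy / ny) ** 2 / (ny - 1))
    p = float(stats.t.sf(t, df))
    return float(t), float(df), p


def bh_adjust(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, in input order."""
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adjusted = np.minimum.accumulate(ranked[::-1])[::-1]
    out = np.empty(m)
    out[order] = np.minimum(adjusted, 1.0)
    return out


def differential_table(imputed: ImputedMatrix, control_label: str | None = None) -> pd.DataFrame:
    """One row per (protein, bait) over the union of tested proteins.

    A protein is *tested* in a bait iff it was detected there (>= 1 nonzero
    replicate pre-imputation). BH adjustment runs within each bait over its
    tested proteins; in the merged table, untested (protein, bait) rows carry
    adj_p = 1 and no test statistic, but their fold change is still reported
    (it is 0 when the protein is entirely absent from the bait).
    """
    matrix = imputed.matrix
    control_label = control_label or matrix.control_label
    if control_label not in matrix.conditions:
        raise KeyError(f"unknown control label {control_label!r}")
    floor = imputed.pool_bounds[0]
    control_block = matrix.condition_values(control_label).to_numpy(dtype=float)

    per_bait: list[pd.DataFrame] = []
    tested_union: set[str] = set()
    for bait in matrix.baits:
        bait_block = matrix.condition_values(bait).to_numpy(dtype=float)
        tested = imputed.detected_in_condition(bait).to_numpy()
        tested_union.update(np.asarray(matrix.protein_ids)[tested])
        rows = []
        for i, protein in enumerate(matrix.protein_ids):
            if not tested[i]:
                continue
            fc, flag = fold_change(bait_block[i], control_block[i], denominator_floor=floor)
            t, df, p = welch_one_tailed_greater(bait_block[i], control_block[i])
            rows.append((protein, bait, fc, t, df, p, flag, bait_block.shape[1], control_block.shape[1]))
        table = pd.DataFrame(
            rows,
            columns=["protein", "bait", "fc", "t_stat", "df", "p_value",
                     "denominator_flag", "n_bait", "n_control"],
        )
        table["adj_p"] = bh_adjust(table["p_value"].to_numpy()) if len(table) else []
        per_bait.append(table)

    merged = pd.concat(per_bait, ignore_index=True) if per_bait else pd.DataFrame()
    universe = sorted(tested_union)
    full_index = pd.MultiIndex.from_product(
        [universe, matrix.baits], names=["protein", "bait"]
    )
    merged = merged.set_index(["protein", "bait"]).reindex(full_index).reset_index()
    merged["tested"] = merged["p_value"].notna()

    # absent-from-bait rows: adjusted P set to 1; FC recomputed so the row is complete
    missing = ~merged["tested"]
    if missing.any():
        merged.loc[missing, "adj_p"] = 1.0
        prot_pos = {p: i for i, p in enumerate(matrix.protein_ids)}
        bait_blocks = {
            b: matrix.condition_values(b).to_numpy(dtype=float) for b in matrix.baits
        }
        for idx in merged.index[missing]:
            protein, bait = merged.at[idx, "protein"], merged.at[idx, "bait"]
            i = prot_pos[protein]
            fc, flag = fold_change(
                bait_blocks[bait][i], control_block[i], denominator_floor=floor
            )
            merged.at[idx, "fc"] = fc
            merged.at[idx, "denominator_flag"] = flag
            merged.at[idx, "n_bait"] = bait_blocks[bait].shape[1]
            merged.at[idx, "n_control"] = control_block.shape[1]

    with np.errstate(divide="ignore"):
        merged["log2fc"] = np.log2(merged["fc"].astype(float))
    merged["n_bait"] = merged["n_bait"].astype(int)
    merged["n_control"] = merged["n_control"].astype(int)
    return merged[DIFFERENTIAL_COLUMNS].sort_values(["protein", "bait"]).reset_index(drop=True)


def call_prey(
    rows: pd.DataFrame, thresholds: Thresholds = Thresholds()
) -> tuple[dict[str, set[str]], set[str], set[str]]:
    """Apply the prey filters to a differential table.

    Returns ``(membership_by_bait, gate_set, prey_universe)``:

    * ``membership_by_bait[b]`` — proteins with FC >= fc_min in bait b;
    * ``gate_set`` — proteins with adj_p <= adjp_max in at least one bait;
    * ``prey_universe`` — membership holders (any bait) that pass the gate.
    """
    fc_pass = rows[rows["fc"] >= thresholds.fc_min]
    membership: dict[str, set[str]] = {
        bait: set(sub["protein"]) for bait, sub in fc_pass.groupby("bait")
    }
    for bait in rows["bait"].unique():
        membership.setdefault(bait, set())
    gate = set(rows.loc[rows["adj_p"] <= thresholds.adjp_max, "protein"])
    holders = set().union(*membership.values()) if membership else set()
    return membership, gate, holders & gate
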