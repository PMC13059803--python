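"""Cross-bait conservation of prey, UpSet-style intersections, and PCA.

A prey protein's *membership set* is the set of baits where its fold change
clears the threshold. Conserved prey are the gate-passing proteins whose
membership covers at least ``k_min`` of the baits (the screen used 6 of 8).
Intersections are counted exclusively, UpSet-style: each protein contributes
once, under its exact membership set.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.decomposition import PCA

from .differential import Thresholds
from .impute import ImputedMatrix


@dataclass
class PreyMembership:
    """Per-protein bait membership (fc >= fc_min) and the adjusted-P gate."""

    bait_sets: dict[str, frozenset[str]]  # protein -> baits where fc passes
    gate_pass: dict[str, bool]  # protein -> adj_p <= adjp_max in >= 1 bait
    baits: tuple[str, ...]

    @classmethod
    def from_differential(
        cls, rows: pd.DataFrame, thresholds: Thresholds = Thresholds()
    ) -> "PreyMembership":
        baits = tuple(dict.fromkeys(rows["bait"]))
        fc_pass = rows[rows["fc"] >= thresholds.fc_min]
        sets = {
            protein: frozenset(sub["bait"])
            for protein, sub in fc_pass.groupby("protein")
        }
        gate_proteins = set(rows.loc[rows["adj_p"] <= thresholds.adjp_max, "protein"])
        proteins = sets.keys() | gate_proteins
        return cls(
            bait_sets={p: sets.get(p, frozenset()) for p in proteins},
            gate_pass={p: p in gate_proteins for p in proteins},
            baits=baits,
        )

    @property
    def prey_universe(self) -> set[str]:
        return {
            p for p, s in self.bait_sets.items() if s and self.gate_pass.get(p, False)
        }


def shared_prey(membership: PreyMembership, k_min: int) -> set[str]:
    """Gate-passing proteins whose membership covers >= k_min baits."""
    if not 1 <= k_min <= len(membership.baits):
        raise ValueError(
            f"k_min must lie in [1, {len(membership.baits)}], got {k_min}"
        )
    return {
        p
        for p, s in membership.bait_sets.items()
        if membership.gate_pass.get(p, False) and len(s) >= k_min
    }


def upset_counts(
    membership: PreyMembership,
) -> tuple[dict[frozenset[str], int], dict[str, int]]:
    """Exclusive intersection counts plus per-bait marginal totals.

    The exclusive counts partition the prey universe: each gate-passing
    protein with a non-empty membership is counted once under its exact bait
    set. Marginals count every prey of a bait regardless of what else it
    hits.
    """
    exclusive: dict[frozenset[str], int] = {}
    marginals: dict[str, int] = {b: 0 for b in membership.baits}
    for protein in membership.prey_universe:
        s = membership.bait_sets[protein]
        exclusive[s] = exclusive.get(s, 0) + 1
        for bait in s:
            marginals[bait] += 1
    return exclusive, marginals


def upset_counts_table(membership: PreyMembership) -> pd.DataFrame:
    """Exclusive counts as a tidy table sorted by count (desc) then combo."""
    exclusive, _ = upset_counts(membership)
    rows = [
        {"baits": "&".join(sorted(s)), "degree": len(s), "count": c}
        for s, c in exclusive.items()
    ]
    return (
        pd.DataFrame(rows, columns=["baits", "degree", "count"])
        .sort_values(["count", "baits"], ascending=[False, True])
        .reset_index(drop=True)
    )


@dataclass
class PCAResult:
    scores: pd.DataFrame  # replicate x component
    variance_fraction: np.ndarray
    component_count: int
    n_variables_used: int
    n_variables_dropped: int


def pca_replicates(imputed: ImputedMatrix, log2: bool = False, n_components: int | None = None) -> PCAResult:
    """PCA of the imputed matrix with samples as observations.

    Variables (proteins) are centered and scaled to unit variance;
    zero-variance proteins are dropped (their count is reported). Component
    signs are fixed so each component's largest-magnitude loading is
    positive, making scores reproducible.
    """
    values = imputed.values
    if values.shape[1] < 3:
        raise ValueError("PCA needs at least 3 samples")
    x = values.to_numpy(dtype=float).T  # samples x proteins
    if log2:
        x = np.log2(np.where(x > 0, x, np.nan))
        x = np.where(np.isfinite(x), x, 0.0)
    sd = x.std(axis=0, ddof=1)
    keep = sd > 0
    n_dropped = int((~keep).sum())
    if keep.sum() < 2:
        raise ValueError("fewer than 2 proteins with nonzero variance")
    x = (x[:, keep] - x[:, keep].mean(axis=0)) / sd[keep]
    max_components = min(x.shape[0] - 1, x.shape[1])
    k = max_components if n_components is None else min(n_components, max_components)
    pca = PCA(n_components=k, svd_solver="full")
    scores = pca.fit_transform(x)
    # deterministic sign: largest-|loading| positive per component
    for j in range(k):
        lead = np.argmax(np.abs(pca.components_[j]))
        if pca.components_[j, lead] < 0:
            scores[:, j] *= -1
    score_df = pd.DataFrame(
        scores,
        index=values.columns,
        columns=[f"PC{j + 1}" for j in range(k)],
    )
    return PCAResult(
        scores=score_df,
        variance_fraction=pca.explained_variance_ratio_.copy(),
        component_count=k,
        n_variables_used=int(keep.sum()),
        n_variables_dropped=n_dropped,
    )


def conserved_dotplot_table(
    rows: pd.DataFrame, selection: set[str], adjp_max: float = 0.1
) -> pd.DataFrame:
    """One row per (selected protein, bait) with log2fc and adjusted P.

    ``below_gate`` flags rows with adj_p above the gate — rendered as gray in
    the dot-plot figure. The table is sorted by protein then bait, so output
    is stable across runs.
    """
    known = set(rows["protein"])
    unknown = set(selection) - known
    if unknown:
        raise KeyError(f"selection contains unknown proteins: {sorted(unknown)[:5]}")
    sub = rows[rows["protein"].isin(selection)].copy()
    sub["below_gate"] = sub["adj_p"] > adjp_max
    sub = sub[["protein", "bait", "log2fc", "adj_p", "below_gate"]]
    return sub.sort_values(["protein", "bait"], kind="stable").reset_index(drop=True)
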