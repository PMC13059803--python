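"""Ortholog-overlap enrichment of a conserved prey set.

Given a set of acylated organism-A proteins (e.g. the yeast prey conserved
across baits), a reference set of organism-B proteins (e.g. human IcsB
substrates), and an A<->B ortholog pair table, the test asks whether the
prey set contains more reference orthologs than expected by chance.

The population is the set of B proteins that have A orthologs, the success
class is its reference subset, and the draw is the set of acylated A
proteins that have B orthologs; the p-value is the exact hypergeometric
upper tail P(X >= x) — a one-tailed Fisher exact test.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from scipy.stats import hypergeom

from .io import read_ortholog_pairs, read_protein_list


@dataclass(frozen=True)
class EnrichmentInput:
    """The four counts of the hypergeometric construction.

    x — acylated A proteins with an ortholog inside the reference set;
    n_ref — reference B proteins having A orthologs (success class);
    m_nonref — B proteins with A orthologs outside the reference;
    k_draw — acylated A proteins having B orthologs (draw size).
    """

    x: int
    n_ref: int
    m_nonref: int
    k_draw: int

    def __post_init__(self) -> None:
        if min(self.x, self.n_ref, self.m_nonref, self.k_draw) < 0:
            raise ValueError("counts must be non-negative")
        if self.x > min(self.n_ref, self.k_draw):
            raise ValueError(
                f"x={self.x} exceeds min(n_ref={self.n_ref}, k_draw={self.k_draw})"
            )
        if self.k_draw > self.n_ref + self.m_nonref:
            raise ValueError("draw size exceeds population size")

    @property
    def population(self) -> int:
        return self.n_ref + self.m_nonref


@dataclass
class EnrichmentResult:
    input: EnrichmentInput
    p_value: float
    mapping_report: dict[str, int] = field(default_factory=dict)


def build_counts(
    acylated_A: set[str],
    reference_B: set[str],
    pairs: set[tuple[str, str]],
    universe_B: set[str] | None = None,
) -> EnrichmentInput:
    """Assemble the hypergeometric counts from protein sets and ortholog pairs.

    A protein "has an ortholog" iff at least one pair involves it;
    many-to-many orthology is collapsed to set membership (proteins are
    counted, not pairs). ``universe_B`` defaults to every B-side protein in
    the pair table.
    """
    if not pairs:
        raise ValueError("ortholog pair set is empty")
    a_with_orth = {a for a, _ in pairs}
    b_with_orth = {b for _, b in pairs}
    if universe_B is None:
        universe_B = b_with_orth
    if not reference_B <= universe_B:
        missing = sorted(reference_B - universe_B)
        raise ValueError(
            f"reference proteins outside the universe: {missing[:5]}"
        )
    orthologs_of: dict[str, set[str]] = {}
    for a, b in pairs:
        if b in universe_B:
            orthologs_of.setdefault(a, set()).add(b)

    n_ref = len(reference_B & b_with_orth)
    m_nonref = len((universe_B & b_with_orth) - reference_B)
    drawn = {a for a in acylated_A if a in orthologs_of}
    k_draw = len(drawn)
    x = sum(1 for a in drawn if orthologs_of[a] & reference_B)
    return EnrichmentInput(x=x, n_ref=n_ref, m_nonref=m_nonref, k_draw=k_draw)


def hypergeom_upper_tail(inp: EnrichmentInput) -> float:
    """P(X >= x) with X ~ Hypergeom(population, n_ref successes, k_draw draws)."""
    if inp.k_draw == 0 or inp.x == 0:
        return 1.0
    return float(hypergeom.sf(inp.x - 1, inp.population, inp.n_ref, inp.k_draw))


def run_enrichment(
    selection: set[str],
    reference_path,
    pairs_path,
    universe_path=None,
) -> EnrichmentResult:
    """Read inputs, build the counts and compute the enrichment p-value."""
    pairs = read_ortholog_pairs(pairs_path)
    reference = read_protein_list(reference_path)
    universe = read_protein_list(universe_path) if universe_path else None
    a_with_orth = {a for a, _ in pairs}
    b_with_orth = {b for _, b in pairs}
    inp = build_counts(selection, reference, pairs, universe)
    report = {
        "selection_total": len(selection),
        "selection_without_ortholog": len(selection - a_with_orth),
        "reference_total": len(reference),
        "reference_without_ortholog": len(reference - b_with_orth),
    }
    return EnrichmentResult(
        input=inp, p_value=hypergeom_upper_tail(inp), mapping_report=report
    )
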