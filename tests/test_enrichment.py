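import math

import numpy as np
import pytest

from acylscan import (
    EnrichmentInput,
    build_counts,
    hypergeom_upper_tail,
    run_enrichment,
)


def brute_force_upper_tail(x, population, successes, draws):
    """P(X >= x) by direct enumeration of the hypergeometric mass function."""
    total = 0.0
    denom = math.comb(population, draws)
    for j in range(x, min(successes, draws) + 1):
        if draws - j <= population - successes:
            total += math.comb(successes, j) * math.comb(population - successes, draws - j)
    return total / denom


class TestBuildCounts:
    PAIRS = {(f"y{i}", f"h{i}") for i in range(1, 11)}

    def test_toy_construction(self):
        """10 B proteins all orthologed 1:1; reference {h1..h4}; acylated A maps
        to {h1..h4, h9} -> x=4, n_ref=4, m_nonref=6, k_draw=5."""
        inp = build_counts(
            acylated_A={"y1", "y2", "y3", "y4", "y9"},
            reference_B={"h1", "h2", "h3", "h4"},
            pairs=self.PAIRS,
            universe_B={f"h{i}" for i in range(1, 11)},
        )
        assert (inp.x, inp.n_ref, inp.m_nonref, inp.k_draw) == (4, 4, 6, 5)

    def test_empty_reference(self):
        inp = build_counts(set(), set(), self.PAIRS)
        assert inp.n_ref == 0 and inp.x == 0

    def test_all_acylated_inside_reference(self):
        inp = build_counts({"y1", "y2"}, {"h1", "h2", "h3"}, self.PAIRS)
        assert inp.x == inp.k_draw == 2

    def test_universe_defaults_to_pair_table(self):
        inp = build_counts({"y1"}, {"h1"}, self.PAIRS)
        assert inp.population == 10

    def test_selection_without_orthologs_not_drawn(self):
        inp = build_counts({"zz1", "zz2", "y1"}, {"h1"}, self.PAIRS)
        assert inp.k_draw == 1

    def test_many_to_many_collapses_to_membership(self):
        pairs = {("y1", "h1"), ("y1", "h2"), ("y2", "h1"), ("y3", "h3")}
        inp = build_counts({"y1", "y2"}, {"h1", "h2"}, pairs)
        # proteins, not pairs, are counted on both sides
        assert inp.k_draw == 2 and inp.x == 2 and inp.n_ref == 2 and inp.m_nonref == 1

    def test_empty_pairs_rejected(self):
        with pytest.raises(ValueError, match="empty"):
            build_counts({"y1"}, {"h1"}, set())

    def test_reference_outside_universe_rejected(self):
        with pytest.raises(ValueError, match="universe"):
            build_counts({"y1"}, {"h99"}, self.PAIRS, universe_B={"h1"})


class TestHypergeomUpperTail:
    def test_x_zero_is_one(self):
        assert hypergeom_upper_tail(EnrichmentInput(0, 4, 6, 5)) == 1.0

    def test_toy_exact_value(self):
        # C(4,4) * C(6,1) / C(10,5) = 6/252
        p = hypergeom_upper_tail(EnrichmentInput(4, 4, 6, 5))
        assert p == pytest.approx(6 / 252, rel=1e-12)

    def test_monotone_nonincreasing_in_x(self):
        ps = [hypergeom_upper_tail(EnrichmentInput(x, 6, 9, 7)) for x in range(7)]
        assert all(a >= b for a, b in zip(ps, ps[1:]))

    def test_invalid_counts_rejected(self):
        with pytest.raises(ValueError):
            EnrichmentInput(5, 4, 6, 5)  # x > n_ref
        with pytest.raises(ValueError):
            EnrichmentInput(0, 2, 2, 5)  # draws exceed population

    def test_matches_enumeration_on_random_configurations(self):
        """Exact agreement with brute-force enumeration for populations <= 15."""
        rng = np.random.default_rng(17)
        for _ in range(200):
            population = int(rng.integers(1, 16))
            successes = int(rng.integers(0, population + 1))
            draws = int(rng.integers(0, population + 1))
            x = int(rng.integers(0, min(successes, draws) + 1))
            if draws - x > population - successes:
                x = draws - (population - successes)
            inp = EnrichmentInput(x, successes, population - successes, draws)
            expected = brute_force_upper_tail(x, population, successes, draws) if x > 0 else 1.0
            assert hypergeom_upper_tail(inp) == pytest.approx(expected, rel=1e-12)

    def test_null_p_values_stochastically_conservative(self):
        """Under random draws, P(p <= alpha) <= alpha (discrete conservatism)."""
        rng = np.random.default_rng(23)
        population, successes, draws = 40, 10, 12
        labels = np.array([1] * successes + [0] * (population - successes))
        trials = 2000
        ps = []
        for _ in range(trials):
            x = int(labels[rng.permutation(population)[:draws]].sum())
            ps.append(hypergeom_upper_tail(EnrichmentInput(x, successes, population - successes, draws)))
        ps = np.array(ps)
        for alpha in (0.01, 0.05, 0.1, 0.25):
            band = 3 * np.sqrt(alpha * (1 - alpha) / trials)
            assert (ps <= alpha).mean() <= alpha + band


class TestRunEnrichment:
    def _write(self, tmp_path, name, lines):
        p = tmp_path / name
        p.write_text("\n".join(lines) + "\n")
        return p

    def test_composition_and_mapping_report(self, tmp_path):
        pairs = self._write(tmp_path, "pairs.tsv", [f"y{i}\th{i}" for i in range(1, 11)])
        ref = self._write(tmp_path, "ref.txt", ["h1", "h2", "h3", "h4"])
        res = run_enrichment({"y1", "y2", "y3", "y4", "y9", "orphan"}, ref, pairs)
        assert (res.input.x, res.input.k_draw) == (4, 5)
        assert res.p_value == pytest.approx(6 / 252, rel=1e-12)
        assert res.mapping_report["selection_without_ortholog"] == 1

    def test_selection_without_orthologs_gives_p_one(self, tmp_path):
        pairs = self._write(tmp_path, "pairs.tsv", ["y1\th1", "y2\th2"])
        ref = self._write(tmp_path, "ref.txt", ["h1"])
        res = run_enrichment({"zz"}, ref, pairs)
        assert res.input.k_draw == 0 and res.p_value == 1.0

    def test_duplicate_pair_rows_do_not_change_result(self, tmp_path):
        base = [f"y{i}\th{i}" for i in range(1, 11)]
        p1 = self._write(tmp_path, "p1.tsv", base)
        p2 = self._write(tmp_path, "p2.tsv", base + base[:5])
        ref = self._write(tmp_path, "ref.txt", ["h1", "h2"])
        sel = {"y1", "y5"}
        r1, r2 = run_enrichment(sel, ref, p1), run_enrichment(sel, ref, p2)
        assert r1.input == r2.input and r1.p_value == r2.p_value

    def test_enriched_construction_yields_small_p(self, tmp_path):
        """Over-sampling reference orthologs into the selection produces
        strong enrichment signal."""
        n = 60
        pairs = self._write(tmp_path, "pairs.tsv", [f"y{i}\th{i}" for i in range(n)])
        ref = self._write(tmp_path, "ref.txt", [f"h{i}" for i in range(15)])
        selection = {f"y{i}" for i in range(12)}  # 12 of 12 inside the reference
        res = run_enrichment(selection, ref, pairs)
        assert res.p_value < 1e-6
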