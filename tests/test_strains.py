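import numpy as np
import pandas as pd
import pytest

from viroclean.strains import (
    AlleleProfile,
    StrainComparison,
    build_allele_profile,
    build_strain_tree,
    compare_strains,
    consensus_sequence,
    is_shared_strain,
)

_BITS = {"A": 1, "C": 2, "G": 4, "T": 8}


def pileup_frame(rows):
    return pd.DataFrame(rows, columns=["pos", "A", "C", "G", "T"])


def profile_from_strings(votu, sample, alleles, consensus):
    """Build a profile from per-position allele strings ('' = uncovered)."""
    L = len(alleles)
    mask = np.zeros(L, dtype=np.uint8)
    cons = np.full(L, -1, dtype=np.int8)
    for i, (a, c) in enumerate(zip(alleles, consensus)):
        if a:
            mask[i] = sum(_BITS[b] for b in a)
            cons[i] = "ACGT".index(c)
    return AlleleProfile(votu, sample, L, mask, cons)


def random_profile(rng, votu, sample, L):
    mask = rng.random(L) < 0.8
    n_alleles = 1 + (rng.random(L) < 0.1)  # ~10% multi-allelic sites
    allele = np.zeros(L, dtype=np.uint8)
    cons = np.full(L, -1, dtype=np.int8)
    for i in np.flatnonzero(mask):
        bases = rng.choice(4, size=n_alleles[i], replace=False)
        allele[i] = sum(1 << b for b in bases)
        cons[i] = min(bases)
    return AlleleProfile(votu, sample, L, allele, cons)


def brute_force_compare(a, b):
    """Position-by-position scan straight from the definitions."""
    compared = pop = con = 0
    for p in range(a.genome_length):
        set_a = {i for i in range(4) if a.allele_mask[p] & (1 << i)}
        set_b = {i for i in range(4) if b.allele_mask[p] & (1 << i)}
        if not set_a or not set_b:
            continue
        compared += 1
        if not set_a & set_b:
            pop += 1
        if a.consensus_code[p] != b.consensus_code[p]:
            con += 1
    return compared, pop, con


class TestAlleleProfile:
    def test_single_base_site(self):
        prof = build_allele_profile(
            pileup_frame([(5, 3, 0, 0, 0)]), "v", "s", 10
        )
        assert prof.alleles_at(5) == {"A"}
        assert consensus_sequence(prof)[4] == "A"
        assert list(prof.covered_positions) == [5]

    def test_multiallelic_site_modal_consensus(self):
        prof = build_allele_profile(pileup_frame([(7, 2, 0, 1, 0)]), "v", "s", 10)
        assert prof.alleles_at(7) == {"A", "G"}
        assert consensus_sequence(prof)[6] == "A"

    def test_depth_tie_breaks_lexicographically(self):
        prof = build_allele_profile(pileup_frame([(1, 2, 0, 2, 0)]), "v", "s", 3)
        assert consensus_sequence(prof) == "ANN"

    def test_absent_positions_uncovered(self):
        prof = build_allele_profile(pileup_frame([(2, 1, 0, 0, 0)]), "v", "s", 4)
        assert consensus_sequence(prof) == "NANN"
        assert 3 not in prof.covered_positions

    def test_min_cov_excludes_shallow_sites(self):
        rows = pileup_frame([(1, 1, 0, 0, 0), (2, 2, 0, 0, 0)])
        prof = build_allele_profile(rows, "v", "s", 2, min_cov=2)
        assert list(prof.covered_positions) == [2]

    def test_zero_coverage_all_n(self):
        prof = build_allele_profile(pileup_frame([]), "v", "s", 5)
        assert consensus_sequence(prof) == "NNNNN"


class TestCompareStrains:
    def test_identical_full_coverage(self):
        a = profile_from_strings("v", "s1", ["A"] * 1000, ["A"] * 1000)
        b = profile_from_strings("v", "s2", ["A"] * 1000, ["A"] * 1000)
        comp = compare_strains(a, b)
        assert comp.popani == 100.0 and comp.conani == 100.0
        assert comp.fraction_compared == 1.0

    def test_one_difference_in_100k_is_exactly_99999(self):
        L = 100_000
        alleles_a, alleles_b = ["A"] * L, ["A"] * L
        alleles_b[0] = "G"
        a = profile_from_strings("v", "s1", alleles_a, ["A"] * L)
        cons_b = ["A"] * L
        cons_b[0] = "G"
        b = profile_from_strings("v", "s2", alleles_b, cons_b)
        comp = compare_strains(a, b)
        assert comp.popani_diff_count == 1
        assert comp.popani == pytest.approx(99.999, abs=1e-12)
        assert is_shared_strain(comp, mode="analysis")

    def test_shared_allele_counts_for_popani_not_conani(self):
        # alleles {A} vs {A,G} with consensus A vs G: popANI same, conANI differs
        a = profile_from_strings("v", "s1", ["A", "C"], ["A", "C"])
        b = profile_from_strings("v", "s2", ["AG", "C"], ["G", "C"])
        comp = compare_strains(a, b)
        assert comp.popani_diff_count == 0
        assert comp.conani_diff_count == 1
        assert comp.popani >= comp.conani

    def test_votu_mismatch_rejected(self):
        a = profile_from_strings("v1", "s1", ["A"], ["A"])
        b = profile_from_strings("v2", "s2", ["A"], ["A"])
        with pytest.raises(ValueError, match="mismatch"):
            compare_strains(a, b)

    def test_matches_brute_force_scan(self, rng):
        for _ in range(20):
            L = int(rng.integers(50, 400))
            a = random_profile(rng, "v", "s1", L)
            b = random_profile(rng, "v", "s2", L)
            comp = compare_strains(a, b)
            compared, pop, con = brute_force_compare(a, b)
            assert comp.compared_positions == compared
            assert comp.popani_diff_count == pop
            assert comp.conani_diff_count == con
            assert pop <= con

    def test_symmetry(self, rng):
        a = random_profile(rng, "v", "s1", 200)
        b = random_profile(rng, "v", "s2", 200)
        ab, ba = compare_strains(a, b), compare_strains(b, a)
        assert ab.compared_positions == ba.compared_positions
        assert ab.popani_diff_count == ba.popani_diff_count
        assert ab.conani_diff_count == ba.conani_diff_count

    def test_planted_difference_exactness(self, rng):
        L, k = 5000, 17
        cons = list(rng.choice(list("ACGT"), L))
        other = cons.copy()
        for p in rng.choice(L, k, replace=False):
            other[p] = "ACGT"[("ACGT".index(cons[p]) + 1) % 4]
        a = profile_from_strings("v", "s1", cons, cons)
        b = profile_from_strings("v", "s2", other, other)
        comp = compare_strains(a, b)
        assert comp.popani_diff_count == k
        assert comp.popani == pytest.approx(100 * (L - k) / L)


class TestIsSharedStrain:
    def _comp(self, diff, compared, L):
        return StrainComparison("v", "a", "b", L, compared, diff, diff)

    def test_boundary_inclusive(self):
        assert is_shared_strain(self._comp(1, 100_000, 125_000), mode="analysis")

    def test_two_diffs_in_100k_not_shared(self):
        comp = self._comp(2, 100_000, 100_000)
        assert not is_shared_strain(comp, mode="analysis")
        assert not is_shared_strain(comp, mode="decontamination")

    def test_fraction_rule_waived_in_decontamination_mode(self):
        comp = self._comp(0, 5000, 10_000)  # popANI 100 at fraction 0.5
        assert not is_shared_strain(comp, mode="analysis")
        assert is_shared_strain(comp, mode="decontamination")

    def test_null_comparison_rejected(self):
        with pytest.raises(ValueError, match="null"):
            is_shared_strain(self._comp(0, 0, 100))

    def test_monotone_in_popani_and_fraction(self):
        for diff in range(4):
            for compared in (75_000, 90_000, 100_000):
                weaker = is_shared_strain(
                    self._comp(diff + 1, compared, 100_000), mode="analysis"
                )
                stronger = is_shared_strain(
                    self._comp(diff, compared, 100_000), mode="analysis"
                )
                assert stronger or not weaker


def brute_force_agglomerate(dist, method):
    """Naive agglomerative clustering oracle over label sets."""
    clusters = {i: frozenset([i]) for i in range(len(dist))}
    heights = []
    agg = min if method == "single" else max
    while len(clusters) > 1:
        best = None
        for i in clusters:
            for j in clusters:
                if i < j:
                    d = agg(
                        dist[a][b]
                        for a in clusters[i]
                        for b in clusters[j]
                    )
                    if best is None or d < best[0]:
                        best = (d, i, j)
        d, i, j = best
        heights.append(d)
        clusters[min(i, j)] = clusters.pop(i) | clusters.pop(j)
    return sorted(heights)


class TestStrainTree:
    def _comp(self, a, b, popani, L=10_000, fraction=1.0):
        compared = int(L * fraction)
        diff = int(round(compared * (1 - popani / 100)))
        return StrainComparison("v", a, b, L, compared, diff, diff)

    def test_two_leaves_half_branch(self):
        tree = build_strain_tree([self._comp("a", "b", 99.9)])
        assert tree.to_newick() == "(a:0.0005,b:0.0005);"

    def test_three_leaves_complete_linkage(self):
        comps = [
            self._comp("A", "B", 99.9),
            self._comp("A", "C", 99.0),
            self._comp("B", "C", 99.0),
        ]
        tree = build_strain_tree(comps)
        assert tree.to_newick() == "(C:0.005,(A:0.0005,B:0.0005):0.0045);"

    def test_all_identical_star_at_height_zero(self):
        comps = [
            self._comp(a, b, 100.0)
            for a, b in [("a", "b"), ("a", "c"), ("b", "c")]
        ]
        tree = build_strain_tree(comps)
        assert np.allclose(tree.node_heights(), 0.0)

    def test_low_fraction_pairs_excluded_and_missing_pairs_error(self):
        comps = [
            self._comp("a", "b", 99.9),
            self._comp("a", "c", 99.0),
            self._comp("b", "c", 99.0, fraction=0.5),  # excluded -> incomplete
        ]
        with pytest.raises(ValueError, match="missing pairs"):
            build_strain_tree(comps)

    @pytest.mark.parametrize("method", ["single", "complete"])
    def test_heights_match_brute_force_agglomeration(self, rng, method):
        for _ in range(10):
            n = int(rng.integers(3, 7))
            names = [f"s{i}" for i in range(n)]
            popanis = {}
            comps = []
            for i in range(n):
                for j in range(i + 1, n):
                    p = float(np.round(rng.uniform(98.0, 100.0), 3))
                    popanis[(i, j)] = p
                    comps.append(self._comp(names[i], names[j], p))
            tree = build_strain_tree(comps, linkage_method=method)
            dist = [[0.0] * n for _ in range(n)]
            for (i, j), p in popanis.items():
                d = 1 - round(10_000 * (1 - p / 100)) / 10_000
                dist[i][j] = dist[j][i] = 1 - d  # reconstruct rounded distance
            expected = brute_force_agglomerate(dist, method)
            got = sorted(tree.linkage[:, 2])
            assert np.allclose(got, expected, atol=1e-12)
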