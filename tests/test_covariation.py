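import math
from collections import Counter

import numpy as np
import pytest
from hypothesis import given, strategies as st

from codonstats import (
    STANDARD_CODE,
    CdsRecord,
    build_pair_tables,
    cluster_rscpu,
    compute_rscpu,
    corpus_pair_counts,
    expected_pairs,
    pair_zscores,
    rscpu,
    rscpu_matrix,
    shade_pairs,
    successive_pairs,
)
from codonstats.covariation import PairTable, family_frequencies, overlap_counts
from codonstats.genetic_code import iter_codons
from codonstats.simulate import SpeciesSpec, generate_species


class TestSuccessivePairs:
    def test_ordered_pairs_of_consecutive_occurrences(self):
        # Ala occurrences GCT, GCC, GCT
        pairs = successive_pairs("GCTGCCGCT")
        assert pairs["A"] == Counter({("GCT", "GCC"): 1, ("GCC", "GCT"): 1})

    def test_intervening_codons_do_not_break_succession(self):
        # Ala .. Lys .. Ala: the two Ala occurrences still pair
        pairs = successive_pairs("GCTAAAGCC")
        assert pairs["A"] == Counter({("GCT", "GCC"): 1})
        assert "K" not in pairs

    def test_adjacent_only_mode_requires_contiguity(self):
        pairs = successive_pairs("GCTAAAGCC", adjacent_only=True)
        assert "A" not in pairs
        assert successive_pairs("GCTGCC", adjacent_only=True)["A"] == Counter(
            {("GCT", "GCC"): 1})

    def test_single_occurrence_yields_no_pairs(self):
        assert "A" not in successive_pairs("GCTAAA")

    def test_pairs_never_span_genes(self):
        recs = [CdsRecord("g1", "s", "GCT"), CdsRecord("g2", "s", "GCC")]
        pairs, occ = corpus_pair_counts(recs)
        assert pairs == {}
        assert occ["A"] == Counter({"GCT": 1, "GCC": 1})

    def test_stop_codons_excluded(self):
        pairs = successive_pairs("GCTTAAGCC")
        assert pairs["A"] == Counter({("GCT", "GCC"): 1})

    @given(st.lists(st.sampled_from(["GCT", "GCC", "GCA", "GCG", "AAA", "AAG"]),
                    max_size=60))
    def test_conservation_pairs_equal_occurrences_minus_one(self, codons):
        seq = "".join(codons)
        pairs = successive_pairs(seq)
        for aa in ("A", "K"):
            occ = sum(1 for c in iter_codons(seq)
                      if STANDARD_CODE.codon_to_aa[c] == aa)
            expected = max(0, occ - 1)
            assert sum(pairs.get(aa, Counter()).values()) == expected


class TestExpectedAndZ:
    def test_expected_from_frequency_products(self):
        # f(GCT)=2/3, f(GCA)=1/3, n_pairs=2 -> expected(GCT,GCT) = 2*(2/3)^2
        pc = Counter({("GCT", "GCT"): 1, ("GCT", "GCA"): 1})
        exp = expected_pairs(pc, {"GCT": 2 / 3, "GCA": 1 / 3}, ("GCT", "GCA"))
        assert exp[0, 0] == pytest.approx(8 / 9)
        assert exp.sum() == pytest.approx(2.0)

    def test_uniform_family_expected_unity(self):
        codons = ("GCA", "GCC", "GCG", "GCT")
        pc = Counter({(a, b): 1 for a in codons for b in codons})
        exp = expected_pairs(pc, {c: 0.25 for c in codons}, codons)
        assert np.allclose(exp, 1.0)

    def test_z_zero_when_observed_matches_expected(self):
        obs = np.full((2, 2), 4.0)
        z = pair_zscores(obs, obs.copy(), 16)
        assert np.allclose(z, 0.0)

    def test_binomial_z_value(self):
        # obs=8, exp=4, n=16 -> z = 4 / sqrt(16 * .25 * .75) = 4/sqrt(3)
        obs = np.array([[8.0]])
        exp = np.array([[4.0]])
        z = pair_zscores(obs, exp, 16)
        assert z[0, 0] == pytest.approx(4 / math.sqrt(3))

    def test_degenerate_certain_cell_z_zero(self):
        obs = np.array([[0.0]])
        exp = np.array([[16.0]])  # p = 1 -> sd = 0
        assert pair_zscores(obs, exp, 16)[0, 0] == 0.0

    def test_chain_variance_shrinks_toward_oracle(self, uniform_null_species):
        """The neighbouring-pair covariance correction moves analytic z onto
        the Monte-Carlo independence null (small replicate count here; the
        full-scale check runs in the acceptance suite)."""
        from codonstats import permutation_zscores

        _, records, _, _ = uniform_null_species
        tables = build_pair_tables(records)
        z_mc, _, _ = permutation_zscores(records, "K", n_permutations=20_000, seed=3)
        assert np.abs(tables["K"].z - z_mc).max() < 0.2

    def test_table_totals_conserved(self, uniform_null_species):
        _, records, _, _ = uniform_null_species
        tables = build_pair_tables(records)
        for t in tables.values():
            assert t.observed.sum() == t.n_pairs
            assert t.expected.sum() == pytest.approx(t.n_pairs)


class TestShading:
    @pytest.mark.parametrize("z,shade", [(5.0, "strong"), (1.2, "slight"),
                                         (-0.4, "none"), (3.0, "slight"),
                                         (0.0, "none")])
    def test_thresholds(self, z, shade):
        t = PairTable("K", ("AAA", "AAG"), np.zeros((1, 1)), np.zeros((1, 1)),
                      np.array([[z]]), 0)
        assert shade_pairs(t)[0, 0] == shade


class TestRSCPU:
    def test_independence_table_gives_exactly_one(self):
        # pair counts = outer product of occurrence counts -> RSCPU = 1
        r, s = 120, 280
        occ = {"K": Counter({"AAA": r, "AAG": s})}
        pairs = {"K": Counter({("AAA", "AAA"): r * r, ("AAA", "AAG"): r * s,
                               ("AAG", "AAA"): s * r, ("AAG", "AAG"): s * s})}
        table = rscpu(pairs, occ)
        for v in table.pairs.values():
            assert v == pytest.approx(1.0, abs=1e-12)

    def test_unobserved_pair_of_used_codons_is_zero(self):
        occ = {"K": Counter({"AAA": 3, "AAG": 3})}
        pairs = {"K": Counter({("AAA", "AAA"): 4})}
        table = rscpu(pairs, occ)
        assert table.pairs[("AAG", "AAG")] == 0.0

    def test_scale_invariance(self):
        occ = {"K": Counter({"AAA": 4, "AAG": 2})}
        pairs = {"K": Counter({("AAA", "AAA"): 3, ("AAA", "AAG"): 2})}
        t1 = rscpu(pairs, occ)
        t2 = rscpu({"K": Counter({k: 5 * v for k, v in pairs["K"].items()})},
                   {"K": Counter({k: 5 * v for k, v in occ["K"].items()})})
        assert t1.pairs == pytest.approx(t2.pairs)

    def test_unused_codon_pairs_reported_missing(self):
        occ = {"K": Counter({"AAA": 5})}
        pairs = {"K": Counter({("AAA", "AAA"): 4})}
        table = rscpu(pairs, occ)
        assert ("AAG", "AAG") in table.missing and ("AAG", "AAG") not in table.pairs

    def test_empty_corpus_fatal(self):
        with pytest.raises(ValueError):
            rscpu({}, {})

    def test_global_frequency_mode_differs(self):
        occ = {"K": Counter({"AAA": 4, "AAG": 2}),
               "F": Counter({"TTT": 6})}
        pairs = {"K": Counter({("AAA", "AAA"): 3})}
        fam = rscpu(pairs, occ, freq_mode="family")
        glob = rscpu(pairs, occ, freq_mode="global")
        assert glob.pairs[("AAA", "AAA")] > fam.pairs[("AAA", "AAA")]


class TestShuffleInvariance:
    @staticmethod
    def _shuffle_within_genes(records, rng):
        shuffled = []
        for rec in records:
            codons = list(iter_codons(rec.sequence))
            by_aa = {}
            for i, c in enumerate(codons):
                by_aa.setdefault(STANDARD_CODE.codon_to_aa[c], []).append(i)
            out = codons[:]
            for aa, idxs in by_aa.items():
                vals = [codons[i] for i in idxs]
                rng.shuffle(vals)
                for i, v in zip(idxs, vals):
                    out[i] = v
            shuffled.append("".join(out))
        return shuffled

    def test_within_gene_shuffle_destroys_order_covariation(self):
        """Shuffling each gene's codon order (composition fixed) removes the
        order component of planted stickiness: the composition-conditioned
        (gene-scope) permutation z is strongly positive on the diagonal
        before shuffling and centred on 0 after, averaged over shuffles."""
        from codonstats import permutation_zscores

        spec = SpeciesSpec(
            species_id="sticky", domain="Bacteria", gc_target=0.5,
            arginine_profile=(1, 1, 1, 1, 1, 1), optimal_set={},
            stickiness=0.7, n_genes=60, gene_length_range=(300, 600),
            expression_spread=0.0, seed=11)
        records, _, _ = generate_species(spec)
        z0, _, _ = permutation_zscores(records, "A", n_permutations=2000,
                                       seed=5, scope="gene")
        assert np.diag(z0).mean() > 2.0  # planted order signal

        rng = np.random.default_rng(0)
        acc, n = 0.0, 0
        for rep in range(10):
            shuffled = self._shuffle_within_genes(records, rng)
            z, _, sd = permutation_zscores(shuffled, "A", n_permutations=2000,
                                           seed=100 + rep, scope="gene")
            mask = sd > 0
            acc += z[mask].sum()
            n += mask.sum()
        assert abs(acc / n) < 0.2

    def test_null_corpus_rscpu_centred_on_one(self, uniform_null_species):
        _, records, _, _ = uniform_null_species
        table = compute_rscpu(records)
        vals = np.array(list(table.pairs.values()))
        assert vals.mean() == pytest.approx(1.0, abs=0.05)


class TestRSCPUClustering:
    def _table(self, eps):
        occ = {"K": Counter({"AAA": 10, "AAG": 10})}
        pairs = {"K": Counter({("AAA", "AAA"): 5 + eps, ("AAA", "AAG"): 5 - eps,
                               ("AAG", "AAA"): 5 - eps, ("AAG", "AAG"): 5 + eps})}
        return rscpu(pairs, occ)

    def test_identical_tables_merge_at_zero(self):
        dend = cluster_rscpu({"s1": self._table(0), "s2": self._table(0)})
        assert dend.linkage_matrix[0, 2] == pytest.approx(0.0)

    def test_stickiness_strata_separate(self):
        tables = {}
        rng = np.random.default_rng(9)
        for j, stick in enumerate([0.0, 0.8]):
            for i in range(3):
                spec = SpeciesSpec(
                    species_id=f"st{j}_{i}", domain="Bacteria", gc_target=0.5,
                    arginine_profile=(1, 1, 1, 1, 1, 1), optimal_set={},
                    stickiness=stick, n_genes=40, gene_length_range=(300, 600),
                    expression_spread=0.0, seed=int(rng.integers(2**31 - 1)))
                recs, _, _ = generate_species(spec)
                tables[spec.species_id] = compute_rscpu(recs)
        dend = cluster_rscpu(tables)
        clusters = dend.cut(2)
        groups = {}
        for sp, cl in clusters.items():
            groups.setdefault(cl, set()).add(sp.split("_")[0])
        assert all(len(g) == 1 for g in groups.values())

    def test_missing_pairs_imputed_neutral_for_distance(self):
        full = self._table(2)
        sparse = rscpu({"K": Counter({("AAA", "AAA"): 4})},
                       {"K": Counter({"AAA": 5})})
        mat = rscpu_matrix({"a": full, "b": sparse})
        assert mat.loc["b", "AAA-AAG"] == 1.0


def test_overlap_counts_sum_of_occurrences_minus_two():
    recs = ["GCTGCCGCAGCT", "GCTGCC", "GCT"]
    # Ala occurrences per gene: 4, 2, 1 -> overlaps 2 + 0 + 0
    assert overlap_counts(recs)["A"] == 2
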