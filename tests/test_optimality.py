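import numpy as np
import pandas as pd
import pytest

from codonstats import (
    CdsRecord,
    bin_rscu,
    call_optimality,
    covariation_overlap,
    detect_switch,
    fit_trend,
    stratify_by_abundance,
)
from codonstats.covariation import PairTable
from codonstats.io import SpeciesCollection
from codonstats.optimality import INTERMEDIATE, NONOPTIMAL, OPTIMAL
from codonstats.rscu import RSCUVector, canonical_codon_order


def _vector(values, imputed=()):
    base = {c: 1.0 for c in canonical_codon_order()}
    base.update(values)
    return RSCUVector(base, frozenset(imputed), "v")


class TestStratify:
    def _coll(self, n):
        recs = [CdsRecord(f"g{i:03d}", "sp", "GCTGCAAAA") for i in range(n)]
        return SpeciesCollection("sp", "Bacteria", "p", recs)

    def test_equal_size_bins(self):
        ab = {f"g{i:03d}": float(i + 1) for i in range(100)}
        bins = stratify_by_abundance(self._coll(100), ab, n_bins=4)
        assert [len(b) for b in bins.gene_ids] == [25, 25, 25, 25]
        # lowest-abundance bin first
        assert bins.gene_ids[0][0] == "g000" and bins.gene_ids[-1][-1] == "g099"

    def test_ties_broken_by_gene_id(self):
        ab = {f"g{i:03d}": 1.0 for i in range(10)}
        bins = stratify_by_abundance(self._coll(10), ab, n_bins=2)
        assert bins.gene_ids[0] == [f"g{i:03d}" for i in range(5)]

    def test_unmatched_genes_counted(self):
        ab = {f"g{i:03d}": float(i + 1) for i in range(80)}
        bins = stratify_by_abundance(self._coll(100), ab, n_bins=4)
        assert bins.n_unmatched == 20

    def test_no_overlap_fatal(self):
        with pytest.raises(ValueError):
            stratify_by_abundance(self._coll(10), {"other": 1.0}, n_bins=2)

    def test_too_few_bins_fatal(self):
        with pytest.raises(ValueError):
            stratify_by_abundance(self._coll(10), {"g000": 1.0}, n_bins=1)

    def test_bin_rscu_family_sums(self):
        ab = {f"g{i:03d}": float(i + 1) for i in range(20)}
        bins = stratify_by_abundance(self._coll(20), ab, n_bins=4)
        for v in bin_rscu(bins):
            fam = [v[c] for c in ("GCA", "GCC", "GCG", "GCT")]
            assert sum(fam) == pytest.approx(4.0)


class TestTrend:
    def test_constant_rscu_flat_fit(self):
        genes = [f"g{i}" for i in range(30)]
        frame = pd.DataFrame({"GCT": np.full(30, 1.7)}, index=genes)
        logab = {g: x for g, x in zip(genes, np.linspace(-2, 2, 30))}
        trend = fit_trend(frame, logab, span=0.6)
        assert np.allclose(trend.fitted["GCT"].values, 1.7, atol=1e-9)

    def test_exact_linear_relation_recovered(self):
        genes = [f"g{i}" for i in range(40)]
        x = np.linspace(0, 1, 40)
        frame = pd.DataFrame({"GCT": 0.5 + 1.5 * x}, index=genes)
        trend = fit_trend(frame, dict(zip(genes, x)), span=0.7)
        assert np.abs(trend.fitted["GCT"].values - (0.5 + 1.5 * x)).max() < 1e-3

    def test_noisy_monotone_trend_mostly_monotone_on_grid(self):
        rng = np.random.default_rng(4)
        genes = [f"g{i}" for i in range(200)]
        x = np.sort(rng.uniform(-2, 2, 200))
        y = 1.0 + 0.4 * x + rng.normal(0, 0.15, 200)
        trend = fit_trend(pd.DataFrame({"AAA": y}, index=genes),
                          dict(zip(genes, x)), span=0.5)
        steps = np.diff(trend.grid_fitted["AAA"].values)
        assert (steps > 0).mean() >= 0.95

    def test_insufficient_support_skipped(self):
        genes = [f"g{i}" for i in range(5)]
        frame = pd.DataFrame({"GCT": np.ones(5)}, index=genes)
        trend = fit_trend(frame, {g: float(i) for i, g in enumerate(genes)},
                          min_support=10)
        assert trend.fitted["GCT"].isna().all()


class TestCallOptimality:
    def test_rule_examples(self):
        high = _vector({"AAA": 1.8, "AAG": 0.3})
        low = _vector({"AAA": 0.6, "AAG": 1.5})
        call = call_optimality(high, low)
        assert call.classes["AAA"] == OPTIMAL
        assert call.classes["AAG"] == NONOPTIMAL

    def test_neutral_band_intermediate(self):
        high = _vector({"AAA": 1.02, "AAG": 0.98})
        low = _vector({"AAA": 0.98, "AAG": 1.02})
        call = call_optimality(high, low)
        assert call.classes["AAA"] == INTERMEDIATE
        assert call.classes["AAG"] == INTERMEDIATE

    def test_high_must_exceed_low_for_optimal(self):
        # abundant in both strata but declining -> not optimal
        high = _vector({"AAA": 1.5, "AAG": 0.5})
        low = _vector({"AAA": 1.8, "AAG": 0.2})
        call = call_optimality(high, low)
        assert call.classes["AAA"] == INTERMEDIATE

    def test_imputed_family_intermediate_and_flagged(self):
        high = _vector({"AAA": 1.8}, imputed=("GCA", "GCC", "GCG", "GCT"))
        low = _vector({"AAA": 0.5})
        call = call_optimality(high, low)
        assert call.classes["GCT"] == INTERMEDIATE
        assert "A" in call.intermediate_only_families

    def test_every_non_met_trp_codon_classified(self):
        call = call_optimality(_vector({}), _vector({}))
        assert len(call.classes) == 59


class TestDetectSwitch:
    def test_switch_when_argmax_differs(self):
        low = _vector({"GCT": 2.5, "GCC": 0.5, "GCA": 0.5, "GCG": 0.5})
        high = _vector({"GCT": 0.5, "GCC": 2.5, "GCA": 0.5, "GCG": 0.5})
        flags = detect_switch(low, high)
        assert flags["A"].switched is True
        assert flags["A"].low_preferred == "GCT"
        assert flags["A"].high_preferred == "GCC"

    def test_no_switch_when_argmax_stable(self):
        low = _vector({"AAA": 1.6, "AAG": 0.4})
        high = _vector({"AAA": 1.2, "AAG": 0.8})
        assert detect_switch(low, high)["K"].switched is False

    def test_tie_flagged_with_alphabetical_break(self):
        low = _vector({"AAA": 1.0, "AAG": 1.0})
        high = _vector({"AAA": 1.6, "AAG": 0.4})
        flag = detect_switch(low, high)["K"]
        assert flag.tie and flag.low_preferred == "AAA"

    def test_imputed_family_undefined(self):
        low = _vector({}, imputed=("AAA", "AAG"))
        high = _vector({})
        assert detect_switch(low, high)["K"].switched is None


def _pair_table(aa, codons, z_entries):
    k = len(codons)
    z = np.zeros((k, k))
    for (c1, c2), v in z_entries.items():
        z[codons.index(c1), codons.index(c2)] = v
    return PairTable(aa, tuple(codons), np.zeros((k, k), dtype=int),
                     np.zeros((k, k)), z, 0)


class TestOverlap:
    def _call(self, classes):
        base = {c: INTERMEDIATE for c in canonical_codon_order()}
        base.update(classes)
        return __import__("codonstats").OptimalityCall(
            classes=base, rscu_high={c: 1.0 for c in base},
            rscu_low={c: 1.0 for c in base}, delta=0.1)

    def test_mixed_pairs_constructed_example(self):
        # 3 within-class + 1 cross-class qualifying pairs, 1 touching an
        # intermediate codon -> fraction 3/4 with one excluded
        tables = {
            "A": _pair_table("A", ["GCA", "GCC", "GCG", "GCT"],
                             {("GCA", "GCA"): 5, ("GCC", "GCC"): 4,
                              ("GCA", "GCT"): 3.5, ("GCT", "GCT"): 6,
                              ("GCG", "GCG"): 4.5}),
        }
        call = self._call({"GCA": OPTIMAL, "GCC": OPTIMAL, "GCT": NONOPTIMAL,
                           "GCG": INTERMEDIATE})
        res = covariation_overlap(tables, call, sd_min=3)
        assert res.n_excluded_intermediate == 1          # (GCG,GCG)
        assert res.n_counted == 4 and res.n_within_class == 3
        assert res.fraction == pytest.approx(0.75)

    def test_cross_class_pair_reduces_fraction(self):
        tables = {"K": _pair_table("K", ["AAA", "AAG"],
                                   {("AAA", "AAA"): 5, ("AAA", "AAG"): 4,
                                    ("AAG", "AAG"): 3.2})}
        call = self._call({"AAA": OPTIMAL, "AAG": NONOPTIMAL})
        res = covariation_overlap(tables, call, sd_min=3)
        assert res.n_counted == 3 and res.n_within_class == 2
        assert res.fraction == pytest.approx(2 / 3)

    def test_include_accounting_counts_intermediate_in_denominator(self):
        tables = {"K": _pair_table("K", ["AAA", "AAG"],
                                   {("AAA", "AAA"): 5, ("AAG", "AAG"): 4})}
        call = self._call({"AAA": OPTIMAL, "AAG": INTERMEDIATE})
        excl = covariation_overlap(tables, call, sd_min=3)
        incl = covariation_overlap(tables, call, sd_min=3, accounting="include")
        assert excl.fraction == 1.0 and excl.n_counted == 1
        assert incl.fraction == 0.5 and incl.n_counted == 2

    def test_threshold_inclusive(self):
        tables = {"K": _pair_table("K", ["AAA", "AAG"], {("AAA", "AAA"): 3.0})}
        call = self._call({"AAA": OPTIMAL, "AAG": NONOPTIMAL})
        assert covariation_overlap(tables, call, sd_min=3).n_counted == 1

    def test_no_qualifying_pairs_undefined(self):
        tables = {"K": _pair_table("K", ["AAA", "AAG"], {})}
        call = self._call({"AAA": OPTIMAL, "AAG": OPTIMAL})
        res = covariation_overlap(tables, call, sd_min=3)
        assert res.fraction is None and res.n_counted == 0
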