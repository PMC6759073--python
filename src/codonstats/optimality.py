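"""Expression-stratified codon preferences and codon optimality.

Optimal codons are over-represented in highly expressed genes of a genome;
nonoptimal codons are over-represented in lowly expressed genes. Genes are
ranked by protein abundance, split into equal-size quantile bins, and RSCU
is computed on the pooled codon counts of each bin. Calls compare the
high-expression stratum against the low-expression stratum with a neutral
band of width delta around RSCU = 1; an amino acid shows a preference
"switch" when its most-used codon differs between the two strata. The
covariation-optimality overlap asks how many strongly autocorrelated codon
pairs are within-class (optimal-optimal or nonoptimal-nonoptimal).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Dict, List, Mapping, Optional

import numpy as np
import pandas as pd
from statsmodels.nonparametric.smoothers_lowess import lowess

from .genetic_code import CodonCounts, GeneticCode, STANDARD_CODE, count_codons
from .io import SpeciesCollection
from .covariation import PairTable
from .rscu import RSCUVector, canonical_amino_acids, rscu_vector

logger = logging.getLogger(__name__)

OPTIMAL = "optimal"
NONOPTIMAL = "nonoptimal"
INTERMEDIATE = "intermediate"


def read_abundance_table(path) -> Dict[str, float]:
    """TSV with columns gene_id, abundance; non-positive values dropped."""
    df = pd.read_csv(path, sep="\t", dtype={"gene_id": str})
    if not {"gene_id", "abundance"} <= set(df.columns):
        raise ValueError(f"{path}: required columns gene_id, abundance")
    table = {g: float(a) for g, a in zip(df["gene_id"], df["abundance"]) if a > 0}
    if len(table) < len(df):
        logger.warning("dropped %d genes with non-positive abundance", len(df) - len(table))
    return table


@dataclass
class AbundanceBins:
    """Equal-size quantile bins of genes by abundance, lowest first."""

    gene_ids: List[List[str]]
    counts: List[CodonCounts]
    n_unmatched: int

    @property
    def n_bins(self) -> int:
        return len(self.gene_ids)


@dataclass
class ExpressionTrend:
    """Locally-weighted polynomial fit of RSCU against log abundance.

    Descriptive only: optimality calls use binned RSCU, not the smooth.
    ``fitted`` holds fitted values at the observed abundances (genes x
    codons), ``grid``/``grid_fitted`` an evaluation grid by interpolation.
    Codons with fewer than the minimum local support are skipped (NaN).
    """

    fitted: pd.DataFrame
    grid: np.ndarray
    grid_fitted: pd.DataFrame
    span: float


@dataclass
class OptimalityCall:
    """Per-codon class with the supporting stratum RSCU values."""

    classes: Dict[str, str]
    rscu_high: Dict[str, float]
    rscu_low: Dict[str, float]
    delta: float
    intermediate_only_families: frozenset = frozenset()

    def class_of(self, codon: str) -> str:
        return self.classes[codon]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [(c, self.classes[c], self.rscu_high[c], self.rscu_low[c])
             for c in self.classes],
            columns=["codon", "class", "rscu_high", "rscu_low"])


@dataclass
class SwitchFlag:
    amino_acid: str
    switched: Optional[bool]     # None when undefined (imputed family)
    low_preferred: Optional[str]
    high_preferred: Optional[str]
    tie: bool = False


@dataclass
class OverlapResult:
    """Covariation-optimality overlap among strongly autocorrelated pairs."""

    fraction: Optional[float]
    n_within_class: int
    n_counted: int
    pairs: pd.DataFrame
    n_excluded_intermediate: int
    accounting: str


def stratify_by_abundance(
    collection: SpeciesCollection,
    abundance: Mapping[str, float],
    n_bins: int = 5,
    code: GeneticCode = STANDARD_CODE,
) -> AbundanceBins:
    """Split genes into equal-size abundance quantile bins; pool counts per bin.

    Genes are ranked by abundance ascending (ties broken by gene id) and cut
    into ``n_bins`` near-equal groups, lowest-expression bin first. Genes
    absent from the abundance table are excluded and counted.
    """
    if n_bins < 2:
        raise ValueError("need at least 2 bins")
    matched = [(abundance[r.seq_id], r.seq_id, r) for r in collection.records
               if r.seq_id in abundance]
    n_unmatched = collection.n_genes - len(matched)
    if not matched:
        raise ValueError("no overlap between corpus gene ids and abundance table")
    if len(matched) < n_bins:
        raise ValueError(f"only {len(matched)} matched genes for {n_bins} bins")
    matched.sort(key=lambda t: (t[0], t[1]))
    chunks = np.array_split(np.arange(len(matched)), n_bins)
    gene_ids, counts = [], []
    for chunk in chunks:
        recs = [matched[i][2] for i in chunk]
        gene_ids.append([r.seq_id for r in recs])
        counts.append(CodonCounts.pool(count_codons(r, code) for r in recs))
    return AbundanceBins(gene_ids=gene_ids, counts=counts, n_unmatched=n_unmatched)


def bin_rscu(bins: AbundanceBins, code: GeneticCode = STANDARD_CODE) -> List[RSCUVector]:
    """Pooled RSCU vector of each abundance bin, lowest-expression first."""
    return [rscu_vector(c, code, source_id=f"bin_{i}") for i, c in enumerate(bins.counts)]


def fit_trend(
    per_gene_rscu: pd.DataFrame,
    log_abundance: Mapping[str, float],
    span: float = 0.5,
    min_support: int = 10,
    grid_size: int = 50,
) -> ExpressionTrend:
    """Lowess fit of per-gene RSCU against log abundance, per codon.

    ``per_gene_rscu`` is genes x codons with NaN for imputed entries (see
    ``per_gene_rscu_frame(..., mask_imputed=True)``). Codons with fewer
    than ``min_support`` informative genes are skipped with a warning.
    """
    x_all = pd.Series(log_abundance)
    genes = per_gene_rscu.index.intersection(x_all.index)
    if len(genes) == 0:
        raise ValueError("no genes shared between RSCU frame and abundances")
    frame = per_gene_rscu.loc[genes]
    x = x_all.loc[genes].values.astype(float)
    grid = np.linspace(x.min(), x.max(), grid_size)
    fitted = pd.DataFrame(np.nan, index=frame.index, columns=frame.columns)
    grid_fit = pd.DataFrame(np.nan, index=np.arange(grid_size), columns=frame.columns)
    for codon in frame.columns:
        y = frame[codon].values.astype(float)
        ok = ~np.isnan(y)
        if ok.sum() < min_support:
            logger.warning("codon %s: only %d informative genes; trend skipped",
                           codon, int(ok.sum()))
            continue
        smooth = lowess(y[ok], x[ok], frac=span, return_sorted=True)
        xs, ys = smooth[:, 0], np.clip(smooth[:, 1], 0.0, None)
        fitted.loc[ok, codon] = np.interp(x[ok], xs, ys)
        grid_fit[codon] = np.interp(grid, xs, ys)
    return ExpressionTrend(fitted=fitted, grid=grid, grid_fitted=grid_fit, span=span)


def call_optimality(
    rscu_high: RSCUVector,
    rscu_low: RSCUVector,
    delta: float = 0.1,
    code: GeneticCode = STANDARD_CODE,
) -> OptimalityCall:
    """Classify every codon as optimal / nonoptimal / intermediate.

    A codon is optimal when its RSCU in the high-expression stratum is at
    least 1 + delta and exceeds its RSCU in the low stratum; nonoptimal
    when the high-stratum RSCU is at most 1 - delta and falls below the low
    stratum; otherwise intermediate. Families imputed in either stratum are
    wholly intermediate and flagged.
    """
    classes: Dict[str, str] = {}
    inter_only: List[str] = []
    for aa in canonical_amino_acids(code):
        family = code.families[aa]
        imputed = any(c in rscu_high.imputed or c in rscu_low.imputed for c in family)
        family_classes = {}
        for c in family:
            hi, lo = rscu_high.values[c], rscu_low.values[c]
            if imputed:
                family_classes[c] = INTERMEDIATE
            elif hi >= 1 + delta and hi > lo:
                family_classes[c] = OPTIMAL
            elif hi <= 1 - delta and hi < lo:
                family_classes[c] = NONOPTIMAL
            else:
                family_classes[c] = INTERMEDIATE
        if OPTIMAL not in family_classes.values():
            inter_only.append(aa)
        classes.update(family_classes)
    return OptimalityCall(
        classes=classes,
        rscu_high={c: rscu_high.values[c] for c in classes},
        rscu_low={c: rscu_low.values[c] for c in classes},
        delta=delta,
        intermediate_only_families=frozenset(inter_only),
    )


def detect_switch(
    rscu_low: RSCUVector,
    rscu_high: RSCUVector,
    code: GeneticCode = STANDARD_CODE,
) -> Dict[str, SwitchFlag]:
    """Per-amino-acid codon-preference switch between expression strata.

    The preferred codon of a stratum is the family's RSCU argmax (ties
    broken alphabetically and flagged); the switch flag is True when the
    preferred codons differ, None when either stratum is imputed.
    """
    flags: Dict[str, SwitchFlag] = {}
    for aa in canonical_amino_acids(code):
        family = code.families[aa]
        if any(c in rscu_low.imputed or c in rscu_high.imputed for c in family):
            flags[aa] = SwitchFlag(aa, switched=None, low_preferred=None,
                                   high_preferred=None)
            continue
        lo_vals = {c: rscu_low.values[c] for c in family}
        hi_vals = {c: rscu_high.values[c] for c in family}
        lo_best = min(c for c in family if lo_vals[c] == max(lo_vals.values()))
        hi_best = min(c for c in family if hi_vals[c] == max(hi_vals.values()))
        tie = (sum(v == max(lo_vals.values()) for v in lo_vals.values()) > 1
               or sum(v == max(hi_vals.values()) for v in hi_vals.values()) > 1)
        flags[aa] = SwitchFlag(aa, switched=lo_best != hi_best,
                               low_preferred=lo_best, high_preferred=hi_best, tie=tie)
    return flags


def covariation_overlap(
    tables: Mapping[str, PairTable],
    call: OptimalityCall,
    sd_min: float = 3.0,
    accounting: str = "exclude_intermediate",
) -> OverlapResult:
    """Fraction of strongly autocorrelated pairs explained by optimality.

    Among pairs with z >= ``sd_min``, counts those whose two codons share
    the optimal or the nonoptimal class. With the default accounting,
    pairs touching an intermediate codon are excluded from numerator and
    denominator and listed separately; with ``accounting='include'`` they
    stay in the denominator as unexplained. Undefined (no qualifying
    pairs) yields fraction None.
    """
    rows = []
    for aa, table in sorted(tables.items()):
        for i, c1 in enumerate(table.codons):
            for j, c2 in enumerate(table.codons):
                z = float(table.z[i, j])
                if z < sd_min:
                    continue
                cls1, cls2 = call.class_of(c1), call.class_of(c2)
                touches_intermediate = INTERMEDIATE in (cls1, cls2)
                within = (not touches_intermediate) and cls1 == cls2
                rows.append((aa, c1, c2, z, cls1, cls2, within, touches_intermediate))
    pairs = pd.DataFrame(
        rows, columns=["amino_acid", "codon1", "codon2", "z",
                       "class1", "class2", "within_class", "touches_intermediate"])
    n_inter = int(pairs["touches_intermediate"].sum()) if len(pairs) else 0
    if accounting == "exclude_intermediate":
        counted = pairs[~pairs["touches_intermediate"]] if len(pairs) else pairs
    elif accounting == "include":
        counted = pairs
    else:
        raise ValueError(f"unknown accounting {accounting!r}")
    n_counted = len(counted)
    n_within = int(counted["within_class"].sum()) if n_counted else 0
    fraction = n_within / n_counted if n_counted else None
    return OverlapResult(fraction=fraction, n_within_class=n_within,
                         n_counted=n_counted, pairs=pairs,
                         n_excluded_intermediate=n_inter, accounting=accounting)
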