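"""Codon-pair covariation: autocorrelation Z statistics and RSCPU.

Codon autocorrelation (covariation) is the non-random co-occurrence of
specific synonymous codons at successive occurrences of one amino acid
within a transcript. For each amino acid the successive-occurrence pairs
are counted per sequence (pairs never span sequence boundaries), pooled
over the corpus, and compared with the counts expected from the products
of the individual codon frequencies:

    expected(c1, c2) = n_pairs * f(c1) * f(c2)
    z(c1, c2)        = (observed - expected) / sd,   sd = sqrt(n p (1-p))

with p = expected / n_pairs (a binomial model per cell, validated against
a within-gene permutation oracle). Because the Z statistic grows with
corpus size, cross-species comparison uses the size-independent relative
synonymous codon pair usage instead:

    RSCPU(c1, c2) = f_obs_pair / (f_obs(c1) * f_obs(c2))

which equals 1 exactly when pair usage is explained by the individual
codon usages.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Mapping, Optional, Sequence, Tuple, Union

import numpy as np
import pandas as pd

from .genetic_code import (
    STOP,
    CdsRecord,
    GeneticCode,
    STANDARD_CODE,
    iter_codons,
)
from .rscu import Dendrogram, canonical_amino_acids, cluster_matrix

PairCounter = Dict[str, Counter]  # amino acid -> Counter[(codon1, codon2)]


@dataclass
class PairTable:
    """Observed/expected/Z matrices over one amino acid's codon pairs."""

    amino_acid: str
    codons: Tuple[str, ...]
    observed: np.ndarray   # k x k, successive-occurrence ordered pairs
    expected: np.ndarray
    z: np.ndarray
    n_pairs: int
    degenerate: np.ndarray = field(default=None)  # cells where sd == 0

    def cell(self, c1: str, c2: str) -> Tuple[int, float, float]:
        i, j = self.codons.index(c1), self.codons.index(c2)
        return int(self.observed[i, j]), float(self.expected[i, j]), float(self.z[i, j])

    def to_frame(self) -> pd.DataFrame:
        rows = []
        shades = shade_pairs(self)
        for i, c1 in enumerate(self.codons):
            for j, c2 in enumerate(self.codons):
                rows.append((self.amino_acid, c1, c2, int(self.observed[i, j]),
                             float(self.expected[i, j]), float(self.z[i, j]),
                             shades[i, j]))
        return pd.DataFrame(
            rows, columns=["amino_acid", "codon1", "codon2", "observed",
                           "expected", "z", "shade"])


@dataclass
class RSCPUTable:
    """Observed-to-expected codon-pair usage ratios for one corpus.

    ``pairs`` maps each ordered same-amino-acid codon pair to its RSCPU;
    pairs whose expected frequency is zero (an unused codon) are absent
    from ``pairs`` and listed in ``missing``.
    """

    pairs: Dict[Tuple[str, str], float]
    codon_freqs: Dict[str, float]
    n_pairs: Dict[str, int]
    missing: frozenset = frozenset()

    def to_series(self, fill_missing: Optional[float] = None) -> pd.Series:
        s = pd.Series({f"{a}-{b}": v for (a, b), v in self.pairs.items()})
        if fill_missing is not None:
            for a, b in self.missing:
                s[f"{a}-{b}"] = fill_missing
        return s.sort_index()


def successive_pairs(
    record: Union[CdsRecord, str],
    code: GeneticCode = STANDARD_CODE,
    adjacent_only: bool = False,
) -> PairCounter:
    """Per-amino-acid counts of successive same-amino-acid codon pairs.

    For each amino acid, its codon occurrences are taken in transcript
    order and every ordered pair of consecutive occurrences is counted;
    other codons may intervene. ``adjacent_only`` restricts counting to
    pairs at adjacent codon positions (a sensitivity-analysis mode). Stop
    codons and codons with ambiguity characters are excluded.
    """
    seq = record.sequence if isinstance(record, CdsRecord) else record
    pairs: PairCounter = defaultdict(Counter)
    last_codon: Dict[str, str] = {}
    last_pos: Dict[str, int] = {}
    for pos, codon in enumerate(iter_codons(seq)):
        aa = code.codon_to_aa.get(codon)
        if aa is None or aa == STOP:
            continue
        if aa in last_codon and (not adjacent_only or pos == last_pos[aa] + 1):
            pairs[aa][(last_codon[aa], codon)] += 1
        last_codon[aa] = codon
        last_pos[aa] = pos
    return dict(pairs)


def occurrence_counts(
    records: Iterable[Union[CdsRecord, str]], code: GeneticCode = STANDARD_CODE
) -> Dict[str, Counter]:
    """Per-amino-acid codon occurrence counts over a corpus."""
    occ: Dict[str, Counter] = defaultdict(Counter)
    for rec in records:
        seq = rec.sequence if isinstance(rec, CdsRecord) else rec
        for codon in iter_codons(seq):
            aa = code.codon_to_aa.get(codon)
            if aa is not None and aa != STOP:
                occ[aa][codon] += 1
    return dict(occ)


def corpus_pair_counts(
    records: Iterable[Union[CdsRecord, str]],
    code: GeneticCode = STANDARD_CODE,
    adjacent_only: bool = False,
) -> Tuple[PairCounter, Dict[str, Counter]]:
    """Aggregate successive-pair counts and occurrence counts over a corpus.

    Pairs are counted per gene and summed, so no pair spans two sequences.
    """
    pairs: PairCounter = defaultdict(Counter)
    occ: Dict[str, Counter] = defaultdict(Counter)
    for rec in records:
        seq = rec.sequence if isinstance(rec, CdsRecord) else rec
        for aa, counter in successive_pairs(seq, code, adjacent_only).items():
            pairs[aa].update(counter)
        for codon in iter_codons(seq):
            aa = code.codon_to_aa.get(codon)
            if aa is not None and aa != STOP:
                occ[aa][codon] += 1
    return dict(pairs), dict(occ)


def family_frequencies(
    occ: Mapping[str, Counter], code: GeneticCode = STANDARD_CODE
) -> Dict[str, Dict[str, float]]:
    """Within-family codon frequencies per amino acid over corpus occurrences."""
    freqs: Dict[str, Dict[str, float]] = {}
    for aa, counter in occ.items():
        total = sum(counter.values())
        family = code.families[aa]
        freqs[aa] = {c: (counter.get(c, 0) / total if total else 0.0) for c in family}
    return freqs


def expected_pairs(
    pair_counts: Counter, freqs: Mapping[str, float], codons: Sequence[str]
) -> np.ndarray:
    """Expected pair-count matrix: n_pairs * f(c1) * f(c2)."""
    n_pairs = sum(pair_counts.values())
    f = np.array([freqs.get(c, 0.0) for c in codons])
    return n_pairs * np.outer(f, f)


def pair_zscores(
    observed: np.ndarray,
    expected: np.ndarray,
    n_pairs: int,
    n_overlaps: int = 0,
    freqs: Optional[np.ndarray] = None,
) -> np.ndarray:
    """Z per cell under the binomial chain model: (obs - exp) / sd.

    With only counts available the sd is the plain binomial
    ``sqrt(n p (1-p))`` with ``p = exp / n``. When the number of
    overlapping successive-pair positions ``n_overlaps`` (sum over genes
    of max(0, occurrences - 2)) and the within-family frequencies are
    supplied, the variance gets the exact covariance of neighbouring pair
    indicators in an iid codon chain,

        var = n p (1-p) + 2 * n_overlaps * (delta_ij f_i^2 f_j - p^2),

    which matches a Monte-Carlo simulation of the independence null to
    within estimation noise. Cells with sd = 0 are defined as z = 0.
    """
    if n_pairs == 0:
        return np.zeros_like(expected)
    p = expected / n_pairs
    var = n_pairs * p * (1.0 - p)
    if n_overlaps and freqs is not None:
        f = np.asarray(freqs, dtype=float)
        cov = np.diag(f ** 3) - np.outer(f, f) ** 2
        var = var + 2.0 * n_overlaps * cov
    sd = np.sqrt(np.clip(var, 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (observed - expected) / np.where(sd > 0, sd, 1.0), 0.0)
    return z


def overlap_counts(
    records: Iterable[Union[CdsRecord, str]], code: GeneticCode = STANDARD_CODE
) -> Dict[str, int]:
    """Per amino acid, the number of overlapping successive-pair positions
    (sum over genes of max(0, occurrences - 2)); enters the chain-variance
    correction of :func:`pair_zscores`."""
    out: Dict[str, int] = defaultdict(int)
    for rec in records:
        seq = rec.sequence if isinstance(rec, CdsRecord) else rec
        per_gene: Counter = Counter()
        for codon in iter_codons(seq):
            aa = code.codon_to_aa.get(codon)
            if aa is not None and aa != STOP:
                per_gene[aa] += 1
        for aa, m in per_gene.items():
            out[aa] += max(0, m - 2)
    return dict(out)


def build_pair_tables(
    records: Iterable[Union[CdsRecord, str]],
    code: GeneticCode = STANDARD_CODE,
    adjacent_only: bool = False,
) -> Dict[str, PairTable]:
    """Observed/expected/Z pair tables for every multi-codon amino acid.

    Frequencies entering the expectation are corpus-level within-family
    codon frequencies over all occurrences of the amino acid; the Z uses
    the chain variance (binomial with neighbouring-pair covariance).
    """
    records = [r for r in records]
    pairs, occ = corpus_pair_counts(records, code, adjacent_only)
    freqs = family_frequencies(occ, code)
    overlaps = overlap_counts(records, code) if not adjacent_only else {}
    tables: Dict[str, PairTable] = {}
    for aa in canonical_amino_acids(code):
        if aa not in pairs or not pairs[aa]:
            continue
        codons = code.families[aa]
        k = len(codons)
        idx = {c: i for i, c in enumerate(codons)}
        observed = np.zeros((k, k), dtype=int)
        for (c1, c2), n in pairs[aa].items():
            observed[idx[c1], idx[c2]] = n
        n_pairs = int(observed.sum())
        expected = expected_pairs(pairs[aa], freqs[aa], codons)
        f = np.array([freqs[aa][c] for c in codons])
        z = pair_zscores(observed, expected, n_pairs,
                         n_overlaps=overlaps.get(aa, 0), freqs=f)
        p = expected / n_pairs if n_pairs else expected
        degenerate = (p <= 0) | (p >= 1)
        tables[aa] = PairTable(amino_acid=aa, codons=codons, observed=observed,
                               expected=expected, z=z, n_pairs=n_pairs,
                               degenerate=degenerate)
    return tables


# Shading categories used in covariation tables: strongly favored pairs sit
# more than 3 SD above expectation, slightly favored between 0 and 3 SD,
# nonfavored at or below expectation.
SHADE_STRONG = "strong"
SHADE_SLIGHT = "slight"
SHADE_NONE = "none"


def shade_pairs(table: PairTable) -> np.ndarray:
    """Categorize each pair by its Z: >+3 strong, (0, 3] slight, <=0 none."""
    z = table.z
    out = np.full(z.shape, SHADE_NONE, dtype=object)
    out[z > 0] = SHADE_SLIGHT
    out[z > 3] = SHADE_STRONG
    return out


def rscpu(
    pair_counts: Mapping[str, Counter],
    occ: Mapping[str, Counter],
    code: GeneticCode = STANDARD_CODE,
    freq_mode: str = "family",
) -> RSCPUTable:
    """Relative synonymous codon pair usage over a corpus.

    For each amino acid: f_obs_pair = pair count / total pairs of that
    amino acid, f_obs_codon = the codon's frequency, and
    RSCPU = f_obs_pair / (f_obs_codon1 * f_obs_codon2). With
    ``freq_mode='family'`` (default) codon frequencies are within-family;
    ``freq_mode='global'`` normalizes by all sense-codon occurrences in the
    corpus instead. Pairs whose expected frequency is zero are reported as
    missing.
    """
    if not occ:
        raise ValueError("empty corpus: no codon occurrences")
    if freq_mode == "family":
        freqs = family_frequencies(occ, code)
    elif freq_mode == "global":
        total = sum(sum(c.values()) for c in occ.values())
        freqs = {aa: {c: occ[aa].get(c, 0) / total for c in code.families[aa]}
                 for aa in occ}
    else:
        raise ValueError(f"unknown freq_mode {freq_mode!r}")

    values: Dict[Tuple[str, str], float] = {}
    missing: List[Tuple[str, str]] = []
    n_pairs_by_aa: Dict[str, int] = {}
    codon_freqs: Dict[str, float] = {}
    for aa, counter in pair_counts.items():
        n_pairs = sum(counter.values())
        n_pairs_by_aa[aa] = n_pairs
        family = code.families[aa]
        codon_freqs.update(freqs[aa])
        if n_pairs == 0:
            continue
        for c1 in family:
            for c2 in family:
                f_exp = freqs[aa][c1] * freqs[aa][c2]
                if f_exp == 0:
                    missing.append((c1, c2))
                    continue
                f_obs = counter.get((c1, c2), 0) / n_pairs
                values[(c1, c2)] = f_obs / f_exp
    return RSCPUTable(pairs=values, codon_freqs=codon_freqs,
                      n_pairs=n_pairs_by_aa, missing=frozenset(missing))


def compute_rscpu(
    records: Iterable[Union[CdsRecord, str]],
    code: GeneticCode = STANDARD_CODE,
    freq_mode: str = "family",
) -> RSCPUTable:
    """Convenience: pair counts + occurrences + RSCPU for one corpus."""
    pairs, occ = corpus_pair_counts(records, code)
    return rscpu(pairs, occ, code, freq_mode)


def rscpu_matrix(
    tables: Mapping[str, RSCPUTable], impute_missing: float = 1.0
) -> pd.DataFrame:
    """Species x pair matrix over the union of pair keys.

    Pairs undefined in a species (zero expected frequency) are imputed at
    the neutral value 1.0 for distance computation; exports based on the
    individual tables still report them as missing.
    """
    series = {sp: t.to_series(fill_missing=None) for sp, t in tables.items()}
    mat = pd.DataFrame(series).T
    return mat.fillna(impute_missing)


def cluster_rscpu(
    tables: Mapping[str, RSCPUTable],
    metric: str = "euclidean",
    method: str = "ward",
    domains: Optional[Mapping[str, str]] = None,
) -> Dendrogram:
    """Hierarchically cluster species by their RSCPU patterns."""
    if len(tables) < 2:
        raise ValueError("clustering requires at least 2 species")
    mat = rscpu_matrix(tables)
    dend = cluster_matrix(mat, metric=metric, method=method)
    if domains is not None:
        dend.annotations = pd.DataFrame(
            {"domain": [domains.get(sp, "unknown") for sp in mat.index]}, index=mat.index)
    return dend


def pair_tables_frame(
    tables: Mapping[str, PairTable],
    trna_annotation: Optional[Mapping[str, str]] = None,
) -> pd.DataFrame:
    """Long-format export of pair tables, optionally annotated with the
    decoding tRNA label of each codon (pass-through annotation only)."""
    frames = [t.to_frame() for _, t in sorted(tables.items())]
    df = pd.concat(frames, ignore_index=True) if frames else pd.DataFrame(
        columns=["amino_acid", "codon1", "codon2", "observed", "expected", "z", "shade"])
    if trna_annotation:
        df["trna1"] = df["codon1"].map(trna_annotation)
        df["trna2"] = df["codon2"].map(trna_annotation)
    return df


def permutation_zscores(
    records: Iterable[Union[CdsRecord, str]],
    amino_acid: str,
    code: GeneticCode = STANDARD_CODE,
    n_permutations: int = 100_000,
    seed: int = 0,
    scope: str = "resample",
) -> Tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Monte-Carlo null for one amino acid's pair counts.

    Three null designs are offered. ``scope='resample'`` (default) is the
    independence null the binomial model describes: every replicate redraws
    each occurrence of the amino acid iid from the corpus within-family
    codon frequencies (gene sizes preserved) and recounts successive pairs
    within genes; it is the independent oracle against which the analytic
    binomial Z is validated. ``scope='corpus'`` shuffles the observed
    occurrences across the whole corpus (corpus composition fixed), and
    ``scope='gene'`` permutes within each gene (per-gene composition
    fixed); both are conditional nulls with smaller variance than the
    binomial model, useful for conditional inference.

    Returns ``(z_perm, mean, sd)`` with ``z_perm = (observed - mean) / sd``
    and cells of zero permutation variance set to 0.
    """
    codons = code.families[amino_acid]
    k = len(codons)
    idx = {c: i for i, c in enumerate(codons)}
    genes: List[np.ndarray] = []
    observed = np.zeros(k * k, dtype=np.int64)
    for rec in records:
        seq = rec.sequence if isinstance(rec, CdsRecord) else rec
        occ = [idx[c] for c in iter_codons(seq)
               if code.codon_to_aa.get(c) == amino_acid]
        if len(occ) >= 2:
            arr = np.array(occ, dtype=np.int8)
            genes.append(arr)
            cells = arr[:-1].astype(np.int64) * k + arr[1:]
            observed += np.bincount(cells, minlength=k * k)

    rng = np.random.default_rng(seed)
    chunk = max(1, min(n_permutations, 20_000))
    sum_c = np.zeros(k * k, dtype=np.float64)
    sum_c2 = np.zeros(k * k, dtype=np.float64)

    if scope in ("corpus", "resample"):
        pooled = np.concatenate(genes)
        M = pooled.size
        freqs = np.bincount(pooled, minlength=k) / M
        # columns of the (permutation x M) layout at which a successive
        # pair stays inside one gene
        ends = np.cumsum([len(g) for g in genes])
        valid = np.setdiff1d(np.arange(M - 1), ends - 1)
        done = 0
        while done < n_permutations:
            r = min(chunk, n_permutations - done)
            if scope == "resample":
                X = rng.choice(k, size=(r, M), p=freqs).astype(np.int8)
            else:
                order = np.argsort(rng.random((r, M)), axis=1)
                X = pooled[order]
            cells = (X[:, :-1].astype(np.int64) * k + X[:, 1:])[:, valid]
            flat = (np.arange(r, dtype=np.int64)[:, None] * (k * k) + cells).ravel()
            counts = np.bincount(flat, minlength=r * k * k).reshape(r, k * k)
            sum_c += counts.sum(axis=0)
            sum_c2 += (counts.astype(np.float64) ** 2).sum(axis=0)
            done += r
    elif scope == "gene":
        done = 0
        while done < n_permutations:
            r = min(chunk, n_permutations - done)
            counts = np.zeros((r, k * k), dtype=np.int64)
            offsets = np.arange(r, dtype=np.int64)[:, None] * (k * k)
            for arr in genes:
                order = np.argsort(rng.random((r, len(arr))), axis=1)
                perm = arr[order]
                cells = perm[:, :-1].astype(np.int64) * k + perm[:, 1:]
                flat = (offsets + cells).ravel()
                counts += np.bincount(flat, minlength=r * k * k).reshape(r, k * k)
            sum_c += counts.sum(axis=0)
            sum_c2 += (counts.astype(np.float64) ** 2).sum(axis=0)
            done += r
    else:
        raise ValueError(f"unknown scope {scope!r}")

    mean = (sum_c / n_permutations).reshape(k, k)
    var = (sum_c2 / n_permutations).reshape(k, k) - mean ** 2
    sd = np.sqrt(np.clip(var, 0.0, None))
    obs = observed.reshape(k, k)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = np.where(sd > 0, (obs - mean) / np.where(sd > 0, sd, 1.0), 0.0)
    return z, mean, sd
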