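"""Relative synonymous codon usage (RSCU) vectors, species profiles, clustering.

RSCU of a codon c encoding amino acid a is the observed count of c divided
by the count expected were all synonymous codons of a used equally:

    RSCU(c) = n_c / (n_a / k_a)

with n_a the total count over a's family and k_a the family size. A value
of 1 means no bias; values sum to k_a within each family. Vectors exclude
Met, Trp and stop codons, leaving 59 entries under the standard code in a
fixed canonical order (amino acids alphabetical by three-letter name,
codons alphabetical within each family).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.cluster import hierarchy

from .genetic_code import (
    AA_THREE_LETTER,
    CodonCounts,
    GeneticCode,
    STANDARD_CODE,
    count_codons,
    gc_content,
)
from .io import SpeciesCollection


class DegenerateFamilyError(ValueError):
    """Raised when a single-codon family (Met, Trp) is requested as a subset."""


def canonical_amino_acids(code: GeneticCode = STANDARD_CODE) -> Tuple[str, ...]:
    """Amino acids with family size >= 2, alphabetical by three-letter name."""
    aas = [aa for aa, fam in code.families.items() if len(fam) >= 2]
    return tuple(sorted(aas, key=lambda a: AA_THREE_LETTER[a]))


def canonical_codon_order(code: GeneticCode = STANDARD_CODE) -> Tuple[str, ...]:
    """The fixed 59-codon order used by every vector and matrix export."""
    return tuple(c for aa in canonical_amino_acids(code) for c in code.families[aa])


CANONICAL_CODONS = canonical_codon_order()
assert len(CANONICAL_CODONS) == 59


@dataclass
class RSCUVector:
    """Ordered RSCU values (59 for the standard code) with imputation flags.

    Families absent from the underlying counts are imputed at the neutral
    value 1.0 and recorded in ``imputed`` so that downstream consumers (PCA,
    clustering) receive "no information" rather than extreme zeros.
    """

    values: Dict[str, float]
    imputed: frozenset
    source_id: Optional[str] = None

    def __getitem__(self, codon: str) -> float:
        return self.values[codon]

    def to_series(self) -> pd.Series:
        return pd.Series(self.values, name=self.source_id)

    def to_array(self) -> np.ndarray:
        return np.array(list(self.values.values()), dtype=float)

    @property
    def imputed_families(self) -> frozenset:
        return frozenset(_FAMILY_OF[c] for c in self.imputed)

    @property
    def imputed_family_fraction(self) -> float:
        """Fraction of synonymous families that were imputed."""
        return len(self.imputed_families) / len(canonical_amino_acids())


_FAMILY_OF: Dict[str, str] = {
    c: aa for aa in canonical_amino_acids() for c in STANDARD_CODE.families[aa]
}


@dataclass
class SpeciesProfile:
    """Species-level pooled RSCU with GC fraction and taxonomy labels."""

    species_id: str
    domain: str
    phylum: str
    gc: float
    rscu: RSCUVector
    n_genes: int


@dataclass
class Dendrogram:
    """Hierarchical-clustering result over labelled profiles.

    Wraps a SciPy linkage matrix together with the leaf labels and optional
    per-leaf annotation channels (GC fraction, domain) for heatmap export.
    """

    linkage_matrix: np.ndarray
    labels: List[str]
    annotations: pd.DataFrame = field(default_factory=pd.DataFrame)

    @property
    def leaf_order(self) -> List[str]:
        return [self.labels[i] for i in hierarchy.leaves_list(self.linkage_matrix)]

    def cut(self, n_clusters: int) -> Dict[str, int]:
        flat = hierarchy.fcluster(self.linkage_matrix, t=n_clusters, criterion="maxclust")
        return dict(zip(self.labels, flat.tolist()))

    def to_newick(self) -> str:
        tree = hierarchy.to_tree(self.linkage_matrix)

        def render(node) -> str:
            if node.is_leaf():
                return self.labels[node.id]
            left, right = node.get_left(), node.get_right()
            ld = node.dist - left.dist
            rd = node.dist - right.dist
            return f"({render(left)}:{ld:.6g},{render(right)}:{rd:.6g})"

        return render(tree) + ";"


def rscu_vector(
    counts: CodonCounts, code: GeneticCode = STANDARD_CODE, source_id: Optional[str] = None
) -> RSCUVector:
    """RSCU vector from codon counts; absent families imputed at 1.0."""
    values: Dict[str, float] = {}
    imputed: List[str] = []
    for aa in canonical_amino_acids(code):
        family = code.families[aa]
        k = len(family)
        n_a = sum(counts.counts.get(c, 0) for c in family)
        if n_a == 0:
            for c in family:
                values[c] = 1.0
                imputed.append(c)
        else:
            for c in family:
                values[c] = counts.counts.get(c, 0) * k / n_a
    return RSCUVector(values=values, imputed=frozenset(imputed), source_id=source_id)


def species_profile(
    collection: SpeciesCollection,
    code: GeneticCode = STANDARD_CODE,
    mode: str = "pooled",
) -> SpeciesProfile:
    """Species-level RSCU profile.

    ``mode='pooled'`` (default) sums codon counts across the species'
    sequences before computing RSCU, weighting genes by their codon content;
    ``mode='mean'`` averages per-gene RSCU vectors with equal gene weights.
    GC is always computed on the pooled sequence.
    """
    if not collection.records:
        raise ValueError(f"species {collection.species_id} has no records")
    if mode == "pooled":
        pooled = CodonCounts.pool(count_codons(r, code) for r in collection.records)
        vec = rscu_vector(pooled, code, source_id=collection.species_id)
    elif mode == "mean":
        frames = [rscu_vector(count_codons(r, code), code).to_series()
                  for r in collection.records]
        mean = pd.concat(frames, axis=1).mean(axis=1)
        vec = RSCUVector(values=mean.to_dict(), imputed=frozenset(),
                         source_id=collection.species_id)
    else:
        raise ValueError(f"unknown profile mode {mode!r}")
    return SpeciesProfile(
        species_id=collection.species_id,
        domain=collection.domain,
        phylum=collection.phylum,
        gc=gc_content(collection.records),
        rscu=vec,
        n_genes=collection.n_genes,
    )


def subset_amino_acid(
    vector: RSCUVector, aa: str, code: GeneticCode = STANDARD_CODE
) -> Dict[str, float]:
    """RSCU entries of one amino acid's family, canonical order.

    Accepts one- or three-letter amino-acid codes; e.g. 'Arg' yields the six
    arginine entries (AGA, AGG, CGA, CGC, CGG, CGT alphabetically).
    """
    from .genetic_code import THREE_TO_ONE

    key = THREE_TO_ONE.get(aa.capitalize(), aa.upper())
    if key not in code.families:
        raise KeyError(f"unknown amino acid {aa!r}")
    family = code.families[key]
    if len(family) < 2:
        raise DegenerateFamilyError(f"{aa}: single-codon family has no usage bias")
    return {c: vector.values[c] for c in family}


def rscu_matrix(vectors: Iterable[RSCUVector], code: GeneticCode = STANDARD_CODE) -> pd.DataFrame:
    """Stack RSCU vectors into a (rows x 59) DataFrame in canonical order."""
    order = list(canonical_codon_order(code))
    rows = {v.source_id: [v.values[c] for c in order] for v in vectors}
    return pd.DataFrame.from_dict(rows, orient="index", columns=order)


def per_gene_rscu_frame(
    collection: SpeciesCollection,
    code: GeneticCode = STANDARD_CODE,
    mask_imputed: bool = False,
) -> pd.DataFrame:
    """Per-gene RSCU matrix for one species (genes x 59).

    With ``mask_imputed`` imputed entries become NaN instead of the neutral
    1.0, which is what trend fitting against expression wants.
    """
    order = list(canonical_codon_order(code))
    data = np.empty((len(collection.records), len(order)))
    index = []
    for i, rec in enumerate(collection.records):
        vec = rscu_vector(count_codons(rec, code), code, source_id=rec.seq_id)
        row = np.array([vec.values[c] for c in order])
        if mask_imputed and vec.imputed:
            mask = np.array([c in vec.imputed for c in order])
            row[mask] = np.nan
        data[i] = row
        index.append(rec.seq_id)
    return pd.DataFrame(data, index=index, columns=order)


def cluster_profiles(
    profiles: Sequence[SpeciesProfile],
    metric: str = "euclidean",
    method: str = "ward",
) -> Dendrogram:
    """Hierarchically cluster species by their RSCU profiles.

    Defaults to Euclidean distance with Ward linkage on the raw (unscaled)
    59-dimensional vectors; both are configurable. The returned dendrogram
    carries GC and domain annotation channels per leaf.
    """
    profiles = list(profiles)
    if len(profiles) < 2:
        raise ValueError("clustering requires at least 2 profiles")
    mat = rscu_matrix([p.rscu for p in profiles])
    Z = hierarchy.linkage(mat.values, method=method, metric=metric)
    ann = pd.DataFrame(
        {"gc": [p.gc for p in profiles], "domain": [p.domain for p in profiles]},
        index=[p.species_id for p in profiles],
    )
    return Dendrogram(linkage_matrix=Z, labels=list(mat.index), annotations=ann)


def cluster_matrix(
    matrix: pd.DataFrame, metric: str = "euclidean", method: str = "ward"
) -> Dendrogram:
    """Cluster the rows of an arbitrary feature matrix (shared helper)."""
    if len(matrix) < 2:
        raise ValueError("clustering requires at least 2 rows")
    Z = hierarchy.linkage(matrix.values, method=method, metric=metric)
    return Dendrogram(linkage_matrix=Z, labels=list(matrix.index))
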