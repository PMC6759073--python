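"""Seeded generator of multi-species CDS corpora with planted structure.

The generator emulates the statistical features of real multi-species
coding-sequence collections that every analysis stage assumes:

* a GC-content gradient across species, shared by all domains so GC alone
  cannot separate them;
* domain-specific arginine codon signatures (Archaea favor AGA/AGG,
  Bacteria CGC/CGT, Eukarya intermediate), plus mild domain-consistent
  tilts in a few other families;
* expression-dependent codon optimality: each gene draws a log-normal
  abundance, and codon choice interpolates linearly (in log abundance)
  between the species' baseline family distribution and a point mass on
  the planted optimal codon;
* tunable within-gene codon-pair stickiness: with probability
  ``stickiness`` an occurrence reuses the codon of the previous occurrence
  of the same amino acid, planting autocorrelation.

Ground truth (optimal sets, switch sets, stickiness) is recorded so that
downstream modules can be tested for parameter recovery. Regeneration from
the same spec and seed is byte-identical.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy.optimize import brentq

from .genetic_code import CdsRecord, GeneticCode, STANDARD_CODE
from .io import write_fasta

# Single reference amino-acid composition across all species (average
# proteome frequencies), so codon-level effects are isolated from
# amino-acid-level ones.
AA_COMPOSITION: Dict[str, float] = {
    "A": 0.0825, "R": 0.0553, "N": 0.0406, "D": 0.0545, "C": 0.0137,
    "Q": 0.0393, "E": 0.0675, "G": 0.0707, "H": 0.0227, "I": 0.0596,
    "L": 0.0966, "K": 0.0584, "M": 0.0242, "F": 0.0386, "P": 0.0470,
    "S": 0.0656, "T": 0.0534, "W": 0.0108, "Y": 0.0292, "V": 0.0687,
}

#: order of the arginine-profile weights in :class:`SpeciesSpec`
ARG_CODON_ORDER = ("CGT", "CGC", "CGA", "CGG", "AGA", "AGG")

DOMAIN_ARG_PROFILES: Dict[str, Tuple[float, ...]] = {
    # (CGT, CGC, CGA, CGG, AGA, AGG); Archaea AGA/AGG-heavy, Bacteria
    # CGC/CGT-heavy, Eukarya in between.
    "Archaea": (0.08, 0.07, 0.05, 0.05, 0.40, 0.35),
    "Bacteria": (0.34, 0.38, 0.08, 0.08, 0.06, 0.06),
    "Eukarya": (0.16, 0.20, 0.12, 0.10, 0.22, 0.20),
}

# Mild domain-consistent preferences outside arginine (multiplicative
# weight tilts), so domain signal is not carried by a single amino acid.
DOMAIN_FAMILY_TILTS: Dict[str, Dict[str, float]] = {
    "Archaea": {"TTA": 1.8, "ATA": 1.8, "GGA": 1.8, "ACA": 1.6, "GTA": 1.6,
                "CCA": 1.6, "GCA": 1.5, "TCA": 1.5},
    "Bacteria": {"CTG": 1.8, "ATC": 1.8, "GGC": 1.8, "ACC": 1.6, "GTG": 1.6,
                 "CCG": 1.6, "GCC": 1.5, "AGC": 1.5},
    "Eukarya": {"CTC": 1.8, "ATT": 1.8, "GGG": 1.8, "ACT": 1.6, "GTC": 1.6,
                "CCT": 1.6, "GCT": 1.5, "AGT": 1.5},
}

STOP_CODON = "TAA"   # appended to every gene; excluded from all statistics


@dataclass
class SpeciesSpec:
    """Everything needed to generate one synthetic species reproducibly."""

    species_id: str
    domain: str
    gc_target: float
    arginine_profile: Tuple[float, ...]          # weights in ARG_CODON_ORDER
    optimal_set: Dict[str, str]                  # amino acid -> optimal codon
    stickiness: float = 0.0
    n_genes: int = 100
    gene_length_range: Tuple[int, int] = (300, 1500)
    expression_spread: float = 1.0               # sigma of ln(abundance)
    seed: int = 0
    phylum: str = "unknown"
    family_tilts: Dict[str, float] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not 0.0 <= self.stickiness <= 1.0:
            raise ValueError("stickiness must lie in [0, 1]")
        if len(self.arginine_profile) != 6 or min(self.arginine_profile) < 0 \
                or sum(self.arginine_profile) <= 0:
            raise ValueError("arginine_profile: 6 non-negative weights, positive sum")
        lo, hi = self.gene_length_range
        if lo % 3 or hi % 3:
            raise ValueError("gene lengths must be multiples of 3")


@dataclass
class SyntheticCorpus:
    records: List[CdsRecord]
    sequence_metadata: pd.DataFrame     # seq_id, species_id
    species_metadata: pd.DataFrame      # species_id, domain, phylum
    abundance: pd.DataFrame             # gene_id, abundance
    ground_truth: Dict[str, dict]


def _codon_gc(codon: str) -> int:
    return sum(b in "GC" for b in codon)


def baseline_distributions(
    spec: SpeciesSpec, code: GeneticCode = STANDARD_CODE
) -> Dict[str, np.ndarray]:
    """Per-family baseline codon distributions for one species.

    Non-arginine families get weights ``tilt(c) * jitter(c) * exp(alpha *
    (gc(c) - 1.5))`` with alpha calibrated so the expected corpus GC matches
    ``gc_target``; ``jitter`` is a small species-specific log-normal factor
    (sigma 0.08, derived deterministically from the spec seed) giving every
    species idiosyncratic preferences, so within-family baselines have a
    well-defined preferred codon. Arginine uses the spec's profile
    unchanged (its domain signature must not be washed out by the GC
    gradient).
    """
    arg_profile = {c: w for c, w in zip(ARG_CODON_ORDER, spec.arginine_profile)}
    comp = AA_COMPOSITION
    jitter_rng = np.random.default_rng(np.random.SeedSequence([spec.seed, 0x5EED]))
    jitter = {aa: np.exp(jitter_rng.normal(0.0, 0.08, size=len(fam)))
              for aa, fam in sorted(code.families.items())}

    def dists(alpha: float) -> Dict[str, np.ndarray]:
        out = {}
        for aa, family in code.families.items():
            if aa == "R":
                w = np.array([arg_profile[c] for c in family], dtype=float)
            else:
                w = jitter[aa] * np.array(
                    [spec.family_tilts.get(c, 1.0) * np.exp(alpha * (_codon_gc(c) - 1.5))
                     for c in family])
            out[aa] = w / w.sum()
        return out

    def expected_gc(alpha: float) -> float:
        d = dists(alpha)
        return sum(
            comp[aa] * float(np.dot(d[aa], [_codon_gc(c) for c in code.families[aa]]))
            for aa in comp) / 3.0

    lo, hi = -8.0, 8.0
    if expected_gc(lo) >= spec.gc_target:
        warnings.warn(f"{spec.species_id}: gc_target {spec.gc_target} below feasible "
                      "range; best-effort")
        return dists(lo)
    if expected_gc(hi) <= spec.gc_target:
        warnings.warn(f"{spec.species_id}: gc_target {spec.gc_target} above feasible "
                      "range; best-effort")
        return dists(hi)
    alpha = brentq(lambda a: expected_gc(a) - spec.gc_target, lo, hi, xtol=1e-6)
    return dists(alpha)


# Minimum gap between the top two baseline codon probabilities for the
# baseline-preferred codon (and hence the switch truth) to count as
# identifiable: ~4 sampling standard deviations of a quintile-bin RSCU
# estimate at the default corpus sizes.
BASELINE_TIE_MARGIN = 0.02


def planted_truth(spec: SpeciesSpec, code: GeneticCode = STANDARD_CODE) -> dict:
    """Ground truth implied by a spec: baseline preferences and switch set.

    An amino acid is in the switch set when its planted optimal codon
    differs from the baseline-preferred codon (baseline argmax). Families
    whose top two baseline probabilities lie within ``BASELINE_TIE_MARGIN``
    have no statistically identifiable preference; they are listed under
    ``tied_baseline`` and excluded from the switch truth.
    """
    base = baseline_distributions(spec, code)
    preferred: Dict[str, str] = {}
    switch_set: List[str] = []
    ties: List[str] = []
    for aa, family in code.families.items():
        if len(family) < 2:
            continue
        p = base[aa]
        top = float(p.max())
        winners = [c for c, v in zip(family, p) if v == top]
        preferred[aa] = winners[0]
        if len(winners) > 1 or top - float(np.sort(p)[-2]) < BASELINE_TIE_MARGIN:
            ties.append(aa)
            continue
        if aa in spec.optimal_set and spec.optimal_set[aa] != winners[0]:
            switch_set.append(aa)
    return {
        "species_id": spec.species_id,
        "domain": spec.domain,
        "gc_target": spec.gc_target,
        "stickiness": spec.stickiness,
        "optimal_set": dict(spec.optimal_set),
        "baseline_preferred": preferred,
        "switch_set": sorted(switch_set),
        "tied_baseline": sorted(ties),
    }


def generate_species(
    spec: SpeciesSpec, code: GeneticCode = STANDARD_CODE
) -> Tuple[List[CdsRecord], Dict[str, float], dict]:
    """Generate one species' genes, abundances and ground truth.

    Per gene: the amino-acid sequence is drawn from the fixed reference
    composition; abundance is log-normal with spread ``expression_spread``;
    the optimality mix ``m = clip(ln(a) / (2 sigma), 0, 1)`` interpolates
    each planted family between baseline and a point mass on its optimal
    codon; with probability ``stickiness`` an occurrence repeats the
    previous codon of the same amino acid. A TAA stop closes every gene.
    """
    rng = np.random.default_rng(spec.seed)
    base = baseline_distributions(spec, code)
    aas = sorted(AA_COMPOSITION)
    comp = np.array([AA_COMPOSITION[a] for a in aas])
    comp = comp / comp.sum()
    families = {aa: code.families[aa] for aa in aas}
    opt_index = {aa: families[aa].index(c) for aa, c in spec.optimal_set.items()}

    lo, hi = spec.gene_length_range
    records: List[CdsRecord] = []
    abundances: Dict[str, float] = {}
    sigma = spec.expression_spread
    for g in range(spec.n_genes):
        n_codons = int(rng.integers(lo // 3, hi // 3 + 1))
        ln_a = float(rng.normal(0.0, sigma)) if sigma > 0 else 0.0
        m = float(np.clip(ln_a / (2.0 * sigma), 0.0, 1.0)) if sigma > 0 else 0.0
        aa_idx = rng.choice(len(aas), size=n_codons, p=comp)
        codons: List[Optional[str]] = [None] * n_codons
        for ai in np.unique(aa_idx):
            aa = aas[ai]
            family = families[aa]
            positions = np.flatnonzero(aa_idx == ai)
            n = positions.size
            if len(family) == 1:
                for pos in positions:
                    codons[pos] = family[0]
                continue
            p = base[aa]
            if aa in opt_index and m > 0:
                point = np.zeros(len(family))
                point[opt_index[aa]] = 1.0
                p = (1.0 - m) * p + m * point
            fresh = rng.choice(len(family), size=n, p=p)
            if spec.stickiness > 0:
                sticky = rng.random(n) < spec.stickiness
                chosen = fresh.copy()
                for t in range(1, n):
                    if sticky[t]:
                        chosen[t] = chosen[t - 1]
            else:
                chosen = fresh
            for pos, ci in zip(positions, chosen):
                codons[pos] = family[ci]
        seq_id = f"{spec.species_id}_g{g:05d}"
        records.append(CdsRecord(
            seq_id=seq_id, species_id=spec.species_id,
            sequence="".join(codons) + STOP_CODON))
        abundances[seq_id] = float(np.exp(ln_a))
    return records, abundances, planted_truth(spec, code)


def default_domain_specs(
    n_species_per_domain: int,
    seed: int = 0,
    n_genes: int = 100,
    stickiness: float = 0.0,
    expression_spread: float = 1.0,
    gene_length_range: Tuple[int, int] = (300, 1500),
    gc_range: Tuple[float, float] = (0.30, 0.70),
    plant_optimal: bool = True,
) -> List[SpeciesSpec]:
    """Default study conditions: three domains sharing one GC gradient.

    Each domain contributes ``n_species_per_domain`` species whose GC
    targets are drawn from the same jittered range (so GC does not separate
    domains), with the domain's arginine signature (lightly jittered per
    species) and mild domain-consistent tilts in other families. When
    ``plant_optimal`` is set, every multi-codon family except arginine gets
    a planted optimal codon drawn from the species' baseline distribution
    (arginine preferences stay constant across expression levels).
    """
    if n_species_per_domain < 1:
        raise ValueError("need at least one species per domain")
    rng = np.random.default_rng(seed)
    specs: List[SpeciesSpec] = []
    for domain in ("Archaea", "Bacteria", "Eukarya"):
        base_profile = np.array(DOMAIN_ARG_PROFILES[domain])
        for i in range(n_species_per_domain):
            gc_target = float(rng.uniform(*gc_range))
            jitter = np.exp(rng.normal(0.0, 0.10, size=6))
            profile = base_profile * jitter
            profile = tuple(float(x) for x in profile / profile.sum())
            sp_seed = int(rng.integers(2**31 - 1))
            spec = SpeciesSpec(
                species_id=f"{domain[:3].lower()}_{i:03d}",
                domain=domain,
                phylum=f"{domain}_phylum_{i % 2 + 1}",
                gc_target=gc_target,
                arginine_profile=profile,
                optimal_set={},
                stickiness=stickiness,
                n_genes=n_genes,
                gene_length_range=gene_length_range,
                expression_spread=expression_spread,
                seed=sp_seed,
                family_tilts=dict(DOMAIN_FAMILY_TILTS[domain]),
            )
            if plant_optimal:
                base = baseline_distributions(spec)
                optimal: Dict[str, str] = {}
                for aa in sorted(STANDARD_CODE.families):
                    family = STANDARD_CODE.families[aa]
                    if len(family) < 2 or aa == "R":
                        continue
                    optimal[aa] = family[int(rng.choice(len(family), p=base[aa]))]
                spec.optimal_set = optimal
            specs.append(spec)
    return specs


def generate_corpus(
    specs: Sequence[SpeciesSpec],
    outdir: Optional[Path] = None,
    code: GeneticCode = STANDARD_CODE,
) -> SyntheticCorpus:
    """Generate a corpus from specs; optionally write it to disk.

    When ``outdir`` is given, writes ``corpus.fasta``, ``sequences.tsv``,
    ``species.tsv``, ``abundance.tsv`` (the exact formats the readers
    consume) and ``ground_truth.json``.
    """
    if not specs:
        raise ValueError("no species specs")
    records: List[CdsRecord] = []
    seq_rows, sp_rows, ab_rows = [], [], []
    truth: Dict[str, dict] = {}
    for spec in specs:
        recs, abund, gt = generate_species(spec, code)
        records.extend(recs)
        sp_rows.append((spec.species_id, spec.domain, spec.phylum))
        for r in recs:
            seq_rows.append((r.seq_id, r.species_id))
            ab_rows.append((r.seq_id, abund[r.seq_id]))
        truth[spec.species_id] = gt
    corpus = SyntheticCorpus(
        records=records,
        sequence_metadata=pd.DataFrame(seq_rows, columns=["seq_id", "species_id"]),
        species_metadata=pd.DataFrame(sp_rows, columns=["species_id", "domain", "phylum"]),
        abundance=pd.DataFrame(ab_rows, columns=["gene_id", "abundance"]),
        ground_truth=truth,
    )
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_fasta(records, outdir / "corpus.fasta")
        corpus.sequence_metadata.to_csv(outdir / "sequences.tsv", sep="\t", index=False)
        corpus.species_metadata.to_csv(outdir / "species.tsv", sep="\t", index=False)
        corpus.abundance.to_csv(outdir / "abundance.tsv", sep="\t", index=False,
                                float_format="%.8g")
        with open(outdir / "ground_truth.json", "w") as fh:
            json.dump(truth, fh, indent=1, sort_keys=True)
    return corpus
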