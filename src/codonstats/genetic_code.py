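"""Genetic-code tables, CDS validation, codon counting and GC content.

These primitives underlie every statistic in the package: relative
synonymous codon usage (RSCU) works on codon counts produced here, the
pair-covariation statistics walk frame-0 codons produced here, and the
species profiles carry the pooled GC fractions computed here.

All coordinates are frame 0 from the first base of each record; coding
sequences are assumed to be given on the sense strand.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, Mapping, Optional, Tuple, Union

from Bio.Data import CodonTable

BASES = "ACGT"
ALL_CODONS: Tuple[str, ...] = tuple(a + b + c for a in BASES for b in BASES for c in BASES)
STOP = "*"

#: one-letter -> three-letter amino-acid names (used for canonical ordering)
AA_THREE_LETTER: Dict[str, str] = {
    "A": "Ala", "R": "Arg", "N": "Asn", "D": "Asp", "C": "Cys",
    "Q": "Gln", "E": "Glu", "G": "Gly", "H": "His", "I": "Ile",
    "L": "Leu", "K": "Lys", "M": "Met", "F": "Phe", "P": "Pro",
    "S": "Ser", "T": "Thr", "W": "Trp", "Y": "Tyr", "V": "Val",
}
THREE_TO_ONE = {v: k for k, v in AA_THREE_LETTER.items()}


class UntranslatableCodonError(ValueError):
    """Raised when a codon contains characters outside {A,C,G,T}."""


class UndefinedGCError(ValueError):
    """Raised when GC content is requested for zero unambiguous bases."""


@dataclass(frozen=True, eq=False)
class GeneticCode:
    """A codon translation table plus its synonymous-family structure.

    ``families`` maps each amino acid (one-letter code) to its ordered
    codon list; family sizes over the 20 amino acids sum to the number
    of sense codons (61 for the standard code).
    """

    code_id: str
    codon_to_aa: Mapping[str, str]
    families: Mapping[str, Tuple[str, ...]]

    def __post_init__(self) -> None:
        if set(self.codon_to_aa) != set(ALL_CODONS):
            raise ValueError("genetic code must map exactly the 64 codons")
        n_sense = sum(len(v) for v in self.families.values())
        n_stop = sum(1 for aa in self.codon_to_aa.values() if aa == STOP)
        if n_sense + n_stop != 64:
            raise ValueError("family sizes plus stop codons must cover 64 codons")

    @classmethod
    def from_ncbi_id(cls, table_id: int = 1, code_id: Optional[str] = None) -> "GeneticCode":
        """Build a code from an NCBI translation-table id (1 = standard)."""
        table = CodonTable.unambiguous_dna_by_id[table_id]
        codon_to_aa = {c: table.forward_table.get(c, STOP) for c in ALL_CODONS}
        families: Dict[str, Tuple[str, ...]] = {}
        for aa in sorted(set(codon_to_aa.values()) - {STOP}):
            families[aa] = tuple(sorted(c for c, a in codon_to_aa.items() if a == aa))
        return cls(code_id=code_id or f"ncbi_table_{table_id}", codon_to_aa=codon_to_aa,
                   families=families)

    @classmethod
    def standard(cls) -> "GeneticCode":
        return cls.from_ncbi_id(1, "standard")

    @property
    def stop_codons(self) -> Tuple[str, ...]:
        return tuple(sorted(c for c, a in self.codon_to_aa.items() if a == STOP))

    def family_of(self, codon: str) -> Tuple[str, ...]:
        aa = self.codon_to_aa[codon]
        if aa == STOP:
            raise KeyError(f"{codon} is a stop codon and belongs to no family")
        return self.families[aa]


STANDARD_CODE = GeneticCode.standard()


@dataclass
class CdsRecord:
    """One coding sequence, identified within a corpus by ``seq_id``."""

    seq_id: str
    species_id: str
    sequence: str

    @property
    def length_nt(self) -> int:
        return len(self.sequence)


@dataclass
class CodonCounts:
    """64-slot codon occurrence table for one sequence or a pooled collection."""

    counts: Dict[str, int]
    n_codons_counted: int
    n_codons_skipped: int

    @classmethod
    def zero(cls) -> "CodonCounts":
        return cls(counts={c: 0 for c in ALL_CODONS}, n_codons_counted=0, n_codons_skipped=0)

    def __add__(self, other: "CodonCounts") -> "CodonCounts":
        merged = {c: self.counts.get(c, 0) + other.counts.get(c, 0) for c in ALL_CODONS}
        return CodonCounts(
            counts=merged,
            n_codons_counted=self.n_codons_counted + other.n_codons_counted,
            n_codons_skipped=self.n_codons_skipped + other.n_codons_skipped,
        )

    @classmethod
    def pool(cls, parts: Iterable["CodonCounts"]) -> "CodonCounts":
        total = cls.zero()
        for p in parts:
            total = total + p
        return total


@dataclass
class ValidationPolicy:
    """Hard/soft rules applied by :func:`validate_cds`.

    ``partial_codon``: 'reject' (default) refuses sequences whose length is
    not a multiple of 3; 'truncate' keeps them, dropping the trailing bases.
    ``internal_stop``: 'warn' (default) retains sequences with in-frame stop
    codons before the last position; 'reject' refuses them.
    """

    partial_codon: str = "reject"
    internal_stop: str = "warn"
    max_ambiguous_fraction: float = 1.0


@dataclass
class ValidationReport:
    seq_id: str
    is_multiple_of_three: bool
    has_internal_stop: bool
    ambiguous_codon_count: int
    verdict: str  # pass | warn | reject


DEFAULT_POLICY = ValidationPolicy()


def translate_codon(codon: str, code: GeneticCode = STANDARD_CODE) -> str:
    """Translate a 3-mer to its amino acid (one-letter) or '*' for stop.

    Raises :class:`UntranslatableCodonError` for codons containing
    ambiguity characters.
    """
    codon = codon.upper()
    aa = code.codon_to_aa.get(codon)
    if aa is None:
        raise UntranslatableCodonError(f"codon {codon!r} is not translatable")
    return aa


def iter_codons(sequence: str) -> Iterable[str]:
    """Yield frame-0 codons left to right; a trailing partial codon is dropped."""
    seq = sequence.upper()
    for i in range(0, len(seq) - len(seq) % 3, 3):
        yield seq[i:i + 3]


def validate_cds(record: CdsRecord, policy: ValidationPolicy = DEFAULT_POLICY) -> ValidationReport:
    """Validate a CDS record against a policy. Never raises."""
    seq = record.sequence.upper()
    multiple_of_three = len(seq) % 3 == 0
    codons = list(iter_codons(seq))
    ambiguous = sum(1 for c in codons if any(b not in BASES for b in c))
    stops = {i for i, c in enumerate(codons)
             if all(b in BASES for b in c) and translate_codon(c) == STOP}
    # a stop at the final codon position is the terminator, not "internal"
    internal_stop = bool(stops - {len(codons) - 1})

    verdict = "pass"
    if internal_stop and policy.internal_stop == "warn":
        verdict = "warn"
    if codons and ambiguous / len(codons) > policy.max_ambiguous_fraction:
        verdict = "reject"
    if internal_stop and policy.internal_stop == "reject":
        verdict = "reject"
    if not multiple_of_three and policy.partial_codon == "reject":
        verdict = "reject"
    return ValidationReport(
        seq_id=record.seq_id,
        is_multiple_of_three=multiple_of_three,
        has_internal_stop=internal_stop,
        ambiguous_codon_count=ambiguous,
        verdict=verdict,
    )


def count_codons(record: Union[CdsRecord, str], code: GeneticCode = STANDARD_CODE) -> CodonCounts:
    """Count frame-0 codons of one record.

    Codons containing non-ACGT characters are skipped and tallied in
    ``n_codons_skipped``; stop codons are counted (they are excluded later,
    at the RSCU/pair stage). An empty sequence yields all-zero counts.
    """
    seq = record.sequence if isinstance(record, CdsRecord) else record
    counts = {c: 0 for c in ALL_CODONS}
    skipped = 0
    counted = 0
    for codon in iter_codons(seq):
        if codon in counts:
            counts[codon] += 1
            counted += 1
        else:
            skipped += 1
    return CodonCounts(counts=counts, n_codons_counted=counted, n_codons_skipped=skipped)


def gc_content(records: Union[Iterable[Union[CdsRecord, str]], CdsRecord, str]) -> float:
    """Pooled GC fraction over one or more records.

    (#G + #C) / (#A + #C + #G + #T); ambiguity characters are excluded from
    both numerator and denominator. Raises :class:`UndefinedGCError` when no
    unambiguous base is present.
    """
    if isinstance(records, (CdsRecord, str)):
        records = [records]
    gc = at = 0
    for rec in records:
        seq = (rec.sequence if isinstance(rec, CdsRecord) else rec).upper()
        gc += seq.count("G") + seq.count("C")
        at += seq.count("A") + seq.count("T")
    if gc + at == 0:
        raise UndefinedGCError("no unambiguous bases: GC content undefined")
    return gc / (gc + at)
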