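"""Corpus input/output: FASTA + metadata reading, species filtering, splits.

A corpus is a FASTA file of coding sequences (one CDS per record) plus two
TSV metadata tables:

* sequence table with columns ``seq_id``, ``species_id``;
* species table with columns ``species_id``, ``domain``, ``phylum``.

Domain and phylum labels are taken from the metadata as given, never
inferred from the sequences.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO

from .genetic_code import CdsRecord

logger = logging.getLogger(__name__)

DOMAINS = ("Archaea", "Bacteria", "Eukarya")


@dataclass
class SpeciesCollection:
    """All coding sequences of one species plus its taxonomy labels."""

    species_id: str
    domain: str
    phylum: str
    records: List[CdsRecord] = field(default_factory=list)

    @property
    def n_genes(self) -> int:
        return len(self.records)


@dataclass
class CorpusPartition:
    """A reproducible train/test split over sequence ids."""

    train: List[str]
    test: List[str]
    seed: int
    train_fraction: float

    def to_frame(self) -> pd.DataFrame:
        rows = [(s, "train") for s in self.train] + [(s, "test") for s in self.test]
        return pd.DataFrame(rows, columns=["seq_id", "split"])

    def write(self, path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def _read_tsv(path, required: Sequence[str]) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype=str)
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    return df


def read_corpus(
    fasta_path,
    sequence_metadata_path,
    species_metadata_path,
) -> List[SpeciesCollection]:
    """Read a FASTA corpus and group records into species collections.

    Sequences absent from the sequence metadata are dropped with a warning;
    duplicated ``seq_id`` values (in FASTA or metadata) are fatal. Species
    collections are returned in first-appearance order of the metadata.
    """
    seq_meta = _read_tsv(sequence_metadata_path, ["seq_id", "species_id"])
    sp_meta = _read_tsv(species_metadata_path, ["species_id", "domain", "phylum"])
    if seq_meta["seq_id"].duplicated().any():
        raise ValueError("duplicate seq_id in sequence metadata")
    if sp_meta["species_id"].duplicated().any():
        raise ValueError("duplicate species_id in species metadata")

    seq_to_species = dict(zip(seq_meta["seq_id"], seq_meta["species_id"]))
    sp_labels = sp_meta.set_index("species_id")[["domain", "phylum"]].to_dict("index")

    collections: Dict[str, SpeciesCollection] = {}
    seen: set = set()
    n_dropped = 0
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate seq_id in FASTA: {rec.id}")
        seen.add(rec.id)
        species = seq_to_species.get(rec.id)
        if species is None:
            n_dropped += 1
            logger.warning("sequence %s not in metadata; dropped", rec.id)
            continue
        if species not in collections:
            labels = sp_labels.get(species, {"domain": "unknown", "phylum": "unknown"})
            collections[species] = SpeciesCollection(
                species_id=species, domain=labels["domain"], phylum=labels["phylum"])
        collections[species].records.append(
            CdsRecord(seq_id=rec.id, species_id=species, sequence=str(rec.seq).upper()))
    if n_dropped:
        logger.warning("%d sequences dropped (no metadata mapping)", n_dropped)
    return list(collections.values())


def filter_species(
    collections: Iterable[SpeciesCollection], min_genes: int = 1000
) -> List[SpeciesCollection]:
    """Keep species with strictly more than ``min_genes`` sequences.

    The strict inequality removes sparsely sampled species whose pooled
    codon usage would be dominated by a few (possibly overrepresented)
    genes. Idempotent; preserves input order.
    """
    if min_genes < 0:
        raise ValueError("min_genes must be >= 0")
    return [c for c in collections if c.n_genes > min_genes]


def split_train_test(
    collections: Iterable[SpeciesCollection],
    train_fraction: float = 0.10,
    seed: int = 0,
    level: str = "sequence",
) -> CorpusPartition:
    """Uniform random train/test split, reproducible by seed.

    ``level='sequence'`` (default) splits individual sequences, matching a
    per-sequence classification workflow; ``level='species'`` assigns whole
    species to one side, for leakage-controlled evaluation. The train size
    is ``round(N * train_fraction)`` (banker's rounding, as Python's
    ``round``).
    """
    if not 0 < train_fraction < 1:
        raise ValueError("train_fraction must lie strictly between 0 and 1")
    rng = np.random.default_rng(seed)
    if level == "sequence":
        ids = sorted(r.seq_id for c in collections for r in c.records)
        perm = rng.permutation(len(ids))
        n_train = round(len(ids) * train_fraction)
        train = sorted(ids[i] for i in perm[:n_train])
        test = sorted(ids[i] for i in perm[n_train:])
    elif level == "species":
        cols = sorted(collections, key=lambda c: c.species_id)
        perm = rng.permutation(len(cols))
        n_train = round(len(cols) * train_fraction)
        chosen = {cols[i].species_id for i in perm[:n_train]}
        train = sorted(r.seq_id for c in cols if c.species_id in chosen for r in c.records)
        test = sorted(r.seq_id for c in cols if c.species_id not in chosen for r in c.records)
    else:
        raise ValueError(f"unknown split level {level!r}")
    logger.info("split: %d train / %d test (fraction=%.3f, seed=%d)",
                len(train), len(test), train_fraction, seed)
    return CorpusPartition(train=train, test=test, seed=seed, train_fraction=train_fraction)


def write_fasta(records: Iterable[CdsRecord], path, width: int = 70) -> None:
    with open(path, "w") as fh:
        for rec in records:
            fh.write(f">{rec.seq_id}\n")
            seq = rec.sequence
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")
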