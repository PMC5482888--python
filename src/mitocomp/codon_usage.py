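"""Codon counting and relative synonymous codon usage (RSCU).

The genetic code defaults to NCBI translation table 5 (invertebrate
mitochondrial): AGA/AGG encode serine (an eight-codon Ser family), AUA
methionine, UGA tryptophan, and only UAA/UAG terminate.  RSCU for a codon
c in a synonymous family F is ``count(c) * |F| / sum(counts over F)``;
an unbiased codon scores 1 and the values within a family sum to |F|.
Mitochondrial protein genes frequently end on an incomplete stop (a bare
``T`` or ``TA`` completed to UAA by polyadenylation); such 1-2 nt
remainders are excluded from the counts.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Iterable, Mapping, NamedTuple, Optional, Sequence

import pandas as pd
from Bio.Data import CodonTable

from .annotation_io import (GeneFeature, MitogenomeRecord, feature_sequence)
from .vocab import PCG

ALL_CODONS = tuple("".join(c) for c in itertools.product("TCAG", repeat=3))


@dataclass(frozen=True)
class GeneticCode:
    """A codon -> amino-acid mapping with its synonymous-family partition."""

    id: int
    name: str
    codon_to_aa: Mapping[str, str]          # '*' for stop codons
    families: Mapping[str, tuple[str, ...]]  # aa symbol -> codons

    @classmethod
    def from_ncbi_id(cls, table_id: int = 5) -> "GeneticCode":
        tbl = CodonTable.unambiguous_dna_by_id[table_id]
        mapping = dict(tbl.forward_table)
        for stop in tbl.stop_codons:
            mapping[stop] = "*"
        fams: dict[str, list[str]] = {}
        for codon in ALL_CODONS:
            fams.setdefault(mapping[codon], []).append(codon)
        return cls(id=table_id, name=tbl.names[0],
                   codon_to_aa=mapping,
                   families={aa: tuple(cs) for aa, cs in fams.items()})

    def family_of(self, codon: str) -> tuple[str, ...]:
        return self.families[self.codon_to_aa[codon]]

    @property
    def stop_codons(self) -> tuple[str, ...]:
        return self.families["*"]


INVERTEBRATE_MITO = GeneticCode.from_ncbi_id(5)


def extract_cds(record: MitogenomeRecord, feature: GeneFeature) -> str:
    """mRNA-sense CDS of a protein-coding feature (N genes rev-complemented)."""
    if feature.gene_class != PCG:
        raise ValueError(f"{feature.name} is not a protein-coding gene")
    return feature_sequence(record, feature, oriented=True)


def count_codons(cds_sequences: Iterable[str],
                 code: GeneticCode = INVERTEBRATE_MITO) -> dict[str, int]:
    """Aggregate codon counts over CDS sequences.

    Triplets are read in frame from the first position of each CDS; a 1-2 nt
    trailing remainder (incomplete stop) is dropped.  All 64 codons appear
    in the result, absent ones with count 0.
    """
    counts = {c: 0 for c in ALL_CODONS}
    for i, cds in enumerate(cds_sequences):
        s = cds.upper()
        if len(s) < 3:
            raise ValueError(f"CDS #{i} shorter than one codon")
        for j in range(0, len(s) - len(s) % 3, 3):
            codon = s[j:j + 3]
            if codon not in counts:
                raise ValueError(
                    f"CDS #{i}: non-ACGT codon {codon!r} at position {j + 1}")
            counts[codon] += 1
    return counts


def rscu(counts: Mapping[str, int],
         code: GeneticCode = INVERTEBRATE_MITO) -> dict[str, float]:
    """RSCU per codon; a family with zero total maps entirely to 0."""
    out: dict[str, float] = {}
    for family in code.families.values():
        total = sum(counts.get(c, 0) for c in family)
        k = len(family)
        for c in family:
            out[c] = counts.get(c, 0) * k / total if total else 0.0
    return out


@dataclass
class CodonUsageTable:
    """Counts + RSCU for a set of genes under one genetic code."""

    counts: dict[str, int]
    rscu: dict[str, float]
    code: GeneticCode
    genes: list[str] = field(default_factory=list)

    @classmethod
    def from_record(cls, record: MitogenomeRecord,
                    code: GeneticCode = INVERTEBRATE_MITO,
                    genes: Optional[Sequence[str]] = None) -> "CodonUsageTable":
        feats = [f for f in record.features_of_class(PCG)
                 if genes is None or f.name in genes]
        counts = count_codons((extract_cds(record, f) for f in feats), code)
        return cls(counts=counts, rscu=rscu(counts, code), code=code,
                   genes=[f.name for f in feats])


def report_codon_table(usage: CodonUsageTable,
                       decimals: int = 2) -> pd.DataFrame:
    """Codon / amino acid / count / RSCU table, codons shown as RNA."""
    rows = [
        {"codon": c.replace("T", "U"),
         "aa": usage.code.codon_to_aa[c],
         "count": usage.counts.get(c, 0),
         "RSCU": round(usage.rscu.get(c, 0.0), decimals)}
        for c in ALL_CODONS
    ]
    return pd.DataFrame(rows)


class StartStop(NamedTuple):
    start: str
    stop: str
    complete: bool  # True only for a trailing TAA/TAG triplet


def annotate_start_stop(cds: str,
                        code: GeneticCode = INVERTEBRATE_MITO) -> StartStop:
    """First codon and terminal stop of a CDS.

    The stop is the final complete triplet when that triplet is a stop codon
    of the code; otherwise the 1-2 nt remainder (or the non-stop final
    triplet) is returned with ``complete=False``.
    """
    s = cds.upper()
    if len(s) < 3:
        raise ValueError("CDS shorter than one codon")
    start = s[:3]
    rem = len(s) % 3
    if rem:
        return StartStop(start, s[-rem:], False)
    last = s[-3:]
    return StartStop(start, last, last in code.stop_codons)
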