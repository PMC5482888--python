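"""Base composition and strand-skew statistics.

AT skew = (A - T)/(A + T) and GC skew = (G - C)/(G + C) quantify the
compositional asymmetry between the two strands of a mitogenome; both lie
in [-1, 1] and change sign under reverse complementation.  Profiles can be
computed for the whole genome or for annotation-defined regions (protein
genes, tRNAs, rRNAs, control region).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass
from typing import Iterable

import pandas as pd

from .annotation_io import MitogenomeRecord, feature_sequence
from .vocab import CR, PCG, RRNA, TRNA

REGION_ORDER = ("genome", "PCGs", "tRNAs", "rRNAs", "CR")
_REGION_CLASS = {"PCGs": PCG, "tRNAs": TRNA, "rRNAs": RRNA, "CR": CR}


def at_skew(a: float, t: float) -> float:
    """(A - T)/(A + T); accepts counts or percentages (scale-free)."""
    if a < 0 or t < 0:
        raise ValueError("base quantities must be non-negative")
    if a + t == 0:
        raise ValueError("undefined skew: A + T is zero")
    return (a - t) / (a + t)


def gc_skew(g: float, c: float) -> float:
    """(G - C)/(G + C); accepts counts or percentages (scale-free)."""
    if g < 0 or c < 0:
        raise ValueError("base quantities must be non-negative")
    if g + c == 0:
        raise ValueError("undefined skew: G + C is zero")
    return (g - c) / (g + c)


@dataclass(frozen=True)
class CompositionProfile:
    """Exact base counts plus derived fractions and skews for one region."""

    label: str
    a: int
    c: int
    g: int
    t: int

    @property
    def total(self) -> int:
        return self.a + self.c + self.g + self.t

    def pct(self, base: str) -> float:
        return 100.0 * getattr(self, base.lower()) / self.total

    @property
    def at_content(self) -> float:
        return self.pct("A") + self.pct("T")

    @property
    def at_skew(self) -> float:
        return at_skew(self.a, self.t)

    @property
    def gc_skew(self) -> float:
        return gc_skew(self.g, self.c)

    def as_row(self, pct_decimals: int = 1, skew_decimals: int = 3) -> dict:
        """Report row rounded for display; internal values stay exact."""
        return {
            "region": self.label,
            "size_bp": self.total,
            "A%": round(self.pct("A"), pct_decimals),
            "G%": round(self.pct("G"), pct_decimals),
            "T%": round(self.pct("T"), pct_decimals),
            "C%": round(self.pct("C"), pct_decimals),
            "A+T%": round(self.at_content, pct_decimals),
            "AT-skew": round(self.at_skew, skew_decimals),
            "GC-skew": round(self.gc_skew, skew_decimals),
        }


def composition_profile(sequence: str, label: str = "") -> CompositionProfile:
    """Count bases of an A/C/G/T sequence; ambiguity codes are rejected."""
    if not sequence:
        raise ValueError("empty sequence")
    counts = Counter(sequence.upper())
    bad = set(counts) - set("ACGT")
    if bad:
        pos = next(i for i, ch in enumerate(sequence.upper()) if ch in bad)
        raise ValueError(
            f"non-ACGT symbol {sequence[pos]!r} at position {pos + 1}")
    return CompositionProfile(label=label, a=counts["A"], c=counts["C"],
                              g=counts["G"], t=counts["T"])


def region_profiles(record: MitogenomeRecord,
                    strand: str = "coding") -> dict[str, CompositionProfile]:
    """Profiles for the whole genome and each feature class.

    ``strand="coding"`` (default) concatenates each gene on its annotated
    mRNA-sense strand; ``strand="J"`` uses the deposited strand for every
    gene.  The whole-genome profile is always computed on the J strand.
    Regions with no member features are omitted.
    """
    if strand not in ("coding", "J"):
        raise ValueError("strand must be 'coding' or 'J'")
    if record.sequence is None:
        raise ValueError("record carries no sequence")
    out = {"genome": composition_profile(record.sequence, "genome")}
    for label, cls in _REGION_CLASS.items():
        members = record.features_of_class(cls)
        if not members:
            continue
        concat = "".join(
            feature_sequence(record, f, oriented=(strand == "coding"))
            for f in members)
        out[label] = composition_profile(concat, label)
    return out


def composition_table(records: Iterable[MitogenomeRecord],
                      pct_decimals: int = 1,
                      skew_decimals: int = 3) -> pd.DataFrame:
    """One whole-genome row per record (size, base %, A+T%, skews)."""
    rows = []
    for rec in records:
        prof = composition_profile(rec.sequence, rec.accession)
        row = prof.as_row(pct_decimals, skew_decimals)
        row["region"] = rec.accession
        rows.append(row)
    df = pd.DataFrame(rows).rename(columns={"region": "record"})
    return df
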