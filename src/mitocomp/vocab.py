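"""Controlled vocabulary for metazoan mitochondrial gene names.

The canonical symbol set covers the standard 37-gene complement of animal
mitogenomes (13 protein-coding genes, 22 tRNAs with the serine/leucine
isoacceptors disambiguated as S1/S2 and L1/L2, two rRNAs) plus the
non-coding control region ``CR``.  Matching is case-insensitive and an
alias map absorbs the common synonyms found in GenBank records
(``COI`` -> ``cox1``, ``tRNA-Ser`` with an AGN note -> ``trnS1``, ...).
"""

from __future__ import annotations

import re

PCG, TRNA, RRNA, CR = "PCG", "tRNA", "rRNA", "CR"

PCG_NAMES = (
    "cox1", "cox2", "cox3", "atp6", "atp8",
    "nad1", "nad2", "nad3", "nad4", "nad4L", "nad5", "nad6", "cob",
)
TRNA_NAMES = (
    "trnA", "trnC", "trnD", "trnE", "trnF", "trnG", "trnH", "trnI",
    "trnK", "trnL1", "trnL2", "trnM", "trnN", "trnP", "trnQ", "trnR",
    "trnS1", "trnS2", "trnT", "trnV", "trnW", "trnY",
)
RRNA_NAMES = ("rrnL", "rrnS")
CR_NAME = "CR"

#: every accepted canonical symbol, in a stable order
ALL_NAMES = PCG_NAMES + TRNA_NAMES + RRNA_NAMES + (CR_NAME,)

_CLASS_OF = {n: PCG for n in PCG_NAMES}
_CLASS_OF.update({n: TRNA for n in TRNA_NAMES})
_CLASS_OF.update({n: RRNA for n in RRNA_NAMES})
_CLASS_OF[CR_NAME] = CR

# lower-cased alias -> canonical
_ALIASES = {
    "co1": "cox1", "coi": "cox1", "coxi": "cox1",
    "co2": "cox2", "coii": "cox2", "coxii": "cox2",
    "co3": "cox3", "coiii": "cox3", "coxiii": "cox3",
    "atpase6": "atp6", "atpase8": "atp8",
    "nd1": "nad1", "nd2": "nad2", "nd3": "nad3", "nd4": "nad4",
    "nd4l": "nad4L", "nd5": "nad5", "nd6": "nad6",
    "cytb": "cob", "cb": "cob",
    "rrn16": "rrnL", "16s": "rrnL", "l-rrna": "rrnL", "lrrna": "rrnL",
    "rrn12": "rrnS", "12s": "rrnS", "s-rrna": "rrnS", "srrna": "rrnS",
    "d-loop": "CR", "dloop": "CR", "control region": "CR",
    "a+t-rich region": "CR", "at-rich region": "CR",
    "trns(agn)": "trnS1", "trns(ucn)": "trnS2",
    "trnl(cun)": "trnL1", "trnl(uur)": "trnL2",
}

_AA3_TO_1 = {
    "ala": "A", "arg": "R", "asn": "N", "asp": "D", "cys": "C",
    "gln": "Q", "glu": "E", "gly": "G", "his": "H", "ile": "I",
    "leu": "L", "lys": "K", "met": "M", "phe": "F", "pro": "P",
    "ser": "S", "thr": "T", "trp": "W", "tyr": "Y", "val": "V",
}

_TRNA_RE = re.compile(
    r"^trna[-_ ]?(?P<aa>[a-z]{3})\s*(?:\((?P<codon>[a-z]{3})\))?$"
)

# codon-family qualifiers disambiguating the duplicated isoacceptors
_SER_LEU_FAMILY = {
    ("S", "agn"): "trnS1", ("S", "ucn"): "trnS2", ("S", "tcn"): "trnS2",
    ("L", "cun"): "trnL1", ("L", "uur"): "trnL2", ("L", "ttr"): "trnL2",
}


class UnknownGeneError(ValueError):
    """Raised for a symbol outside the accepted mitochondrial vocabulary."""

    def __init__(self, symbol: str):
        super().__init__(
            f"unknown gene symbol {symbol!r}; accepted symbols are: "
            + ", ".join(ALL_NAMES)
        )
        self.symbol = symbol


def canonical_name(symbol: str) -> str:
    """Map ``symbol`` to its canonical gene name.

    Raises :class:`UnknownGeneError` if the symbol cannot be resolved.
    ``trnS``/``trnL`` without an isoacceptor qualifier are ambiguous and
    rejected.
    """
    s = symbol.strip()
    low = s.lower()
    # exact canonical match (case-insensitive)
    for name in ALL_NAMES:
        if low == name.lower():
            return name
    if low in _ALIASES:
        return _ALIASES[low]
    m = _TRNA_RE.match(low)
    if m:
        aa = _AA3_TO_1.get(m.group("aa"))
        if aa in ("S", "L"):
            codon = m.group("codon")
            if codon and (aa, codon) in _SER_LEU_FAMILY:
                return _SER_LEU_FAMILY[(aa, codon)]
            # serine/leucine without an isoacceptor qualifier is ambiguous
            raise UnknownGeneError(symbol)
        if aa is not None:
            cand = f"trn{aa}"
            if cand in TRNA_NAMES:
                return cand
    raise UnknownGeneError(symbol)


def gene_class(name: str) -> str:
    """Return the feature class (PCG / tRNA / rRNA / CR) of a canonical name."""
    try:
        return _CLASS_OF[name]
    except KeyError:
        raise UnknownGeneError(name) from None


#: compact labels used in linear gene-order maps (single letters for tRNAs)
SHORT_LABEL = {n: n for n in PCG_NAMES + RRNA_NAMES + (CR_NAME,)}
SHORT_LABEL.update({n: n[3:] for n in TRNA_NAMES})  # trnL2 -> "L2", trnK -> "K"
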