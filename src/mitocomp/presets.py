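"""Published reference parameters for *Clistocoeloma sinensis* (GenBank KU589292).

These constants transcribe the published annotation summary, per-region
base compositions and codon-usage counts for the 15,706 bp *C. sinensis*
mitogenome.  They serve two roles: a ready-made annotation record for the
analysis stages, and the default parameterisation of the synthetic
mitogenome generator (:mod:`mitocomp.synthetic`), so that a realistic
KU589292-like record can be produced without network access.
"""

from __future__ import annotations

from .annotation_io import GeneFeature, MitogenomeRecord
from .vocab import gene_class

ACCESSION = "KU589292"
GENOME_LENGTH = 15_706

# gene, orientation (J/N/None), start, end, anticodon, start codon, stop codon
# Row order is annotation order around the circle starting at cox1.
_REFERENCE_ROWS = [
    ("cox1",  "J",  1,     1535,  None,  "ATG", "TA"),
    ("trnL2", "J",  1536,  1601,  "TAA", None,  None),
    ("cox2",  "J",  1608,  2295,  None,  "ATG", "T"),
    ("trnK",  "J",  2296,  2365,  "TTT", None,  None),
    ("trnD",  "J",  2366,  2433,  "GTC", None,  None),
    ("atp8",  "J",  2434,  2592,  None,  "ATG", "TAA"),
    ("atp6",  "J",  2586,  3259,  None,  "ATT", "TA"),
    ("cox3",  "J",  3260,  4050,  None,  "ATG", "TA"),
    ("trnG",  "J",  4051,  4115,  "TCC", None,  None),
    ("nad3",  "J",  4116,  4466,  None,  "ATT", "TAA"),
    ("trnA",  "J",  4469,  4532,  "TGC", None,  None),
    ("trnR",  "J",  4538,  4601,  "TCG", None,  None),
    ("trnN",  "J",  4604,  4674,  "GTT", None,  None),
    ("trnS1", "J",  4676,  4743,  "TCT", None,  None),
    ("trnE",  "J",  4743,  4810,  "TTC", None,  None),
    ("trnH",  "N",  4820,  4886,  "GTG", None,  None),
    ("trnF",  "N",  4887,  4951,  "GAA", None,  None),
    ("nad5",  "N",  4956,  6686,  None,  "ATG", "TAA"),
    ("nad4",  "N",  6687,  8065,  None,  "ATG", "TA"),
    ("nad4L", "N",  8066,  8361,  None,  "ATG", "A"),
    ("trnT",  "J",  8369,  8434,  "TGT", None,  None),
    ("trnP",  "N",  8435,  8502,  "TGG", None,  None),
    ("nad6",  "J",  8505,  9008,  None,  "ATT", "TAA"),
    ("cob",   "J",  9009,  10143, None,  "ATT", "A"),
    ("trnS2", "J",  10144, 10212, "TGA", None,  None),
    ("nad1",  "N",  10231, 11169, None,  "ATA", "TAA"),
    ("trnL1", "N",  11209, 11276, "TAG", None,  None),
    ("rrnL",  "N",  11277, 12612, None,  None,  None),
    ("trnV",  "N",  12613, 12685, "TAC", None,  None),
    ("rrnS",  "N",  12686, 13517, None,  None,  None),
    ("CR",    None, 13518, 14201, None,  None,  None),
    ("trnQ",  "N",  14202, 14269, "TTG", None,  None),
    ("trnI",  "J",  14340, 14405, "GAT", None,  None),
    ("trnM",  "J",  14418, 14487, "CAT", None,  None),
    ("nad2",  "J",  14488, 15493, None,  "ATG", "T"),
    ("trnW",  "J",  15494, 15562, "TCA", None,  None),
    ("trnC",  "N",  15574, 15637, "GCA", None,  None),
    ("trnY",  "N",  15638, 15706, "GTA", None,  None),
]

#: published whole-genome base percentages (A, C, G, T)
GENOME_COMPOSITION = {"A": 37.1, "C": 14.9, "G": 9.4, "T": 38.6}

#: published per-region base percentages on the regions' reported scale
REGION_COMPOSITION = {
    "PCGs":  {"A": 36.1, "C": 15.9, "G": 9.9,  "T": 38.1},
    "tRNAs": {"A": 37.7, "C": 12.8, "G": 11.0, "T": 38.5},
    "rRNAs": {"A": 40.4, "C": 13.0, "G": 6.8,  "T": 39.8},
    "CR":    {"A": 43.4, "C": 10.5, "G": 6.6,  "T": 39.5},
}

#: published codon counts over the 13 protein-coding genes (DNA alphabet);
#: the RSCU column of the same table is reproduced from these counts by
#: :func:`mitocomp.codon_usage.rscu` under translation table 5.
CODON_COUNTS = {
    "TTT": 291, "TTC": 42,  "TTA": 401, "TTG": 45,
    "CTT": 60,  "CTC": 10,  "CTA": 49,  "CTG": 2,
    "ATT": 312, "ATC": 26,  "ATA": 203, "ATG": 28,
    "GTT": 85,  "GTC": 5,   "GTA": 115, "GTG": 7,
    "TCT": 111, "TCC": 14,  "TCA": 96,  "TCG": 3,
    "CCT": 90,  "CCC": 6,   "CCA": 40,  "CCG": 2,
    "ACT": 86,  "ACC": 13,  "ACA": 55,  "ACG": 2,
    "GCT": 113, "GCC": 11,  "GCA": 54,  "GCG": 6,
    "TAT": 140, "TAC": 19,  "TAA": 8,   "TAG": 0,
    "CAT": 64,  "CAC": 12,  "CAA": 70,  "CAG": 2,
    "AAT": 128, "AAC": 19,  "AAA": 82,  "AAG": 14,
    "GAT": 50,  "GAC": 11,  "GAA": 66,  "GAG": 10,
    "TGT": 27,  "TGC": 3,   "TGA": 89,  "TGG": 9,
    "CGT": 16,  "CGC": 0,   "CGA": 32,  "CGG": 3,
    "AGT": 47,  "AGC": 1,   "AGA": 77,  "AGG": 15,
    "GGT": 72,  "GGC": 9,   "GGA": 117, "GGG": 17,
}


def reference_record() -> MitogenomeRecord:
    """The published *C. sinensis* annotation as a record (no sequence)."""
    feats = [
        GeneFeature(name=name, gene_class=gene_class(name),
                    orientation=orient, start=start, end=end,
                    anticodon=anticodon, start_codon=start_codon,
                    stop_codon=stop_codon)
        for name, orient, start, end, anticodon, start_codon, stop_codon
        in _REFERENCE_ROWS
    ]
    return MitogenomeRecord(accession=ACCESSION,
                            genome_length=GENOME_LENGTH, features=feats)
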