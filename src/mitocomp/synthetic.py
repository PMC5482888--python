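"""Synthetic mitogenomes and tree-evolved alignments for testing the pipeline.

The generator assembles an annotated circular genome from an explicit plan
(gene order, per-gene lengths, inter-gene spacers, per-region base
composition, codon-usage weights).  The default plan emulates the
published *C. sinensis* record (KU589292): a 15,706 bp circle with the 37
genes + control region at their published coordinates, ~75.7% A+T, and
protein genes drawn codon-wise from the published codon-usage counts so
that RSCU estimates are recoverable from the simulated sequence.

Non-coding stretches (control region, spacers) are sampled i.i.d. per
base from the target composition — no repeat or secondary structure is
modelled.  Alignments for the phylogeny stage are evolved site-wise under
Jukes-Cantor along a user-supplied tree, which keeps a closed form
(p = 3/4 (1 - e^{-4b/3})) available for validating the simulator itself.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field
from typing import Mapping, Optional, Union

import numpy as np
import skbio

from . import presets
from .annotation_io import (GeneFeature, MitogenomeRecord, feature_length,
                            intergenic_spacer, reverse_complement)
from .codon_usage import ALL_CODONS, INVERTEBRATE_MITO, GeneticCode
from .gene_order import Event, GeneOrder, apply_event
from .vocab import CR, PCG, RRNA, TRNA, gene_class

BASES = np.frombuffer(b"ACGT", dtype="S1")


def _fractions(composition: Mapping[str, float]) -> np.ndarray:
    v = np.array([composition[b] for b in "ACGT"], dtype=float)
    if (v < 0).any() or v.sum() <= 0:
        raise ValueError("composition must be non-negative with positive sum")
    return v / v.sum()


def random_sequence(length: int, composition: Mapping[str, float],
                    rng: np.random.Generator) -> str:
    """i.i.d. sequence with the given A/C/G/T weights (any positive scale)."""
    if length < 1:
        raise ValueError("length must be >= 1")
    draws = rng.choice(BASES, size=length, p=_fractions(composition))
    return draws.tobytes().decode()


def generate_cds(length: int, weights: Mapping[str, float],
                 code: GeneticCode = INVERTEBRATE_MITO,
                 rng: Optional[np.random.Generator] = None,
                 seed: Optional[int] = None,
                 start_codon: str = "ATG",
                 stop_codon: str = "TAA") -> str:
    """Codon-wise random CDS of exactly ``length`` nt, mRNA sense.

    Interior codons are drawn from ``weights`` with the code's stop codons
    forced to zero weight; the first codon is ``start_codon``.  The tail
    encodes the stop: a complete ``stop_codon`` when ``length`` is a
    multiple of 3, else the incomplete remainder ``T``/``TA``.
    """
    if rng is None:
        rng = np.random.default_rng(seed)
    if length < 3:
        raise ValueError("CDS length must be >= 3")
    w = np.array([weights.get(c, 0.0) for c in ALL_CODONS], dtype=float)
    if (w < 0).any():
        raise ValueError("codon weights must be non-negative")
    for i, c in enumerate(ALL_CODONS):
        if c in code.stop_codons:
            w[i] = 0.0
    if w.sum() <= 0:
        raise ValueError("all usable codon weights are zero")
    p = w / w.sum()
    rem = length % 3
    tail = {0: stop_codon, 1: "T", 2: "TA"}[rem]
    n_random = (length - 3 - len(tail)) // 3 if rem == 0 else \
        (length - 3 - rem) // 3
    if n_random < 0:
        raise ValueError(f"length {length} too short for start + stop")
    idx = rng.choice(len(ALL_CODONS), size=n_random, p=p)
    body = "".join(ALL_CODONS[i] for i in idx)
    return start_codon + body + tail


@dataclass
class GenomeSpec:
    """Plan for one synthetic mitogenome.

    ``gene_order`` fixes the circular arrangement and strands;
    ``lengths``/``spacers`` fix the coordinates (spacers keyed by the
    upstream gene name, negative = overlap with the next gene);
    ``region_composition`` drives the non-coding and RNA-gene sequences;
    ``codon_weights`` drives the protein genes.  The ``ku589292_like``
    classmethod fills every field with the published values.
    """

    gene_order: GeneOrder
    lengths: dict[str, int]
    spacers: dict[str, int]
    region_composition: dict[str, dict[str, float]]
    codon_weights: dict[str, float]
    gene_meta: dict[str, tuple[Optional[str], Optional[str], Optional[str]]] \
        = field(default_factory=dict)  # name -> (anticodon, start, stop)
    accession: str = "synthetic"
    seed: int = 0

    def __post_init__(self):
        for name, L in self.lengths.items():
            if L < 1:
                raise ValueError(f"{name}: length must be >= 1")
        total = sum(self.lengths.values()) + sum(self.spacers.values())
        if total < 1:
            raise ValueError("plan yields a non-positive genome length")

    @property
    def genome_length(self) -> int:
        return sum(self.lengths.values()) + sum(self.spacers.values())

    @classmethod
    def ku589292_like(cls, seed: int = 0) -> "GenomeSpec":
        ref = presets.reference_record()
        feats = sorted(ref.features, key=lambda f: f.start)
        sign = {"J": +1, "N": -1, None: 0}
        order = GeneOrder(tuple((f.name, sign[f.orientation]) for f in feats))
        lengths = {f.name: feature_length(f, ref.genome_length) for f in feats}
        spacers = {
            prev.name: intergenic_spacer(prev, nxt, ref.genome_length)
            for prev, nxt in zip(feats, feats[1:] + feats[:1])
        }
        meta = {f.name: (f.anticodon, f.start_codon, f.stop_codon)
                for f in feats}
        return cls(gene_order=order, lengths=lengths, spacers=spacers,
                   region_composition={k: dict(v) for k, v in
                                       presets.REGION_COMPOSITION.items()},
                   codon_weights=dict(presets.CODON_COUNTS),
                   gene_meta=meta,
                   accession="synthetic-" + presets.ACCESSION, seed=seed)


_REGION_OF_CLASS = {TRNA: "tRNAs", RRNA: "rRNAs", CR: "CR"}


def generate_genome(spec: GenomeSpec,
                    seed: Optional[int] = None) -> MitogenomeRecord:
    """Materialise a spec into an annotated record with sequence.

    Genes are laid out around the circle in order; a negative spacer makes
    the next gene start inside the previous one (the downstream gene's
    sequence takes precedence over the overlap, as in real atp8/atp6
    overlaps where the frames share bases).  Remaining unassigned
    positions are filled from the control-region composition.  The same
    seed always yields the same record.
    """
    rng = np.random.default_rng(spec.seed if seed is None else seed)
    L = spec.genome_length
    code = INVERTEBRATE_MITO

    # coordinate plan
    coords: list[tuple[str, int, int, int]] = []  # (name, sign, start, end)
    pos = 1
    for name, sign in spec.gene_order.elements:
        if name not in spec.lengths:
            raise ValueError(f"no length planned for {name}")
        glen = spec.lengths[name]
        start, end = pos, pos + glen - 1
        coords.append((name, sign, start, end))
        pos = end + 1 + spec.spacers.get(name, 0)
    if pos - 1 != L:
        raise ValueError("plan does not close the circle")

    genome = np.full(L, b"-", dtype="S1")
    feats: list[GeneFeature] = []
    for name, sign, start, end in coords:
        cls = gene_class(name)
        glen = end - start + 1
        anticodon, start_codon, stop_codon = spec.gene_meta.get(
            name, (None, None, None))
        if cls == PCG:
            seq = generate_cds(glen, spec.codon_weights, code, rng=rng,
                               start_codon=start_codon or "ATG",
                               stop_codon=(stop_codon if stop_codon in
                                           code.stop_codons else "TAA"))
            # record what the plan actually encodes at the tail
            rem = glen % 3
            stop_out = seq[-3:] if rem == 0 else seq[-rem:]
            start_out = seq[:3]
        else:
            comp = spec.region_composition[_REGION_OF_CLASS[cls]]
            seq = random_sequence(glen, comp, rng)
            start_out = stop_out = None
        placed = reverse_complement(seq) if sign < 0 else seq
        arr = np.frombuffer(placed.encode(), dtype="S1")
        idx = (np.arange(start - 1, end) % L)
        genome[idx] = arr
        wrapped_end = end if end <= L else end - L
        feats.append(GeneFeature(
            name=name, gene_class=cls,
            orientation=None if sign == 0 else ("J" if sign > 0 else "N"),
            start=start, end=wrapped_end,
            anticodon=anticodon if cls == TRNA else None,
            start_codon=start_out if cls == PCG else None,
            stop_codon=stop_out if cls == PCG else None,
        ))

    gaps = genome == b"-"
    n_gap = int(gaps.sum())
    if n_gap:
        filler = random_sequence(
            n_gap, spec.region_composition["CR"], rng)
        genome[gaps] = np.frombuffer(filler.encode(), dtype="S1")

    return MitogenomeRecord(
        accession=spec.accession, genome_length=L, features=feats,
        sequence=genome.tobytes().decode(), circular=True)


def apply_rearrangement(order: GeneOrder, event: Event) -> GeneOrder:
    """Apply swap / translocation / inversion / identity to a gene order."""
    return apply_event(order, event)


# ---------------------------------------------------------------------------
# sequence evolution along a tree (Jukes-Cantor)

def _as_tree(tree: Union[str, "skbio.TreeNode"]) -> "skbio.TreeNode":
    if isinstance(tree, skbio.TreeNode):
        return tree
    return skbio.TreeNode.read(io.StringIO(tree))


def simulate_alignment_on_tree(tree: Union[str, "skbio.TreeNode"],
                               length: int,
                               seed: Optional[int] = None,
                               rng: Optional[np.random.Generator] = None,
                               ) -> dict[str, str]:
    """Evolve a gap-free alignment along a tree under Jukes-Cantor.

    Branch lengths are expected substitutions per site; along a branch of
    length b each site changes with probability 3/4 (1 - e^{-4b/3}), to a
    uniformly chosen different base.  The root sequence is uniform over
    A/C/G/T.  Internal nodes must be strictly bifurcating (the root may be
    an unrooted trifurcation).
    """
    t = _as_tree(tree)
    if rng is None:
        rng = np.random.default_rng(seed)
    for node in t.non_tips(include_self=False):
        if len(node.children) != 2:
            raise ValueError("tree must be binary (non-root internal node "
                             f"with {len(node.children)} children)")
    if len(t.children) not in (2, 3):
        raise ValueError("root must have 2 or 3 children")

    root_seq = rng.integers(0, 4, size=length)
    out: dict[str, str] = {}

    def descend(node, seq):
        for child in node.children:
            b = child.length or 0.0
            if b < 0:
                raise ValueError("branch lengths must be >= 0")
            p_change = 0.75 * (1.0 - np.exp(-4.0 * b / 3.0))
            child_seq = seq.copy()
            hit = rng.random(length) < p_change
            n_hit = int(hit.sum())
            if n_hit:
                # uniform over the 3 other bases
                shift = rng.integers(1, 4, size=n_hit)
                child_seq[hit] = (child_seq[hit] + shift) % 4
            if child.is_tip():
                out[child.name] = BASES[child_seq].tobytes().decode()
            else:
                descend(child, child_seq)

    descend(t, root_seq)
    return out
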