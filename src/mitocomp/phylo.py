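"""Desk-scale phylogenetic support stage: supermatrix, NJ, bootstrap.

This stage mirrors the *role* of a full model-based phylogenomic analysis
(concatenate per-gene alignments, drop poorly aligned columns, infer a
tree, attach support values, test sister-pair hypotheses) with fast,
deterministic components: uncorrected p-distances, neighbor-joining with
the canonical Q criterion, and a column-resampling bootstrap.  It is a
stand-in for heavy ML/Bayesian inference, suitable for pipeline testing
and simulation studies, not a reimplementation of those engines.

Column filtering is a simplified conserved-block filter in the spirit of
alignment-masking tools: keep maximal runs of columns that are
sufficiently gap-free and conserved, discarding runs shorter than a
minimum block length.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import skbio
from Bio import SeqIO
from skbio import DistanceMatrix, TreeNode

GAP = ord("-")


@dataclass
class Supermatrix:
    """Equal-length concatenated alignment with a gene -> column map."""

    taxa: list[str]
    sequences: list[str]                     # aligned, over {A,C,G,T,-}
    partitions: dict[str, tuple[int, int]] = field(default_factory=dict)
    # partitions are 0-based half-open column intervals

    def __post_init__(self):
        if len(self.taxa) != len(self.sequences):
            raise ValueError("taxa and sequences differ in number")
        widths = {len(s) for s in self.sequences}
        if len(widths) > 1:
            raise ValueError(f"rows have unequal lengths: {sorted(widths)}")

    @property
    def n_columns(self) -> int:
        return len(self.sequences[0]) if self.sequences else 0

    def as_array(self) -> np.ndarray:
        return np.frombuffer(
            "".join(self.sequences).encode(), dtype=np.uint8
        ).reshape(len(self.taxa), self.n_columns)

    def row(self, taxon: str) -> str:
        return self.sequences[self.taxa.index(taxon)]


def read_fasta_alignment(path) -> list[tuple[str, str]]:
    """(name, sequence) pairs of a FASTA alignment, in file order."""
    return [(rec.id, str(rec.seq).upper())
            for rec in SeqIO.parse(str(path), "fasta")]


def concatenate_supermatrix(
    gene_alignments: Mapping[str, Union[Mapping[str, str],
                                        Sequence[tuple[str, str]]]],
) -> Supermatrix:
    """Concatenate per-gene alignments into one matrix.

    Taxa are the union over genes (first-appearance order); a taxon absent
    from a gene gets an all-gap stretch for that partition.  A taxon
    occurring twice within one gene is an error.
    """
    per_gene: dict[str, dict[str, str]] = {}
    taxa: list[str] = []
    for gene, aln in gene_alignments.items():
        pairs = list(aln.items()) if isinstance(aln, Mapping) else list(aln)
        seen: dict[str, str] = {}
        for taxon, seq in pairs:
            if taxon in seen:
                raise ValueError(f"duplicate taxon {taxon!r} in gene {gene}")
            seen[taxon] = seq.upper()
            if taxon not in taxa:
                taxa.append(taxon)
        widths = {len(s) for s in seen.values()}
        if len(widths) > 1:
            raise ValueError(f"gene {gene}: unequal sequence lengths")
        if not seen:
            raise ValueError(f"gene {gene}: empty alignment")
        per_gene[gene] = seen

    partitions: dict[str, tuple[int, int]] = {}
    chunks: dict[str, list[str]] = {t: [] for t in taxa}
    col = 0
    for gene, aln in per_gene.items():
        width = len(next(iter(aln.values())))
        partitions[gene] = (col, col + width)
        col += width
        for t in taxa:
            chunks[t].append(aln.get(t, "-" * width))
    return Supermatrix(taxa=taxa,
                       sequences=["".join(chunks[t]) for t in taxa],
                       partitions=partitions)


def filter_conserved_blocks(matrix: Supermatrix,
                            min_block_len: int = 10,
                            max_gap_frac: float = 0.0,
                            min_conservation: float = 0.5) -> Supermatrix:
    """Keep maximal runs of clean, conserved columns.

    A column qualifies when its gap fraction is <= ``max_gap_frac`` and its
    majority residue (among non-gap characters) reaches frequency
    >= ``min_conservation``; qualifying runs shorter than
    ``min_block_len`` are discarded.  The partition map is re-indexed onto
    the surviving columns.
    """
    arr = matrix.as_array()
    n_taxa, n_cols = arr.shape
    gaps = arr == GAP
    gap_frac = gaps.mean(axis=0)
    ok = gap_frac <= max_gap_frac
    non_gap = (~gaps).sum(axis=0)
    conservation = np.zeros(n_cols)
    for col in range(n_cols):
        if non_gap[col] == 0:
            continue
        residues = arr[~gaps[:, col], col]
        _, counts = np.unique(residues, return_counts=True)
        conservation[col] = counts.max() / non_gap[col]
    ok &= conservation >= min_conservation

    keep = np.zeros(n_cols, dtype=bool)
    i = 0
    while i < n_cols:
        if not ok[i]:
            i += 1
            continue
        j = i
        while j < n_cols and ok[j]:
            j += 1
        if j - i >= min_block_len:
            keep[i:j] = True
        i = j
    if not keep.any():
        raise ValueError(
            f"no columns retained ({n_cols} screened, "
            f"{int(ok.sum())} qualified but no block reached "
            f"{min_block_len} columns)")

    new_parts: dict[str, tuple[int, int]] = {}
    cum = np.concatenate([[0], np.cumsum(keep)])
    for gene, (a, b) in matrix.partitions.items():
        new_parts[gene] = (int(cum[a]), int(cum[b]))
    kept = arr[:, keep]
    return Supermatrix(
        taxa=list(matrix.taxa),
        sequences=[row.tobytes().decode() for row in kept],
        partitions=new_parts)


# ---------------------------------------------------------------------------
# distances and neighbor-joining

def p_distance_matrix(matrix: Supermatrix) -> DistanceMatrix:
    """Uncorrected pairwise distances with pairwise complete deletion."""
    arr = matrix.as_array()
    n = len(matrix.taxa)
    if n < 3:
        raise ValueError("need at least 3 taxa")
    gaps = arr == GAP
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            valid = ~(gaps[i] | gaps[j])
            m = int(valid.sum())
            if m == 0:
                raise ValueError(
                    f"{matrix.taxa[i]} and {matrix.taxa[j]} share no "
                    "gap-free columns")
            d[i, j] = d[j, i] = np.mean(arr[i, valid] != arr[j, valid])
    return DistanceMatrix(d, ids=matrix.taxa)


def nj_tree(distances: DistanceMatrix) -> TreeNode:
    """Neighbor-joining by the canonical Q criterion.

    Deterministic: the pair minimising Q is chosen, ties broken by the
    lowest (row, column) index in the current working matrix (node order
    follows input taxon order, joined nodes appended at the end).
    Negative branch-length estimates are clamped to zero.  The returned
    tree is unrooted with a trifurcating root.
    """
    ids = list(distances.ids)
    if len(ids) < 3:
        raise ValueError("need at least 3 taxa")
    d = np.array(distances.data, dtype=float)
    nodes: list[TreeNode] = [TreeNode(name=t) for t in ids]

    while len(nodes) > 3:
        m = len(nodes)
        r = d.sum(axis=1)
        q = (m - 2) * d - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        # row-major argmin -> lowest (i, j) on ties
        i, j = divmod(int(np.argmin(q)), m)
        if i > j:
            i, j = j, i
        li = 0.5 * d[i, j] + (r[i] - r[j]) / (2.0 * (m - 2))
        lj = d[i, j] - li
        a, b = nodes[i], nodes[j]
        a.length = max(li, 0.0)
        b.length = max(lj, 0.0)
        parent = TreeNode(children=[a, b])
        dk = 0.5 * (d[i, :] + d[j, :] - d[i, j])
        keep = [k for k in range(m) if k not in (i, j)]
        new_d = np.zeros((m - 1, m - 1))
        new_d[:-1, :-1] = d[np.ix_(keep, keep)]
        new_d[-1, :-1] = new_d[:-1, -1] = dk[keep]
        d = new_d
        nodes = [nodes[k] for k in keep] + [parent]

    # final three-way join
    (d01, d02, d12) = (d[0, 1], d[0, 2], d[1, 2])
    lengths = (0.5 * (d01 + d02 - d12),
               0.5 * (d01 + d12 - d02),
               0.5 * (d02 + d12 - d01))
    for node, bl in zip(nodes, lengths):
        node.length = max(bl, 0.0)
    return TreeNode(children=list(nodes))


def bipartitions(tree: TreeNode) -> set[frozenset]:
    """Non-trivial splits of an (unrooted) tree.

    Each split is the frozenset {side, complement} of two frozensets of
    tip names, so it is invariant to which side a rooted traversal saw.
    """
    all_tips = frozenset(t.name for t in tree.tips())
    splits: set[frozenset] = set()
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        comp = all_tips - side
        if len(side) >= 2 and len(comp) >= 2:
            splits.add(frozenset((side, comp)))
    return splits


def bootstrap_support(matrix: Supermatrix, replicates: int = 100,
                      seed: Optional[int] = None) -> TreeNode:
    """NJ point-estimate tree with column-resampling bootstrap supports.

    Each replicate resamples alignment columns with replacement, rebuilds
    the p-distance NJ tree, and every internal edge of the point-estimate
    tree is scored by the percentage of replicates containing its
    bipartition.  Supports are stored on internal nodes as ``.support``
    (a float in [0, 100]) and mirrored into ``.name`` for Newick output.
    """
    if replicates < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)
    point = nj_tree(p_distance_matrix(matrix))
    arr = matrix.as_array()
    n_cols = arr.shape[1]
    counts: dict[frozenset, int] = {bp: 0 for bp in bipartitions(point)}
    for _ in range(replicates):
        cols = rng.integers(0, n_cols, size=n_cols)
        res = Supermatrix(
            taxa=list(matrix.taxa),
            sequences=[row.tobytes().decode() for row in arr[:, cols]])
        rep_tree = nj_tree(p_distance_matrix(res))
        for bp in bipartitions(rep_tree):
            if bp in counts:
                counts[bp] += 1
    all_tips = frozenset(matrix.taxa)
    for node in point.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        key = frozenset((side, all_tips - side))
        if key in counts:
            pct = 100.0 * counts[key] / replicates
            node.bootstrap = pct
            node.name = f"{pct:g}"
    return point


def is_sister_pair(tree: TreeNode, taxon_a: str, taxon_b: str,
                   outgroup: Optional[str] = None,
                   ) -> tuple[bool, Optional[float]]:
    """Do two taxa form a cherry, and with what support?

    True iff some internal edge separates exactly {taxon_a, taxon_b} from
    all other taxa — equivalently, the pair is sister after rooting on any
    outside taxon (``outgroup`` is validated but does not change the
    answer).  Returns (answer, bootstrap support of the defining edge, or
    None if the tree carries no supports or the pair is not sister).
    """
    tips = {t.name for t in tree.tips()}
    for taxon in filter(None, (taxon_a, taxon_b, outgroup)):
        if taxon not in tips:
            raise KeyError(f"taxon {taxon!r} not in tree")
    if outgroup in (taxon_a, taxon_b):
        raise ValueError("outgroup cannot be part of the tested pair")
    target = frozenset((taxon_a, taxon_b))
    for node in tree.non_tips(include_self=False):
        side = frozenset(t.name for t in node.tips())
        if side == target or (tips - side) == target:
            support = getattr(node, "bootstrap", None)
            return True, support
    return False, None
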