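"""Gene-order rearrangement analysis on signed circular permutations.

A mitogenome's gene order is modelled as a circular sequence of signed
elements (+ = majority/J strand, - = minority/N strand; the control region
is unsigned).  Orders are compared through their sets of signed
adjacencies: the adjacency (a, b) is identified with its reading on the
opposite strand (-b, -a), and the breakpoint distance between two orders
is the number of adjacencies of one that are absent from the other.  A
greedy classifier explains the difference as inversions, adjacent swaps
and single-gene translocations where possible; anything it cannot
reconstruct is reported as unclassified rather than forced into a
duplication/loss scenario.

The built-in reference is the pancrustacean ground pattern, the inferred
ancestral arthropod arrangement against which crustacean rearrangements
are conventionally described.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

from .annotation_io import MitogenomeRecord
from .vocab import SHORT_LABEL

Element = tuple[str, int]  # (gene name, sign: +1 / -1 / 0 for unsigned)


@dataclass(frozen=True)
class GeneOrder:
    """A signed circular gene order; equality is rotation-invariant."""

    elements: tuple[Element, ...]
    circular: bool = True

    def __post_init__(self):
        names = [n for n, _ in self.elements]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise ValueError(f"duplicate gene name(s): {', '.join(dupes)}")

    @property
    def names(self) -> frozenset[str]:
        return frozenset(n for n, _ in self.elements)

    def sign_of(self, name: str) -> int:
        for n, s in self.elements:
            if n == name:
                return s
        raise KeyError(name)

    def rotated(self, k: int) -> "GeneOrder":
        e = self.elements
        k %= len(e)
        return GeneOrder(e[k:] + e[:k], self.circular)

    def _canonical(self) -> tuple[Element, ...]:
        if not self.circular or not self.elements:
            return self.elements
        n = len(self.elements)
        return min((self.elements[k:] + self.elements[:k]) for k in range(n))

    def __eq__(self, other):
        if not isinstance(other, GeneOrder):
            return NotImplemented
        return (self.circular == other.circular
                and self._canonical() == other._canonical())

    def __hash__(self):
        return hash((self.circular, self._canonical()))

    def reversed_genome(self) -> "GeneOrder":
        """The order read from the opposite strand (list reversed, signs flipped)."""
        return GeneOrder(tuple((n, -s) for n, s in reversed(self.elements)),
                         self.circular)


def _canon_adj(a: Element, b: Element) -> tuple[Element, Element]:
    fwd = (a, b)
    rev = ((b[0], -b[1]), (a[0], -a[1]))
    return min(fwd, rev)


def adjacency_set(order: GeneOrder) -> frozenset[tuple[Element, Element]]:
    """Canonical signed adjacencies of a circular order."""
    e = order.elements
    pairs = zip(e, e[1:] + e[:1]) if order.circular else zip(e, e[1:])
    return frozenset(_canon_adj(a, b) for a, b in pairs)


def _check_same_genes(a: GeneOrder, b: GeneOrder) -> None:
    if a.names != b.names:
        diff = sorted(a.names ^ b.names)
        raise ValueError(f"orders cover different gene sets: {', '.join(diff)}")


def breakpoint_count(a: GeneOrder, b: GeneOrder) -> int:
    """Signed circular breakpoint distance (symmetric; 0 iff orders equal)."""
    _check_same_genes(a, b)
    return len(adjacency_set(a) - adjacency_set(b))


def encode_gene_order(record: MitogenomeRecord) -> GeneOrder:
    """Gene order of a record by ascending start coordinate."""
    feats = sorted(record.features, key=lambda f: f.start)
    sign = {"J": +1, "N": -1, None: 0}
    return GeneOrder(tuple((f.name, sign[f.orientation]) for f in feats),
                     circular=record.circular)


_GROUND = (
    ("cox1", +1), ("trnL2", +1), ("cox2", +1), ("trnK", +1), ("trnD", +1),
    ("atp8", +1), ("atp6", +1), ("cox3", +1), ("trnG", +1), ("nad3", +1),
    ("trnA", +1), ("trnR", +1), ("trnN", +1), ("trnS1", +1), ("trnE", +1),
    ("trnF", -1), ("nad5", -1), ("trnH", -1), ("nad4", -1), ("nad4L", -1),
    ("trnT", +1), ("trnP", -1), ("nad6", +1), ("cob", +1), ("trnS2", +1),
    ("nad1", -1), ("trnL1", -1), ("rrnL", -1), ("trnV", -1), ("rrnS", -1),
    ("CR", 0), ("trnI", +1), ("trnQ", -1), ("trnM", +1), ("nad2", +1),
    ("trnW", +1), ("trnC", -1), ("trnY", -1),
)


def ground_pattern() -> GeneOrder:
    """The pancrustacean ground pattern (ancestral arthropod-like order)."""
    return GeneOrder(_GROUND, circular=True)


# ---------------------------------------------------------------------------
# rearrangement events

@dataclass(frozen=True)
class Event:
    kind: str           # "adjacent-swap" | "translocation" | "inversion" | "unclassified"
    genes: tuple[str, ...]
    detail: str = ""


def apply_event(order: GeneOrder, event: Event) -> GeneOrder:
    """Apply a single rearrangement event to an order."""
    elems = list(order.elements)
    idx = {n: i for i, (n, _) in enumerate(elems)}
    if event.kind == "identity":
        return order
    if event.kind == "inversion":
        (g,) = event.genes
        i = idx[g]
        elems[i] = (g, -elems[i][1])
        return GeneOrder(tuple(elems), order.circular)
    if event.kind == "adjacent-swap":
        g1, g2 = event.genes
        i, j = idx[g1], idx[g2]
        n = len(elems)
        if (j - i) % n == 1 or (i - j) % n == 1:
            elems[i], elems[j] = elems[j], elems[i]
            return GeneOrder(tuple(elems), order.circular)
        raise ValueError(f"{g1} and {g2} are not adjacent")
    if event.kind == "translocation":
        g, left, right = event.genes
        i = idx[g]
        moved = elems.pop(i)
        idx2 = {n: k for k, (n, _) in enumerate(elems)}
        li, ri = idx2[left], idx2[right]
        n = len(elems)
        if (ri - li) % n != 1:
            raise ValueError(
                f"translocation target {left}/{right} not adjacent")
        elems.insert(li + 1, moved)
        return GeneOrder(tuple(elems), order.circular)
    raise ValueError(f"cannot apply event of kind {event.kind!r}")


@dataclass
class RearrangementReport:
    breakpoints: int
    displaced: set[str]
    events: list[Event] = field(default_factory=list)

    @property
    def identical(self) -> bool:
        return self.breakpoints == 0


def _neighbour_adjacencies(order: GeneOrder, gene: str):
    return frozenset(adj for adj in adjacency_set(order)
                     if gene in (adj[0][0], adj[1][0]))


def _find_run(order: GeneOrder, run: Sequence[Element]) -> bool:
    e = order.elements
    n = len(e)
    doubled = e + e
    for i in range(n):
        if list(doubled[i:i + len(run)]) == list(run):
            return True
    return False


def diff_report(observed: GeneOrder, reference: GeneOrder) -> RearrangementReport:
    """Explain how ``observed`` differs from ``reference``.

    Displaced genes are those with at least one changed signed adjacency.
    Events are inferred greedily — sign-only inversions, then adjacent
    swaps, then single-gene translocations — and validated by replaying
    them on the reference: if the replay does not reproduce the observed
    order, a final ``unclassified`` event lists the genes still out of
    place.
    """
    _check_same_genes(observed, reference)
    bp = breakpoint_count(observed, reference)
    displaced = {
        g for g in observed.names
        if _neighbour_adjacencies(observed, g)
        != _neighbour_adjacencies(reference, g)
    }
    events: list[Event] = []
    work = reference

    # inversions: sign flip in an otherwise conserved neighbourhood
    for g in sorted(displaced):
        if observed.sign_of(g) == work.sign_of(g):
            continue
        flipped = apply_event(work, Event("inversion", (g,)))
        if (_neighbour_adjacencies(flipped, g)
                == _neighbour_adjacencies(observed, g)):
            work = flipped
            events.append(Event("inversion", (g,), f"strand switch of {g}"))

    # adjacent swaps: p x y q  ->  p y x q with per-gene signs kept
    changed = True
    while changed:
        changed = False
        e = work.elements
        n = len(e)
        for i in range(n):
            p, x, y, q = (e[(i - 1) % n], e[i], e[(i + 1) % n], e[(i + 2) % n])
            if x == y or len({p[0], x[0], y[0], q[0]}) < 4:
                continue
            if _find_run(observed, [p, y, x, q]) and not _find_run(
                    observed, [p, x, y, q]):
                work = apply_event(work, Event("adjacent-swap", (x[0], y[0])))
                events.append(Event(
                    "adjacent-swap", (x[0], y[0]),
                    f"{x[0]}-{y[0]} becomes {y[0]}-{x[0]}"))
                changed = True
                break

    # translocations: move g between its observed neighbours
    changed = True
    rounds = 0
    while changed and work != observed and rounds <= len(observed.elements):
        changed = False
        rounds += 1
        for g in sorted(displaced):
            if (_neighbour_adjacencies(work, g)
                    == _neighbour_adjacencies(observed, g)):
                continue
            oe = observed.elements
            n = len(oe)
            i = next(k for k, (name, _) in enumerate(oe) if name == g)
            left, right = oe[(i - 1) % n], oe[(i + 1) % n]
            if observed.sign_of(g) != work.sign_of(g):
                continue
            try:
                moved = apply_event(
                    work, Event("translocation", (g, left[0], right[0])))
            except (ValueError, KeyError):
                continue
            events.append(Event(
                "translocation", (g, left[0], right[0]),
                f"{g} moved between {left[0]} and {right[0]}"))
            work = moved
            changed = True
            break

    if work != observed:
        leftover = {
            g for g in observed.names
            if _neighbour_adjacencies(work, g)
            != _neighbour_adjacencies(observed, g)
        }
        events.append(Event("unclassified", tuple(sorted(leftover)),
                            "greedy replay did not reach the observed order"))
    return RearrangementReport(breakpoints=bp, displaced=displaced,
                               events=events)


# ---------------------------------------------------------------------------
# rendering

def render_linear_map(order: GeneOrder) -> str:
    """Two-line text map: gene labels, with ``<`` marking N-strand genes.

    tRNAs are shown by their single-letter code (S1/S2/L1/L2 kept distinct);
    the marker line underlines minority-strand genes so the label line
    remains a clean space-separated gene list.
    """
    labels = [SHORT_LABEL[n] for n, _ in order.elements]
    marks = ["<" * len(lbl) if s < 0 else " " * len(lbl)
             for (_, s), lbl in zip(order.elements, labels)]
    return " ".join(labels) + "\n" + " ".join(marks).rstrip()
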