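"""Layered secondary structures with pseudoknots and ring topology.

An xrRNA secondary structure is represented as three pair layers: a
nested base layer (layer 0, the helices of the three-way junction) and
two pseudoknot layers (PK1, PK2) whose pairs may cross layer 0 and each
other.  The defining feature of exoribonuclease resistance — the
ring-like fold that encloses the 5' end — is operationalized here as a
purely topological test on those pair sets (:func:`check_ring_closure`):
PK2 must close the ring by crossing the P1 helix set while a threaded
5' segment remains upstream of the first paired position.  PK1 is a
stabilizer, not a requirement, mirroring the observed hierarchy where
PK2 deletion abolishes resistance but PK1 deletion only weakens it.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "StructureError",
    "TargetStructure",
    "TopologyReport",
    "parse_extended_dotbracket",
    "pairs_to_dotbracket",
    "crossing",
    "instantiate_target",
    "check_ring_closure",
    "MIN_HAIRPIN",
]

#: minimum number of unpaired nucleotides enclosed by any pair
MIN_HAIRPIN = 3

_OPEN = {"(": 0, "[": 1, "{": 2}
_CLOSE = {")": 0, "]": 1, "}": 2}
_BRACKETS = [("(", ")"), ("[", "]"), ("{", "}")]


class StructureError(ValueError):
    pass


def crossing(p: tuple[int, int], q: tuple[int, int]) -> bool:
    """True iff pairs ``p`` and ``q`` cross (pseudoknot relation).

    Pairs are (i, j) with i < j; crossing means exactly one endpoint of
    ``q`` lies strictly inside the interval (p.i, p.j).
    """
    (pi, pj), (qi, qj) = p, q
    return (pi < qi < pj) != (pi < qj < pj)


def _validate_layer0_nested(pairs: set[tuple[int, int]]) -> None:
    ordered = sorted(pairs)
    for a in range(len(ordered)):
        for b in range(a + 1, len(ordered)):
            if crossing(ordered[a], ordered[b]):
                raise StructureError(
                    f"layer-0 pairs cross: {ordered[a]} / {ordered[b]}"
                )


@dataclass
class TargetStructure:
    """Concrete layered structure; positions are 1-based, i < j per pair."""

    length: int
    base_pairs: frozenset = frozenset()
    pk1_pairs: frozenset = frozenset()
    pk2_pairs: frozenset = frozenset()
    element_of: dict = field(default_factory=dict)
    #: base-triple annotations: (i, j, k, name); not part of any pair layer
    triples: tuple = ()

    def __post_init__(self) -> None:
        self.base_pairs = frozenset(tuple(p) for p in self.base_pairs)
        self.pk1_pairs = frozenset(tuple(p) for p in self.pk1_pairs)
        self.pk2_pairs = frozenset(tuple(p) for p in self.pk2_pairs)
        seen: set[int] = set()
        for layer in (self.base_pairs, self.pk1_pairs, self.pk2_pairs):
            for i, j in layer:
                if not (1 <= i < j <= self.length):
                    raise StructureError(f"pair ({i}, {j}) out of bounds")
                if j - i <= MIN_HAIRPIN:
                    raise StructureError(
                        f"pair ({i}, {j}) violates minimum hairpin size"
                    )
                if i in seen or j in seen:
                    raise StructureError(
                        f"position in more than one pair: ({i}, {j})"
                    )
                seen.update((i, j))
        _validate_layer0_nested(set(self.base_pairs))

    def all_pairs(self) -> frozenset:
        return self.base_pairs | self.pk1_pairs | self.pk2_pairs

    def paired_positions(self) -> set[int]:
        out: set[int] = set()
        for i, j in self.all_pairs():
            out.update((i, j))
        return out

    def elements(self) -> dict[str, list[int]]:
        """Element name -> sorted positions (concrete coordinates)."""
        out: dict[str, list[int]] = {}
        for pos in sorted(self.element_of):
            out.setdefault(self.element_of[pos], []).append(pos)
        return out

    def to_dotbracket(self) -> str:
        chars = ["."] * self.length
        for layer, (o, c) in zip(
            (self.base_pairs, self.pk1_pairs, self.pk2_pairs), _BRACKETS
        ):
            for i, j in layer:
                chars[i - 1] = o
                chars[j - 1] = c
        return "".join(chars)


def pairs_to_dotbracket(n: int, pairs) -> str:
    """Plain (layer-0 only) dot-bracket from 0-based pair tuples."""
    chars = ["."] * n
    for i, j in pairs:
        chars[i] = "("
        chars[j] = ")"
    return "".join(chars)


def parse_extended_dotbracket(s: str) -> TargetStructure:
    """Parse extended dot-bracket: ``()`` layer 0, ``[]`` PK1, ``{}`` PK2."""
    layers: list[set[tuple[int, int]]] = [set(), set(), set()]
    stacks: list[list[int]] = [[], [], []]
    for pos, ch in enumerate(s, start=1):
        if ch == ".":
            continue
        elif ch in _OPEN:
            stacks[_OPEN[ch]].append(pos)
        elif ch in _CLOSE:
            layer = _CLOSE[ch]
            if not stacks[layer]:
                raise StructureError(f"unbalanced {ch!r} at position {pos}")
            i = stacks[layer].pop()
            layers[layer].add((i, pos))
        else:
            raise StructureError(f"invalid character {ch!r} at position {pos}")
    for layer, stack in enumerate(stacks):
        if stack:
            raise StructureError(
                f"unbalanced {_BRACKETS[layer][0]!r} at position {stack[-1]}"
            )
    return TargetStructure(
        length=len(s),
        base_pairs=frozenset(layers[0]),
        pk1_pairs=frozenset(layers[1]),
        pk2_pairs=frozenset(layers[2]),
    )


# ---------------------------------------------------------------------------
# Instantiation of a symbolic model at concrete element lengths
# ---------------------------------------------------------------------------

def instantiate_target(model, lengths: dict) -> TargetStructure:
    """Concrete structure of ``model`` at the given element lengths.

    ``lengths`` maps element names to realized lengths (bp for paired
    elements; specifying either strand of a pair suffices).  Helical
    elements contribute paired positions with their partners, loops and
    linkers unpaired positions, in the model's 5'->3' layout.  Length
    ranges and correlation windows are enforced.
    """
    from .model_io import ModelError  # local import to avoid cycle

    lens = dict(lengths)
    # propagate paired-element lengths to partners; validate equality
    for el in model.elements:
        if el.partner:
            a, b = el.name, el.partner
            if a in lens and b in lens and lens[a] != lens[b]:
                raise ModelError(
                    f"paired elements {a}/{b} given different lengths"
                )
            if a in lens:
                lens.setdefault(b, lens[a])
            elif b in lens:
                lens.setdefault(a, lens[b])
    for el in model.elements:
        if el.name not in lens:
            if el.length_min == el.length_max:
                lens[el.name] = el.length_min
            else:
                raise ModelError(f"no length given for element {el.name!r}")
        if not (el.length_min <= lens[el.name] <= el.length_max):
            raise ModelError(
                f"length {lens[el.name]} out of range "
                f"[{el.length_min}, {el.length_max}] for element {el.name!r}"
            )
    for corr in model.correlations:
        la, lb = lens[corr.element_a], lens[corr.element_b]
        slope, intercept = corr.line(model)
        if abs(lb - (slope * la + intercept)) > corr.window + 1e-9:
            raise ModelError(
                f"correlation window violated for "
                f"({corr.element_a}, {corr.element_b}): lengths ({la}, {lb})"
            )

    # lay out positions 5'->3'
    start: dict[str, int] = {}
    element_of: dict[int, str] = {}
    pos = 1
    for el in model.elements:
        L = lens[el.name]
        start[el.name] = pos
        for p in range(pos, pos + L):
            element_of[p] = el.name
        pos += L
    n = pos - 1

    layer_sets: dict[int, set[tuple[int, int]]] = {0: set(), 1: set(), 2: set()}
    seen_pairs: set[frozenset] = set()
    for el in model.elements:
        if not el.partner:
            continue
        key = frozenset((el.name, el.partner))
        if key in seen_pairs:
            continue
        seen_pairs.add(key)
        mate = model.element(el.partner)
        five, three = (el, mate)  # model validation guarantees order
        L = lens[el.name]
        for k in range(L):
            i = start[five.name] + k
            j = start[three.name] + (L - 1 - k)
            layer = five.pk_layer if five.kind == "pseudoknot" else 0
            layer_sets[layer].add((i, j))

    triples = []
    for t in model.base_triples:
        coords = []
        for ename, idx in ((t.elem_i, t.idx_i), (t.elem_j, t.idx_j),
                           (t.elem_k, t.idx_k)):
            el = model.element(ename)
            off = _realized_offset(el, idx, lens[ename])
            if off is None:
                coords = None
                break
            coords.append(start[ename] + off)
        if coords is not None:
            triples.append((*coords, t.name))

    return TargetStructure(
        length=n,
        base_pairs=frozenset(layer_sets[0]),
        pk1_pairs=frozenset(layer_sets[1]),
        pk2_pairs=frozenset(layer_sets[2]),
        element_of=element_of,
        triples=tuple(triples),
    )


def _realized_offset(el, mask_idx: int, realized_len: int) -> int | None:
    """Concrete offset of mask index ``mask_idx`` at ``realized_len``.

    Canonical gap placement: a 5' strand (or any unpaired element) keeps
    mask indices [0, len); a 3' paired strand keeps the last ``len``
    mask indices.  Returns None if the position is gapped out.
    """
    if el.is_three_prime_strand:
        lo = el.length_max - realized_len
        if mask_idx < lo:
            return None
        return mask_idx - lo
    return mask_idx if mask_idx < realized_len else None


# ---------------------------------------------------------------------------
# Ring-closure topology
# ---------------------------------------------------------------------------

@dataclass
class TopologyReport:
    """Diagnostic verdict on the protective ring topology."""

    ring_closed: bool
    pk1_pair_count: int
    pk2_pair_count: int
    crossing_found: bool
    threaded_5prime_len: int
    pk1_stabilization: bool
    notes: list[str] = field(default_factory=list)


def check_ring_closure(
    ts: TargetStructure, min_thread: int = 4, p1_elements: set[str] | None = None
) -> TopologyReport:
    """Topological test for the XRN1-blocking ring.

    The ring is considered closed iff (a) at least one PK2 pair exists,
    (b) some PK2 pair crosses a layer-0 pair of the P1-containing helix
    set, and (c) the 5'-most paired position (any layer) leaves an
    upstream threaded segment of >= ``min_thread`` nucleotides — the
    stretch XRN1 needs to engage.  PK1 presence is reported as a
    stabilization flag but is not required for closure.

    This is a 2D operationalization of a 3D property (threading is
    approximated by the crossing rule); the notes flag it as such.
    """
    notes = ["2D crossing-rule approximation of ring threading"]
    pk2 = sorted(ts.pk2_pairs)
    pk1 = sorted(ts.pk1_pairs)

    if p1_elements is None:
        names = {e for e in set(ts.element_of.values())}
        p1_elements = {e for e in names if e.upper().startswith("P1")} or None

    def in_p1_set(pair: tuple[int, int]) -> bool:
        if p1_elements is None:
            return True  # no element annotation: any layer-0 pair counts
        i, j = pair
        return (
            ts.element_of.get(i) in p1_elements
            or ts.element_of.get(j) in p1_elements
        )

    cross = any(
        crossing(p, q)
        for p in pk2
        for q in sorted(ts.base_pairs)
        if in_p1_set(q)
    )

    paired = ts.paired_positions()
    first_paired = min(paired) if paired else ts.length + 1
    threaded = first_paired - 1

    closed = bool(pk2) and cross and threaded >= min_thread
    if not pk2:
        notes.append("PK2 absent: ring cannot close")
    elif not cross:
        notes.append("no PK2 pair crosses the P1 helix set")
    if threaded < min_thread:
        notes.append(
            f"threaded 5' segment ({threaded} nt) shorter than "
            f"min_thread ({min_thread} nt)"
        )
    stab = bool(pk1)
    if closed and not stab:
        notes.append("PK1 absent: ring closed but stabilization reduced")
    return TopologyReport(
        ring_closed=closed,
        pk1_pair_count=len(pk1),
        pk2_pair_count=len(pk2),
        crossing_found=cross,
        threaded_5prime_len=threaded,
        pk1_stabilization=stab,
        notes=notes,
    )
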