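"""Symbolic variable-length models of an xrRNA family.

A family of exoribonuclease-resistant RNAs is described by an ordered
5'->3' list of structural elements (helices, loops, junction linkers,
pseudoknots), each annotated with a length range, a per-position
conservation mask, and — for paired elements — a partner strand.
Length correlations between elements (e.g. the strong negative
correlation between stem P3 and its capping loop L3 in mosquito-borne
flavivirus xrRNAs) are carried as explicit constraints.  Such a model
can be written by hand (YAML), shipped as a package default, or derived
from an annotated multiple alignment: a nucleotide is fixed at a column
iff its identity among non-gap characters strictly exceeds the
conservation threshold (default 90%).
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import yaml

SCHEMA = "xrdesign-model/1"
NUCS = "ACGU"
#: letter pairs satisfying complementarity (canonical + wobble)
COMPLEMENTARY = frozenset(
    {("G", "C"), ("C", "G"), ("A", "U"), ("U", "A"), ("G", "U"), ("U", "G")}
)
ELEMENT_KINDS = ("helix", "loop", "junction", "pseudoknot", "linker")
PAIRED_KINDS = ("helix", "pseudoknot")


class ModelError(ValueError):
    pass


def _norm_mask_entry(entry: str) -> str:
    entry = (entry or "").upper().replace("T", "U")
    if entry in ("", "N", "."):
        return NUCS
    letters = sorted(set(entry))
    if not set(letters) <= set(NUCS):
        raise ModelError(f"invalid mask entry {entry!r}")
    return "".join(letters)


@dataclass
class ElementSpec:
    """One structural element (a single strand, for paired kinds)."""

    name: str
    kind: str
    length_min: int
    length_max: int
    partner: str = ""
    #: per-mask-index allowed nucleotides; "ACGU" = unconstrained
    conserved_mask: list = field(default_factory=list)
    #: favor (not force) G-C at this element's pairs during sampling
    gc_favored: bool = False
    #: pseudoknot layer (1 or 2); 0 for non-pseudoknots
    pk_layer: int = 0
    #: set by SymbolicModel from element order; 3' strand of a duplex
    is_three_prime_strand: bool = False

    def __post_init__(self) -> None:
        if self.kind not in ELEMENT_KINDS:
            raise ModelError(f"element {self.name!r}: unknown kind {self.kind!r}")
        if self.length_min < 0 or self.length_min > self.length_max:
            raise ModelError(
                f"element {self.name!r}: inverted length range "
                f"({self.length_min}, {self.length_max})"
            )
        if bool(self.partner) != (self.kind in PAIRED_KINDS):
            raise ModelError(
                f"element {self.name!r}: partner must be set iff kind is "
                f"helix/pseudoknot"
            )
        if not self.conserved_mask:
            self.conserved_mask = [NUCS] * self.length_max
        self.conserved_mask = [_norm_mask_entry(e) for e in self.conserved_mask]
        if len(self.conserved_mask) != self.length_max:
            raise ModelError(
                f"element {self.name!r}: mask length "
                f"{len(self.conserved_mask)} != length_max {self.length_max}"
            )
        if self.kind == "pseudoknot" and self.pk_layer not in (1, 2):
            raise ModelError(
                f"element {self.name!r}: pseudoknot needs pk_layer 1 or 2"
            )

    @property
    def is_paired(self) -> bool:
        return self.kind in PAIRED_KINDS

    def allowed(self, mask_idx: int) -> str:
        return self.conserved_mask[mask_idx]


@dataclass
class Correlation:
    """Length-correlation constraint between two elements.

    Enforced at sampling/instantiation time as a joint window: the
    realized (len_a, len_b) must satisfy
    ``|len_b - (slope * len_a + intercept)| <= window``.  When the line
    is not given explicitly (e.g. hand-written models), it is derived
    from ``rho`` and the elements' length ranges assuming uniform
    marginals.
    """

    element_a: str
    element_b: str
    rho: float
    window: float = 1.0
    slope: float | None = None
    intercept: float | None = None

    def __post_init__(self) -> None:
        if not -1.0 <= self.rho <= 1.0:
            raise ModelError("correlation rho must be in [-1, 1]")
        if self.window < 0:
            raise ModelError("correlation window must be >= 0")

    def line(self, model: "SymbolicModel") -> tuple[float, float]:
        if self.slope is not None and self.intercept is not None:
            return self.slope, self.intercept
        ea = model.element(self.element_a)
        eb = model.element(self.element_b)

        def stats(el: ElementSpec) -> tuple[float, float]:
            k = el.length_max - el.length_min + 1
            sd = math.sqrt((k * k - 1) / 12.0)
            return (el.length_min + el.length_max) / 2.0, sd

        mid_a, sd_a = stats(ea)
        mid_b, sd_b = stats(eb)
        if sd_a == 0 or sd_b == 0:
            raise ModelError(
                f"correlation ({self.element_a}, {self.element_b}) on "
                f"fixed-length element"
            )
        slope = self.rho * sd_b / sd_a
        return slope, mid_b - slope * mid_a


@dataclass
class BaseTriple:
    """Tertiary base-triple annotation: a nucleotide contacting a pair."""

    elem_i: str
    idx_i: int
    elem_j: str
    idx_j: int
    elem_k: str
    idx_k: int
    name: str = ""


@dataclass
class SymbolicModel:
    """Ordered, variable-length symbolic description of an RNA family."""

    elements: list
    correlations: list = field(default_factory=list)
    mean_length: float = 0.0
    total_length_range: tuple = (0, 0)
    conservation_threshold: float = 0.9
    base_triples: list = field(default_factory=list)
    name: str = "model"

    def __post_init__(self) -> None:
        self.total_length_range = tuple(self.total_length_range)
        names = [e.name for e in self.elements]
        if len(set(names)) != len(names):
            raise ModelError("duplicate element names")
        index = {e.name: i for i, e in enumerate(self.elements)}
        for el in self.elements:
            if not el.partner:
                continue
            if el.partner not in index:
                raise ModelError(
                    f"element {el.name!r}: asymmetric partner "
                    f"({el.partner!r} not defined)"
                )
            mate = self.elements[index[el.partner]]
            if mate.partner != el.name:
                raise ModelError(
                    f"element {el.name!r}: asymmetric partner declaration"
                )
            if mate.kind != el.kind:
                raise ModelError(
                    f"partners {el.name!r}/{mate.name!r} differ in kind"
                )
            if (mate.length_min, mate.length_max) != (
                el.length_min,
                el.length_max,
            ):
                raise ModelError(
                    f"partners {el.name!r}/{mate.name!r} differ in length range"
                )
            if el.kind == "pseudoknot" and mate.pk_layer != el.pk_layer:
                raise ModelError(
                    f"partners {el.name!r}/{mate.name!r} differ in pk_layer"
                )
            el.is_three_prime_strand = index[el.name] > index[el.partner]
        total_min = sum(e.length_min for e in self.elements)
        total_max = sum(e.length_max for e in self.elements)
        if self.total_length_range == (0, 0):
            self.total_length_range = (total_min, total_max)
        lo, hi = self.total_length_range
        if not (total_min <= lo <= hi <= total_max):
            raise ModelError(
                f"total_length_range {self.total_length_range} inconsistent "
                f"with element ranges [{total_min}, {total_max}]"
            )
        if self.mean_length == 0.0:
            self.mean_length = (lo + hi) / 2.0
        if not 0 < self.conservation_threshold <= 1:
            raise ModelError("conservation_threshold must be in (0, 1]")
        for c in self.correlations:
            for nm in (c.element_a, c.element_b):
                if nm not in index:
                    raise ModelError(f"correlation references unknown {nm!r}")
        self._index = index

    def element(self, name: str) -> ElementSpec:
        try:
            return self.elements[self._index[name]]
        except KeyError:
            raise ModelError(f"unknown element {name!r}") from None

    def length_groups(self) -> list:
        """(group_key, member_names, lo, hi); paired strands share a group."""
        groups, seen = [], set()
        for el in self.elements:
            if el.name in seen:
                continue
            members = [el.name]
            seen.add(el.name)
            if el.partner:
                members.append(el.partner)
                seen.add(el.partner)
            groups.append((el.name, tuple(members), el.length_min, el.length_max))
        return groups

    def group_of(self, name: str) -> str:
        el = self.element(name)
        if el.partner and el.is_three_prime_strand:
            return el.partner
        return el.name

    def paired_element_pairs(self) -> list:
        """(five_prime_strand, three_prime_strand) tuples, layout order."""
        out = []
        for el in self.elements:
            if el.is_paired and not el.is_three_prime_strand:
                out.append((el, self.element(el.partner)))
        return out


# ---------------------------------------------------------------------------
# YAML (de)serialization
# ---------------------------------------------------------------------------

def _mask_to_yaml(mask: list) -> list | str:
    if all(len(e) in (1, 4) for e in mask):
        return "".join(e if len(e) == 1 else "N" for e in mask)
    return list(mask)


def model_to_dict(model: SymbolicModel) -> dict:
    return {
        "schema": SCHEMA,
        "name": model.name,
        "conservation_threshold": model.conservation_threshold,
        "mean_length": model.mean_length,
        "total_length_range": list(model.total_length_range),
        "elements": [
            {
                "name": e.name,
                "kind": e.kind,
                "length": [e.length_min, e.length_max],
                **({"partner": e.partner} if e.partner else {}),
                **({"pk_layer": e.pk_layer} if e.pk_layer else {}),
                **({"gc_favored": True} if e.gc_favored else {}),
                "mask": _mask_to_yaml(e.conserved_mask),
            }
            for e in model.elements
        ],
        "correlations": [
            {
                "elements": [c.element_a, c.element_b],
                "rho": c.rho,
                "window": c.window,
                **(
                    {"slope": c.slope, "intercept": c.intercept}
                    if c.slope is not None
                    else {}
                ),
            }
            for c in model.correlations
        ],
        "base_triples": [
            [t.elem_i, t.idx_i, t.elem_j, t.idx_j, t.elem_k, t.idx_k, t.name]
            for t in model.base_triples
        ],
    }


def model_from_dict(d: dict) -> SymbolicModel:
    if d.get("schema") != SCHEMA:
        raise ModelError(
            f"unsupported model schema {d.get('schema')!r} (expected {SCHEMA!r})"
        )
    elements = []
    for ed in d.get("elements", []):
        try:
            lo, hi = ed["length"]
            mask = ed.get("mask", [])
            elements.append(
                ElementSpec(
                    name=ed["name"],
                    kind=ed["kind"],
                    length_min=int(lo),
                    length_max=int(hi),
                    partner=ed.get("partner", ""),
                    conserved_mask=list(mask),
                    gc_favored=bool(ed.get("gc_favored", False)),
                    pk_layer=int(ed.get("pk_layer", 0)),
                )
            )
        except KeyError as exc:
            raise ModelError(
                f"element {ed.get('name', '?')!r}: missing key {exc}"
            ) from None
    correlations = [
        Correlation(
            element_a=cd["elements"][0],
            element_b=cd["elements"][1],
            rho=float(cd["rho"]),
            window=float(cd.get("window", 1.0)),
            slope=cd.get("slope"),
            intercept=cd.get("intercept"),
        )
        for cd in d.get("correlations", [])
    ]
    triples = [BaseTriple(*t) for t in d.get("base_triples", [])]
    return SymbolicModel(
        elements=elements,
        correlations=correlations,
        mean_length=float(d.get("mean_length", 0.0)),
        total_length_range=tuple(d.get("total_length_range", (0, 0))),
        conservation_threshold=float(d.get("conservation_threshold", 0.9)),
        base_triples=triples,
        name=d.get("name", "model"),
    )


def load_model(path) -> SymbolicModel:
    """Load and validate a symbolic model from a YAML spec file."""
    with open(path) as fh:
        d = yaml.safe_load(fh)
    if not isinstance(d, dict):
        raise ModelError(f"{path}: not a mapping")
    return model_from_dict(d)


def save_model(model: SymbolicModel, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(model_to_dict(model), fh, sort_keys=False)


def load_builtin_model(name: str) -> SymbolicModel:
    """Load a model shipped with the package (``default_mbf``/``denovo_mbf``)."""
    from importlib.resources import files

    path = files("xrdesign").joinpath("data", f"{name}.yaml")
    return model_from_dict(yaml.safe_load(path.read_text()))


# ---------------------------------------------------------------------------
# Pearson correlation
# ---------------------------------------------------------------------------

def pearson(x, y) -> float:
    """Pearson product-moment correlation coefficient."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise ModelError("pearson: inputs must be equal-length 1-D")
    if x.size < 3:
        raise ModelError("pearson: need at least 3 observations")
    dx = x - x.mean()
    dy = y - y.mean()
    sx = float(np.sqrt((dx * dx).sum()))
    sy = float(np.sqrt((dy * dy).sum()))
    if sx == 0.0 or sy == 0.0:
        raise ModelError("pearson: zero variance, coefficient undefined")
    return float((dx * dy).sum() / (sx * sy))


# ---------------------------------------------------------------------------
# Model derivation from annotated alignments
# ---------------------------------------------------------------------------

@dataclass
class AlignmentSummary:
    n_sequences: int
    per_column_frequencies: "object"  # pandas DataFrame, columns A C G U gap
    element_lengths: "object"         # DataFrame: per-sequence element lengths
    correlation_matrix: "object"      # DataFrame: Pearson rho between lengths


def _alignment_rows(alignment) -> list[tuple[str, str]]:
    rows = []
    for i, rec in enumerate(alignment):
        if isinstance(rec, str):
            rows.append((f"seq{i}", rec.upper().replace("T", "U")))
        elif isinstance(rec, tuple):
            rows.append((rec[0], rec[1].upper().replace("T", "U")))
        else:  # Bio.SeqRecord
            rows.append((rec.id, str(rec.seq).upper().replace("T", "U")))
    if not rows:
        raise ModelError("empty alignment")
    width = len(rows[0][1])
    if any(len(s) != width for _, s in rows):
        raise ModelError("ragged alignment")
    return rows


def summarize_alignment(alignment, annotation) -> AlignmentSummary:
    """Column frequencies, element lengths, and their Pearson matrix.

    ``annotation`` is a list of ``(col_start, col_end, element)`` with
    1-based inclusive column ranges covering every column exactly once.
    """
    import pandas as pd

    rows = _alignment_rows(alignment)
    width = len(rows[0][1])
    covered = [None] * width
    for start, end, elem in annotation:
        for c in range(int(start) - 1, int(end)):
            if c < 0 or c >= width or covered[c] is not None:
                raise ModelError(
                    f"annotation for {elem!r} overlaps or exceeds alignment"
                )
            covered[c] = elem
    if any(e is None for e in covered):
        missing = [i + 1 for i, e in enumerate(covered) if e is None][:5]
        raise ModelError(f"unannotated alignment columns (e.g. {missing})")

    freq = np.zeros((width, 5))
    letters = {c: k for k, c in enumerate(NUCS)}
    for _, seq in rows:
        for c, ch in enumerate(seq):
            freq[c, letters.get(ch, 4)] += 1  # index 4 = gap/other
    freq /= len(rows)
    freq_df = pd.DataFrame(freq, columns=list(NUCS) + ["gap"])
    freq_df.index = np.arange(1, width + 1)

    cols_of: dict[str, list[int]] = {}
    for c, elem in enumerate(covered):
        cols_of.setdefault(elem, []).append(c)
    lengths = {
        elem: [sum(seq[c] not in "-." for c in cols) for _, seq in rows]
        for elem, cols in cols_of.items()
    }
    len_df = pd.DataFrame(lengths)

    names = list(len_df.columns)
    mat = np.eye(len(names))
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            xa, xb = len_df[names[a]].values, len_df[names[b]].values
            if np.std(xa) == 0 or np.std(xb) == 0 or len(xa) < 3:
                rho = np.nan
            else:
                rho = pearson(xa, xb)
            mat[a, b] = mat[b, a] = rho
    corr_df = pd.DataFrame(mat, index=names, columns=names)
    return AlignmentSummary(len(rows), freq_df, len_df, corr_df)


def _infer_layout_entry(name: str) -> tuple[str, str, int]:
    """(kind, partner, pk_layer) inferred from naming conventions.

    Strand names ending in ``_5p``/``_3p`` (or lowercase ``a``/``b``
    suffix on a ``P*``/``PK*`` stem) denote duplex strands.
    """
    stem, partner = name, ""
    if name.endswith("_5p"):
        stem, partner = name[:-3], name[:-3] + "_3p"
    elif name.endswith("_3p"):
        stem, partner = name[:-3], name[:-3] + "_5p"
    elif name[:1].upper() == "P" and name[-1] in "ab" and len(name) > 1:
        stem = name[:-1]
        partner = stem + ("b" if name[-1] == "a" else "a")
    if partner:
        if stem.upper().startswith("PK"):
            layer = 2 if stem.rstrip("ab").endswith("2") else 1
            return "pseudoknot", partner, layer
        return "helix", partner, 0
    if name.upper().startswith("L"):
        return "loop", "", 0
    return "linker", "", 0


def derive_model(
    alignment,
    annotation,
    threshold: float = 0.9,
    corr_cutoff: float = 0.5,
    gap_fraction: float = 0.5,
    layout: list | None = None,
    name: str = "derived",
) -> SymbolicModel:
    """Derive a symbolic model from an annotated multiple alignment.

    A column's nucleotide enters the conservation mask iff its frequency
    among non-gap characters is *strictly* greater than ``threshold``;
    columns with more than ``gap_fraction`` gaps are treated as part of
    a variable-length element and left open.  Element length ranges are
    the observed min/max; correlations are retained when ``|rho|``
    exceeds ``corr_cutoff``, with the least-squares line through the
    observed joint lengths as the enforcement window.
    """
    if not 0 < threshold <= 1:
        raise ModelError("threshold must be in (0, 1]")
    summary = summarize_alignment(alignment, annotation)
    freq = summary.per_column_frequencies
    len_df = summary.element_lengths

    kinds: dict[str, tuple[str, str, int]] = {}
    if layout:
        for ent in layout:
            kinds[ent["name"]] = (
                ent["kind"],
                ent.get("partner", ""),
                int(ent.get("pk_layer", 0)),
            )

    elements = []
    order = []
    for start, end, elem in sorted(annotation):
        order.append((int(start), int(end), elem))
    for start, end, elem in order:
        kind, partner, layer = kinds.get(elem) or _infer_layout_entry(elem)
        obs = len_df[elem]
        lo, hi = int(obs.min()), int(obs.max())
        width = end - start + 1
        if hi > width:
            raise ModelError(f"element {elem!r}: lengths exceed column block")
        mask = []
        for c in range(start, end + 1):
            row = freq.loc[c]
            if row["gap"] > gap_fraction:
                mask.append(NUCS)
                continue
            nong = row[list(NUCS)]
            tot = float(nong.sum())
            if tot == 0:
                mask.append(NUCS)
                continue
            best = nong.idxmax()
            mask.append(best if nong[best] / tot > threshold else NUCS)
        # mask length must equal length_max: keep the canonical block ends
        if hi < width:
            mask = (
                mask[width - hi :]
                if _is_three_prime(elem, partner, order)
                else mask[:hi]
            )
        elements.append(
            ElementSpec(
                name=elem,
                kind=kind,
                length_min=lo,
                length_max=hi,
                partner=partner,
                conserved_mask=mask,
                pk_layer=layer,
            )
        )

    # reconcile partner strand ranges (pairing forces equal lengths)
    by_name = {e.name: e for e in elements}
    for e in elements:
        if e.partner and e.partner in by_name and not e.is_three_prime_strand:
            mate = by_name[e.partner]
            lo = max(e.length_min, mate.length_min)
            hi = min(e.length_max, mate.length_max)
            if lo > hi:
                raise ModelError(
                    f"partners {e.name!r}/{mate.name!r}: incompatible lengths"
                )
            for el in (e, mate):
                el.length_min, el.length_max = lo, hi
                el.conserved_mask = (
                    el.conserved_mask[len(el.conserved_mask) - hi :]
                    if _is_three_prime(el.name, el.partner, order)
                    else el.conserved_mask[:hi]
                )

    correlations = []
    names = list(len_df.columns)
    pos_of = {elem: i for i, (_, _, elem) in enumerate(order)}

    def gkey(n: str) -> str:
        p = by_name[n].partner
        return n if not p or pos_of[n] < pos_of.get(p, 1 << 30) else p

    group_seen = set()
    for a in range(len(names)):
        for b in range(a + 1, len(names)):
            na, nb = names[a], names[b]
            if by_name[na].partner == nb:
                continue  # partner strands are trivially rho=1
            key = frozenset((gkey(na), gkey(nb)))
            if key in group_seen:
                continue
            xa, xb = len_df[na].values.astype(float), len_df[nb].values.astype(float)
            if np.std(xa) == 0 or np.std(xb) == 0:
                continue
            rho = pearson(xa, xb)
            if abs(rho) <= corr_cutoff:
                continue
            group_seen.add(key)
            slope, intercept = np.polyfit(xa, xb, 1)
            resid = xb - (slope * xa + intercept)
            window = max(1.0, 2.0 * float(np.std(resid)))
            correlations.append(
                Correlation(na, nb, rho, window, float(slope), float(intercept))
            )

    totals = len_df.sum(axis=1)
    return SymbolicModel(
        elements=elements,
        correlations=correlations,
        mean_length=float(totals.mean()),
        total_length_range=(int(totals.min()), int(totals.max())),
        conservation_threshold=threshold,
        name=name,
    )


def _is_three_prime(name: str, partner: str, order) -> bool:
    if not partner:
        return False
    pos = {elem: i for i, (_, _, elem) in enumerate(order)}
    return pos.get(name, 0) > pos.get(partner, 0)


# ---------------------------------------------------------------------------
# Pseudoknot perturbation (deletion / progressive weakening)
# ---------------------------------------------------------------------------

def perturb_pseudoknot(
    model: SymbolicModel, pk: str, action: str = "delete", k: int = 0
) -> SymbolicModel:
    """Delete a pseudoknot or weaken it by removing ``k`` base pairs.

    ``pk`` may name either strand.  ``delete`` sets both strands' length
    range to (0, 0).  ``remove_pairs`` shortens both strands' ranges by
    ``k`` and trims the masks from the terminus distal to the first
    pair (the 5' strand's 3' end / the 3' strand's 5' end).
    """
    el = model.element(pk)
    if el.kind != "pseudoknot":
        raise ModelError(f"{pk!r} is not a pseudoknot element")
    mate_name = el.partner
    new = copy.deepcopy(model)
    a, b = new.element(el.name), new.element(mate_name)
    if action == "delete":
        for s in (a, b):
            s.length_min = s.length_max = 0
            s.conserved_mask = []
    elif action == "remove_pairs":
        if k < 1:
            raise ModelError("remove_pairs: k must be >= 1")
        if a.length_min - k < 1:
            raise ModelError(
                f"remove_pairs({k}) would leave {pk!r} with no pairs; "
                f"use delete instead"
            )
        for s in (a, b):
            s.length_min -= k
            s.length_max -= k
            s.conserved_mask = (
                s.conserved_mask[-s.length_max :]
                if s.is_three_prime_strand
                else s.conserved_mask[: s.length_max]
            )
    else:
        raise ModelError(f"unknown perturbation action {action!r}")
    new.total_length_range = (0, 0)  # recompute from element ranges
    new.mean_length = 0.0
    return SymbolicModel(
        elements=new.elements,
        correlations=new.correlations,
        conservation_threshold=new.conservation_threshold,
        base_triples=new.base_triples,
        name=f"{model.name}_{pk}_{action}" + (f"{k}" if k else ""),
    )


# ---------------------------------------------------------------------------
# Built-in MBF xrRNA models
# ---------------------------------------------------------------------------

def _mbf_elements(relaxed: bool) -> list:
    """Element table of the class-1 mosquito-borne flavivirus xrRNA model.

    Layout (5'->3'): threaded 5' segment, PK1 5' strand near the 5' end,
    the three-way junction of P1-P3 with PK2's 5' strand inside the P3
    loop, the PK1 3' strand ("CU") inside the junction, and PK2's 3'
    strand downstream of P1 — so that PK2 crosses P1 and closes the
    ring around the threaded 5' end.  The relaxed (de novo) variant
    keeps only PK1 and the base-triple nucleotides fixed and favors
    (without forcing) G-C at the junction helices.
    """
    N = "N"

    def mask(conserved: str, open_: str) -> str:
        return open_ if relaxed else conserved

    gc = relaxed  # G-C favored instead of hard-constrained
    return [
        # (name, kind, lo, hi, partner, mask, gc_favored, pk_layer)
        ("S5", "linker", 4, 6, "", "AAUANN", False, 0),
        ("PK1a", "pseudoknot", 2, 2, "PK1b", "AG", False, 1),
        ("J5", "linker", 1, 2, "", "AN", False, 0),
        ("P1a", "helix", 3, 3, "P1b", mask("GCG", "NNN"), gc, 0),
        ("J12", "linker", 0, 1, "", N, False, 0),
        ("P2a", "helix", 0, 3, "P2b", mask("CNN", "NNN"), gc, 0),
        ("L2", "loop", 3, 6, "", "NNNNNN", False, 0),
        ("P2b", "helix", 0, 3, "P2a", mask("NNG", "NNN"), gc, 0),
        ("J23", "linker", 1, 1, "", N, False, 0),
        ("P3a", "helix", 3, 7, "P3b", mask("GNNNNNN", "NNNNNNN"), gc, 0),
        ("L3a", "loop", 1, 3, "", "NNN", False, 0),
        ("PK2a", "pseudoknot", 3, 8, "PK2b", "NNNNNNNN", False, 2),
        ("L3b", "loop", 0, 1, "", N, False, 0),
        ("P3b", "helix", 3, 7, "P3a", mask("NNNNNNC", "NNNNNNN"), gc, 0),
        ("PK1b", "pseudoknot", 2, 2, "PK1a", "CU", False, 1),
        ("J31", "linker", 0, 1, "", N, False, 0),
        ("P1b", "helix", 3, 3, "P1a", mask("CGC", "NNN"), gc, 0),
        ("J1pk", "linker", 2, 5, "", "NNNNN", False, 0),
        ("PK2b", "pseudoknot", 3, 8, "PK2a", "NNNNNNNN", False, 2),
        ("S3", "linker", 0, 2, "", "NN", False, 0),
    ]


def _build_mbf(relaxed: bool) -> SymbolicModel:
    elements = [
        ElementSpec(
            name=n,
            kind=k,
            length_min=lo,
            length_max=hi,
            partner=p,
            conserved_mask=list(m),
            gc_favored=g,
            pk_layer=layer,
        )
        for (n, k, lo, hi, p, m, g, layer) in _mbf_elements(relaxed)
    ]
    return SymbolicModel(
        elements=elements,
        correlations=[Correlation("P3a", "L3a", rho=-0.9, window=1.0)],
        mean_length=54.0,
        conservation_threshold=0.9,
        base_triples=[
            BaseTriple("S5", 2, "P1a", 0, "P1b", 2, "BT1"),
            BaseTriple("J5", 0, "P3a", 0, "P3b", 6, "BT2"),
        ],
        name="denovo_mbf" if relaxed else "default_mbf",
    )


def default_mbf_model() -> SymbolicModel:
    """Conservative MBF xrRNA design model (consensus-constrained)."""
    return _build_mbf(relaxed=False)


def denovo_mbf_model() -> SymbolicModel:
    """Relaxed MBF model: only PK1 and base-triple nucleotides fixed."""
    return _build_mbf(relaxed=True)


# annotation sidecar I/O -----------------------------------------------------

def read_annotation_tsv(path) -> list:
    """Read (column_start, column_end, element) rows from a TSV file."""
    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if parts[0] == "column_start":
                continue
            out.append((int(parts[0]), int(parts[1]), parts[2]))
    return out


def write_annotation_tsv(annotation, path) -> None:
    with open(path, "w") as fh:
        fh.write("column_start\tcolumn_end\telement\n")
        for start, end, elem in annotation:
            fh.write(f"{start}\t{end}\t{elem}\n")
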