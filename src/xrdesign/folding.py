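"""Base-pair-energy folding engine.

Implements minimum free energy (MFE) folding, the McCaskill-style
partition function with base-pair probabilities, ensemble defect, and
the Boltzmann probability of a target structure — all under a simple
additive base-pair energy model (one energy per canonical pair type)
rather than the full nearest-neighbour model.  This is the conventional
energy model of constraint-based RNA sequence design: it is exact,
fast, and sufficient to rank candidate sequences by how strongly they
commit to a target secondary structure.

Pseudoknot pairs cannot enter a nested-structure ensemble; they are
treated as complementarity constraints plus additive energy terms (see
:func:`target_energy` and :func:`ensemble_defect`).  The nested
ensemble (partition function, pair probabilities) covers layer 0 only.

Numerics: the inside recursion runs in log space; the outside /
pair-probability pass works on ratios that are mathematically bounded
by 1, so it is carried out in the linear domain without overflow risk.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterator

import numpy as np

from .structure import TargetStructure, pairs_to_dotbracket

RNA_ALPHABET = "ACGU"

#: canonical pair classes
_GC = frozenset({("G", "C"), ("C", "G")})
_AU = frozenset({("A", "U"), ("U", "A")})
_GU = frozenset({("G", "U"), ("U", "G")})

NON_PAIRABLE = None


class FoldingError(ValueError):
    pass


@dataclass(frozen=True)
class BasePairEnergyModel:
    """Additive pair-energy model (arbitrary units, negative = stabilizing)."""

    e_gc: float = -3.0
    e_au: float = -2.0
    e_gu: float = -1.0
    beta: float = 1.0
    min_hairpin: int = 3

    def __post_init__(self) -> None:
        if self.e_gc > 0 or self.e_au > 0 or self.e_gu > 0:
            raise FoldingError("pair energies must be <= 0 (stabilizing)")
        if self.beta <= 0:
            raise FoldingError("beta must be > 0")
        if self.min_hairpin < 0:
            raise FoldingError("min_hairpin must be >= 0")


DEFAULT_MODEL = BasePairEnergyModel()


def pair_energy(m: BasePairEnergyModel, a: str, b: str) -> float | None:
    """Energy of pairing nucleotides ``a``/``b``; ``None`` if non-pairable."""
    if a not in RNA_ALPHABET or b not in RNA_ALPHABET:
        raise FoldingError(f"invalid nucleotide in pair ({a!r}, {b!r})")
    ab = (a, b)
    if ab in _GC:
        return m.e_gc
    if ab in _AU:
        return m.e_au
    if ab in _GU:
        return m.e_gu
    return None


def _check_seq(seq: str) -> str:
    seq = seq.upper().replace("T", "U")
    bad = set(seq) - set(RNA_ALPHABET)
    if bad:
        raise FoldingError(f"invalid characters in sequence: {sorted(bad)}")
    return seq


def _log_weights(seq: str, m: BasePairEnergyModel) -> np.ndarray:
    """lw[i, j] = -beta * e(s_i, s_j), or -inf if (i, j) cannot pair.

    0-based; enforces the minimum hairpin separation j - i > min_hairpin.
    """
    n = len(seq)
    lw = np.full((n, n), -np.inf)
    for i in range(n):
        for j in range(i + m.min_hairpin + 1, n):
            e = pair_energy(m, seq[i], seq[j])
            if e is not None:
                lw[i, j] = -m.beta * e
    return lw


# ---------------------------------------------------------------------------
# MFE
# ---------------------------------------------------------------------------

def mfe(seq: str, m: BasePairEnergyModel = DEFAULT_MODEL) -> tuple[str, float]:
    """Minimum-energy nested structure under the additive pair model.

    Deterministic traceback: on energy ties the closing base is left
    unpaired; among pairing partners the leftmost (smallest k) wins.
    Returns ``(dot_bracket, energy)``.
    """
    seq = _check_seq(seq)
    n = len(seq)
    if n == 0:
        raise FoldingError("empty sequence")
    lw = _log_weights(seq, m)
    emat = -lw / m.beta  # pair energies, +inf where unpairable
    # E[i][j]: minimum energy over half-open region [i, j)
    E = np.zeros((n + 2, n + 1))
    for span in range(2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span
            last = j - 1
            best = E[i][j - 1]  # last base unpaired
            ks = np.arange(i, last - m.min_hairpin)
            if ks.size:
                cand = E[i, ks] + emat[ks, last] + E[ks + 1, last]
                kbest = float(cand.min()) if cand.size else np.inf
                best = min(best, kbest)
            E[i][j] = best

    pairs: list[tuple[int, int]] = []
    stack = [(0, n)]
    while stack:
        i, j = stack.pop()
        if j - i < 2:
            continue
        last = j - 1
        if E[i][j] == E[i][j - 1]:  # prefer unpaired
            stack.append((i, j - 1))
            continue
        for k in range(i, last - m.min_hairpin):  # then leftmost partner
            if np.isfinite(emat[k][last]) and np.isclose(
                E[i][j], E[i][k] + emat[k][last] + E[k + 1][last]
            ):
                pairs.append((k, last))
                stack.append((i, k))
                stack.append((k + 1, last))
                break
        else:  # numerical safety net; should not happen
            stack.append((i, j - 1))
    energy = float(E[0][n])
    if not np.isfinite(energy):
        energy = 0.0
    return pairs_to_dotbracket(n, pairs), energy


# ---------------------------------------------------------------------------
# Partition function / base-pair probabilities
# ---------------------------------------------------------------------------

@dataclass
class EnsembleResult:
    """Nested-structure (layer 0) Boltzmann ensemble of a sequence."""

    seq: str
    logz: float
    bpp: np.ndarray          # p(i, j), 0-based, upper triangle
    unpaired: np.ndarray     # q(i) = 1 - sum_j p(i, j)
    mfe_structure: str
    mfe_energy: float

    @property
    def z(self) -> float:
        return float(np.exp(self.logz))


def partition_function(
    seq: str, m: BasePairEnergyModel = DEFAULT_MODEL
) -> EnsembleResult:
    """Partition function, pair probabilities and MFE of ``seq``.

    Inside recursion (log domain), half-open intervals::

        Z[i, j) = Z[i, j-1) + sum_k  Z[i, k) * w(k, j-1) * Z[k+1, j-1)

    Outside pass expressed directly on probabilities; every intermediate
    quantity is a ratio of restricted to total partition functions and
    therefore bounded, allowing linear-domain matrix contractions.
    """
    seq = _check_seq(seq)
    n = len(seq)
    if n == 0:
        raise FoldingError("empty sequence")
    lw = _log_weights(seq, m)
    h = m.min_hairpin

    ZH = np.zeros((n + 2, n + 1))  # log Z over [i, j); empty region -> 0
    for span in range(2, n + 1):
        for i in range(0, n - span + 1):
            j = i + span
            last = j - 1
            hi = last - h  # k in [i, hi)
            acc = ZH[i][j - 1]
            if hi > i:
                terms = ZH[i, i:hi] * 0.0  # placeholder to keep dtype
                terms = ZH[i, i:hi] + lw[i:hi, last] + ZH[i + 1 : hi + 1, last]
                tmax = terms.max()
                if np.isfinite(tmax):
                    acc = np.logaddexp(
                        acc, tmax + np.log(np.exp(terms - tmax).sum())
                    )
            ZH[i][j] = acc
    logz = float(ZH[0][n])

    # --- outside: pair probabilities, spans descending -------------------
    # P[i, j]  pair probability
    # G[k, l] = P[k, l] / Z(interior of (k, l))   (bounded <= 1)
    # A[k, i] = Z[k+1, i)   (left gap),  B[j, l] = Z[j+1, l)  (right gap)
    P = np.zeros((n, n))
    G = np.zeros((n, n))
    with np.errstate(over="ignore"):
        A = np.zeros((n, n))
        B = np.zeros((n, n))
        for k in range(n):
            for i in range(k + 1, n):
                A[k, i] = np.exp(ZH[k + 1][i])
        for j in range(n):
            for l in range(j + 1, n):
                B[j, l] = np.exp(ZH[j + 1][l])

    for span in range(n, h + 1, -1):
        idx = [(i, i + span - 1) for i in range(0, n - span + 1)]
        pairable = [(i, j) for (i, j) in idx if np.isfinite(lw[i, j])]
        if not pairable:
            continue
        # enclosing contribution via contraction over already-filled G
        GB = G @ B.T  # GB[k, j] = sum_l G[k, l] * B[j, l]
        for i, j in pairable:
            ext = np.exp(ZH[0][i] + lw[i, j] + ZH[i + 1][j] + ZH[j + 1][n] - logz)
            enc = 0.0
            if i > 0 and j < n - 1:
                enc = float(A[:i, i] @ GB[:i, j]) * np.exp(lw[i, j] + ZH[i + 1][j])
            p = min(1.0, ext + enc)
            P[i, j] = p
            G[i, j] = p * np.exp(-ZH[i + 1][j])

    q = 1.0 - P.sum(axis=0) - P.sum(axis=1)
    q = np.clip(q, 0.0, 1.0)
    s, e = mfe(seq, m)
    return EnsembleResult(seq, logz, P, q, s, e)


# ---------------------------------------------------------------------------
# Enumeration oracle (exact, exponential; for small instances and tests)
# ---------------------------------------------------------------------------

def enumerate_structures(
    seq: str, m: BasePairEnergyModel = DEFAULT_MODEL
) -> Iterator[tuple[frozenset[tuple[int, int]], float]]:
    """Yield every nested structure (0-based pair set) with its energy.

    Exhaustive recursion; intended as an independent oracle on short
    sequences (n <= ~16).
    """
    seq = _check_seq(seq)
    n = len(seq)
    lw = _log_weights(seq, m)
    emat = -lw / m.beta

    def rec(i: int, j: int) -> list[tuple[frozenset, float]]:
        # structures of half-open [i, j)
        if j - i < 2:
            return [(frozenset(), 0.0)]
        out = []
        last = j - 1
        for s, e in rec(i, j - 1):
            out.append((s, e))
        for k in range(i, last - m.min_hairpin):
            if not np.isfinite(emat[k][last]):
                continue
            for sl, el in rec(i, k):
                for sr, er in rec(k + 1, last):
                    out.append(
                        (sl | sr | {(k, last)}, el + er + emat[k][last])
                    )
        return out

    yield from rec(0, n)


# ---------------------------------------------------------------------------
# Target-structure scores
# ---------------------------------------------------------------------------

def target_energy(
    seq: str, ts: TargetStructure, m: BasePairEnergyModel = DEFAULT_MODEL
) -> float:
    """Additive energy of ``seq`` on all target pairs (all layers)."""
    seq = _check_seq(seq)
    if len(seq) != ts.length:
        raise FoldingError(
            f"sequence length {len(seq)} != structure length {ts.length}"
        )
    total = 0.0
    for i, j in sorted(ts.all_pairs()):
        e = pair_energy(m, seq[i - 1], seq[j - 1])
        if e is None:
            raise FoldingError(
                f"target pair ({i}, {j}) not pairable: {seq[i-1]}-{seq[j-1]}"
            )
        total += e
    return total


def target_probability(
    seq: str, ts: TargetStructure, m: BasePairEnergyModel = DEFAULT_MODEL
) -> float:
    """Boltzmann probability of folding into the exact layer-0 target.

    ``exp(-beta * E(layer-0 pairs)) / Z``; 0.0 if any layer-0 pair is
    non-pairable in ``seq``.
    """
    seq = _check_seq(seq)
    if len(seq) != ts.length:
        raise FoldingError("sequence/structure length mismatch")
    e0 = 0.0
    for i, j in ts.base_pairs:
        e = pair_energy(m, seq[i - 1], seq[j - 1])
        if e is None:
            return 0.0
        e0 += e
    res = partition_function(seq, m)
    return float(np.exp(-m.beta * e0 - res.logz))


def ensemble_defect(
    seq: str,
    ts: TargetStructure,
    m: BasePairEnergyModel = DEFAULT_MODEL,
    pk_credit: float = 1.0,
    ensemble: EnsembleResult | None = None,
) -> float:
    """Expected number of incorrectly paired/unpaired nucleotides.

    Standard nucleotide-counting ensemble defect on the layer-0 target::

        d = n - sum_{(i,j) in layer0} 2 p(i,j) - sum_{i unpaired} q(i)

    Pseudoknot target pairs cannot enter the nested ensemble; with the
    default ``pk_credit=1`` each PK pair contributes ``2*pk_credit``
    when its two positions are complementarity-satisfied in ``seq``
    (its positions are then excluded from the unpaired sum).  With
    ``pk_credit=0`` PK positions are treated as layer-0 unpaired.
    Result clamped to ``[0, n]``.
    """
    seq = _check_seq(seq)
    n = ts.length
    if len(seq) != n:
        raise FoldingError("sequence/structure length mismatch")
    res = ensemble if ensemble is not None else partition_function(seq, m)
    score = 0.0
    paired_positions: set[int] = set()
    for i, j in ts.base_pairs:
        score += 2.0 * res.bpp[i - 1, j - 1]
        paired_positions.update((i, j))
    pk_positions: set[int] = set()
    if pk_credit > 0:
        for i, j in ts.pk1_pairs | ts.pk2_pairs:
            pk_positions.update((i, j))
            if pair_energy(m, seq[i - 1], seq[j - 1]) is not None:
                score += 2.0 * pk_credit
    for i in range(1, n + 1):
        if i in paired_positions or i in pk_positions:
            continue
        score += res.unpaired[i - 1]
    return float(np.clip(n - score, 0.0, n))
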