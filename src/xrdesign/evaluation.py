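"""Candidate evaluation and experiment-side computations.

Covers the computational side of the wet-lab workflow: aggregate scoring
of design candidates (fold metrics + ring topology + filter verdicts),
design of the 25-nt 5' leader that turns an xrRNA into an XRN1
substrate, densitometry-based quantification of XRN1 resistance
relative to a wild-type lane, and the arithmetic connecting XRN1 stop
positions to resistant-product lengths on a gel.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .folding import (
    BasePairEnergyModel,
    DEFAULT_MODEL,
    ensemble_defect,
    mfe,
    partition_function,
    target_probability,
)
from .structure import TargetStructure, TopologyReport, check_ring_closure


class EvaluationError(ValueError):
    pass


# ---------------------------------------------------------------------------
# Candidate evaluation
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class FilterThresholds:
    """Package-defined selection filters.

    The exact-target probability decays exponentially with sequence
    length (for a pseudoknotted target the nested ensemble is
    intrinsically frustrated by the competing pseudoknot strands), so
    the default floor is deliberately permissive; raise it when
    comparing candidates of equal length.
    """

    max_defect_fraction: float = 0.15   # defect <= fraction * n
    min_target_probability: float = 1e-12
    min_thread: int = 4


@dataclass
class DesignCandidate:
    id: str
    sequence: str
    structure: TargetStructure
    defect: float
    target_probability: float
    topology: TopologyReport
    element_lengths: dict
    verdicts: dict
    provenance: dict = field(default_factory=dict)
    state: object = None

    @property
    def passes(self) -> bool:
        return all(self.verdicts.values())


def evaluate_candidate(
    seq: str,
    ts: TargetStructure,
    foldm: BasePairEnergyModel = DEFAULT_MODEL,
    thresholds: FilterThresholds | None = None,
    pk_credit: float = 1.0,
    min_thread: int | None = None,
) -> DesignCandidate:
    """Fold ``seq``, score it against ``ts`` and apply the filters."""
    if not seq:
        raise EvaluationError("empty sequence")
    if len(seq) != ts.length:
        raise EvaluationError(
            f"sequence length {len(seq)} != structure length {ts.length}"
        )
    thr = thresholds or FilterThresholds()
    mt = thr.min_thread if min_thread is None else min_thread
    ens = partition_function(seq, foldm)
    defect = ensemble_defect(seq, ts, foldm, pk_credit=pk_credit, ensemble=ens)
    prob = target_probability(seq, ts, foldm)
    topo = check_ring_closure(ts, min_thread=mt)
    element_lengths = {
        name: len(positions) for name, positions in ts.elements().items()
    }
    # a ring is demanded only of targets that carry pseudoknot pairs:
    # a plain hairpin has no ring to close, while a PK2-deleted xrRNA
    # (which still carries PK1) must fail here
    needs_ring = bool(ts.pk1_pairs or ts.pk2_pairs)
    verdicts = {
        "defect": defect <= thr.max_defect_fraction * ts.length,
        "probability": prob >= thr.min_target_probability,
        "topology": topo.ring_closed if needs_ring else True,
    }
    return DesignCandidate(
        id="",
        sequence=seq,
        structure=ts,
        defect=defect,
        target_probability=prob,
        topology=topo,
        element_lengths=element_lengths,
        verdicts=verdicts,
    )


# ---------------------------------------------------------------------------
# 5' leader design
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class LeaderConfig:
    length: int = 25
    min_unpaired_5prime: int = 4
    helix_min: int = 3
    helix_max: int = 5
    #: interference guard: minimum ensemble retention of the xrRNA's own
    #: pairs after concatenation (sum of their pair probabilities in the
    #: leader+xrRNA ensemble over the same sum in the xrRNA alone).
    #: Under the additive pair-energy model any 25-nt extension shares
    #: pairing capacity with the xrRNA, so retention is checked on the
    #: Boltzmann ensemble, not on the (tie-degenerate) MFE structure.
    interference_floor: float = 0.1
    #: retention at which a candidate is accepted without scanning further
    early_accept: float = 0.4
    #: candidate geometries scanned before settling for the best one
    scan_candidates: int = 5
    max_attempts: int = 200


def _helices(structure: str) -> list[list[tuple[int, int]]]:
    """Group a dot-bracket's pairs into maximal stacked helices (0-based)."""
    stack, pairs = [], []
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            pairs.append((stack.pop(), i))
    pairs.sort()
    helices: list[list[tuple[int, int]]] = []
    for p in pairs:
        if helices and helices[-1][-1] == (p[0] - 1, p[1] + 1):
            helices[-1].append(p)
        else:
            helices.append([p])
    return helices


def _pairs_of(structure: str) -> set[tuple[int, int]]:
    stack, pairs = [], set()
    for i, ch in enumerate(structure):
        if ch == "(":
            stack.append(i)
        elif ch == ")":
            pairs.add((stack.pop(), i))
    return pairs


def design_leader(
    xrrna_seq: str,
    foldm: BasePairEnergyModel = DEFAULT_MODEL,
    cfg: LeaderConfig = LeaderConfig(),
    seed: int = 0,
) -> str:
    """Design a 25-nt 5' leader for an xrRNA construct.

    The leader's own MFE structure must leave at least four unpaired
    positions at the 5' end (required for XRN1 loading) and contain a
    single helix of 3-5 base pairs.  Structural interference with the
    xrRNA is kept low at the ensemble level: among the scanned candidate
    geometries the one maximizing the retention of the xrRNA's own pair
    probabilities in the concatenated ensemble is returned, and retention
    below ``cfg.interference_floor`` is an error.  Deterministic per
    (sequence, seed).
    """
    xrrna_seq = xrrna_seq.upper().replace("T", "U")
    if not xrrna_seq or set(xrrna_seq) - set("ACGU"):
        raise EvaluationError("invalid xrRNA sequence")
    rng = np.random.default_rng(np.random.SeedSequence([seed, len(xrrna_seq)]))
    xr_struct, _ = mfe(xrrna_seq, foldm)
    xr_pairs = sorted(_pairs_of(xr_struct))
    xr_ens = partition_function(xrrna_seq, foldm) if xr_pairs else None
    ref_alone = (
        sum(xr_ens.bpp[i, j] for i, j in xr_pairs) if xr_pairs else 0.0
    )
    n_lead = cfg.length

    def retention(leader: str) -> float:
        if not xr_pairs or ref_alone == 0.0:
            return 1.0
        cat = partition_function(leader + xrrna_seq, foldm)
        kept = sum(cat.bpp[i + n_lead, j + n_lead] for i, j in xr_pairs)
        return kept / ref_alone

    best: tuple[float, str] | None = None
    scanned = 0
    for _ in range(cfg.max_attempts):
        h = int(rng.integers(cfg.helix_min, cfg.helix_max + 1))
        loop = int(rng.integers(foldm.min_hairpin, foldm.min_hairpin + 3))
        rem = n_lead - cfg.min_unpaired_5prime - 2 * h - loop
        if rem < 0:
            continue
        pre = int(rng.integers(0, rem + 1))
        tail = rem - pre
        leader = (
            "A" * (cfg.min_unpaired_5prime + pre)
            + "G" * h
            + "A" * loop
            + "C" * h
            + "A" * tail
        )
        ls, _ = mfe(leader, foldm)
        if any(ch != "." for ch in ls[: cfg.min_unpaired_5prime]):
            continue
        hel = _helices(ls)
        if len(hel) != 1 or not (cfg.helix_min <= len(hel[0]) <= cfg.helix_max):
            continue
        r = retention(leader)
        if r >= cfg.early_accept:
            return leader
        if best is None or r > best[0]:
            best = (r, leader)
        scanned += 1
        if scanned >= cfg.scan_candidates:
            break
    if best is not None and best[0] >= cfg.interference_floor:
        return best[1]
    raise EvaluationError(
        f"no satisfying leader found within {cfg.max_attempts} attempts"
    )


# ---------------------------------------------------------------------------
# XRN1 resistance quantification
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GelLane:
    """Densitometry of one degradation-assay lane (arbitrary units).

    ``substrate_intensity`` is the untreated-RNA band; because 5'
    phosphorylation is incomplete, the non-phosphorylated band intensity
    is subtracted from it before forming the product/substrate ratio.
    """

    substrate_intensity: float
    product_intensity: float
    unphosphorylated_intensity: float = 0.0
    label: str = ""

    def __post_init__(self) -> None:
        if min(
            self.substrate_intensity,
            self.product_intensity,
            self.unphosphorylated_intensity,
        ) < 0:
            raise EvaluationError(f"lane {self.label!r}: negative intensity")
        if self.substrate_intensity <= self.unphosphorylated_intensity:
            raise EvaluationError(
                f"lane {self.label!r}: corrected substrate intensity <= 0"
            )

    @property
    def ratio(self) -> float:
        return self.product_intensity / (
            self.substrate_intensity - self.unphosphorylated_intensity
        )


def relative_resistance(wt: GelLane, x: GelLane) -> float:
    """Resistance of lane ``x`` as a percentage of the wild-type lane.

    The wild-type ratio is set to 100%; the query lane's
    background-corrected product/substrate ratio is normalized to it.
    """
    if wt.ratio == 0:
        raise EvaluationError("wild-type lane has zero product ratio")
    return 100.0 * x.ratio / wt.ratio


# ---------------------------------------------------------------------------
# Stop-point arithmetic
# ---------------------------------------------------------------------------

def product_length(substrate_len: int, stop_pos: int) -> int:
    """Length of the XRN1-resistant product.

    ``stop_pos`` is the 1-based position (on the full substrate) of the
    5'-most nucleotide of the resistant fragment.
    """
    if not 1 <= stop_pos <= substrate_len:
        raise EvaluationError(
            f"stop position {stop_pos} out of range [1, {substrate_len}]"
        )
    return substrate_len - stop_pos + 1


def stop_position(substrate_len: int, prod_len: int) -> int:
    """Inverse of :func:`product_length`."""
    if not 1 <= prod_len <= substrate_len:
        raise EvaluationError("product length out of range")
    return substrate_len - prod_len + 1


def stop_offset(ts: TargetStructure, stop_pos: int) -> int:
    """Signed offset of a stop position to PK1's 5' strand (positive =
    upstream), the convention in which natural MBF xrRNAs stop two
    positions upstream of PK1."""
    if not ts.pk1_pairs:
        raise EvaluationError("structure has no PK1 pairs")
    pk1_start = min(i for i, _ in ts.pk1_pairs)
    return pk1_start - stop_pos


# ---------------------------------------------------------------------------
# TSV interfaces
# ---------------------------------------------------------------------------

def read_lanes_tsv(path) -> dict:
    """Read gel lanes from TSV: label, substrate, product, unphosphorylated."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t")
    required = {"label", "substrate", "product", "unphosphorylated"}
    if not required <= set(df.columns):
        raise EvaluationError(f"lane table missing columns {required - set(df.columns)}")
    lanes = {}
    for _, row in df.iterrows():
        lanes[str(row["label"])] = GelLane(
            substrate_intensity=float(row["substrate"]),
            product_intensity=float(row["product"]),
            unphosphorylated_intensity=float(row["unphosphorylated"]),
            label=str(row["label"]),
        )
    return lanes


def read_stop_points_tsv(path):
    """Stop-point records: construct, substrate_len, stop_pos[, read_count]."""
    import pandas as pd

    df = pd.read_csv(path, sep="\t", comment="#")
    required = {"construct", "substrate_len", "stop_pos"}
    if not required <= set(df.columns):
        raise EvaluationError(
            f"stop-point table missing columns {required - set(df.columns)}"
        )
    return df


def candidates_report(candidates) -> "object":
    """Summary table (pandas DataFrame) of evaluated candidates."""
    import pandas as pd

    rows = []
    for c in candidates:
        rows.append(
            {
                "id": c.id,
                "length": c.structure.length,
                "defect": c.defect,
                "target_probability": c.target_probability,
                "ring_closed": c.topology.ring_closed,
                "pk1_pairs": c.topology.pk1_pair_count,
                "pk2_pairs": c.topology.pk2_pair_count,
                "passes": c.passes,
                "sequence": c.sequence,
                "structure": c.structure.to_dotbracket(),
            }
        )
    return pd.DataFrame(rows)
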