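"""Boltzmann-weighted sampling of variable-length xrRNA sequences.

Each model position takes a value in {A, C, G, U, eps}; the empty letter
eps acts like an alignment gap and lets sequence length vary during
design.  Three constraint families are induced from the symbolic model:

1. conservation — positions are limited to their mask nucleotides;
2. complementarity — paired positions (helices *and* pseudoknots) must
   form canonical/wobble pairs;
3. gap regulation — gaps are confined to canonical blocks per element
   (keeping sampling non-ambiguous: one letters-representation per
   concrete sequence), partner strands carry equal gap counts, element
   lengths stay in range, correlated length pairs stay inside their
   joint windows, and the total length stays in the model's range.

Valid assignments are drawn *exactly* from the Boltzmann distribution
with weight

    w(s) = exp(-beta_energy * E_target(s))
           * exp(-alpha_length * |len(s) - mean_length|)
           * gc-bias terms,

where E_target is the additive pair energy on the state's concrete
target structure (all layers).  Because the weight factorizes over
element lengths and pair/position contents, sampling proceeds by exact
enumeration of the element-length configuration space (vectorized)
followed by independent categorical draws per pair and per unpaired
position.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from itertools import product as iproduct

import numpy as np

from .folding import BasePairEnergyModel, DEFAULT_MODEL, pair_energy
from .model_io import COMPLEMENTARY, ModelError, NUCS, SymbolicModel
from .structure import TargetStructure, instantiate_target

GAP = "-"
_GC_PAIRS = frozenset({("G", "C"), ("C", "G")})


class SamplingError(ValueError):
    pass


@dataclass(frozen=True)
class SamplerConfig:
    """Weights and bookkeeping for Boltzmann sequence sampling.

    ``beta_energy`` scales the structure-energy factor, ``alpha_length``
    the penalty on deviating from the family mean length; ``gc_bias``
    multiplies the weight of G-C/C-G pairs at elements flagged
    ``gc_favored`` (a soft preference, not a constraint).
    """

    beta_energy: float = 1.0
    alpha_length: float = 3.0
    n_samples: int = 10
    seed: int = 0
    gc_bias: float = 2.0
    max_length_combos: int = 5_000_000

    def __post_init__(self) -> None:
        if self.beta_energy < 0 or self.alpha_length < 0:
            raise SamplingError("beta_energy and alpha_length must be >= 0")
        if self.gc_bias <= 0:
            raise SamplingError("gc_bias must be > 0")


@dataclass
class SequenceState:
    """Assignment of letters to a symbolic model at concrete lengths.

    ``lengths`` maps each length group (keyed by its 5' element name) to
    the realized length; ``letters_by_element`` holds realized letters
    per element in concrete 5'->3' order.  Gap placement is canonical
    (implicit): trimmed positions sit at the 3' end of 5'/unpaired
    elements and at the 5' end of 3' partner strands.
    """

    model: SymbolicModel
    lengths: dict
    letters_by_element: dict

    def length_of(self, element: str) -> int:
        return self.lengths[self.model.group_of(element)]

    @property
    def total_length(self) -> int:
        return sum(self.length_of(e.name) for e in self.model.elements)

    @property
    def letters(self) -> str:
        """Per-model-position letters including eps (as ``-``)."""
        out = []
        for el in self.model.elements:
            L = self.length_of(el.name)
            body = "".join(self.letters_by_element.get(el.name, ""))
            gaps = GAP * (el.length_max - L)
            out.append(gaps + body if el.is_three_prime_strand else body + gaps)
        return "".join(out)

    def concretize(self) -> tuple[str, TargetStructure]:
        """Concrete RNA string (eps removed) and its target structure."""
        seq = "".join(
            "".join(self.letters_by_element.get(el.name, ""))
            for el in self.model.elements
        )
        lens = {g: L for g, L in self.lengths.items()}
        ts = instantiate_target(self.model, lens)
        if len(seq) != ts.length:
            raise SamplingError("internal: letters inconsistent with lengths")
        return seq, ts

    def copy(self) -> "SequenceState":
        return SequenceState(
            self.model,
            dict(self.lengths),
            {k: list(v) for k, v in self.letters_by_element.items()},
        )


# ---------------------------------------------------------------------------
# Constraint construction
# ---------------------------------------------------------------------------

@dataclass
class Constraints:
    """Compiled constraint set of a symbolic model.

    ``pair_choices[(group, k)]`` lists the allowed letter pairs for pair
    index ``k`` of a duplex group; ``unpaired_choices[(element, k)]``
    the allowed letters of mask index ``k`` of an unpaired element.
    Gap-regulation (equal strand lengths, ranges, correlation windows,
    total-length range) is structural and enforced by the length grid.
    """

    model: SymbolicModel
    pair_choices: dict
    unpaired_choices: dict
    gc_flag: dict  # group -> bool


def build_constraints(model: SymbolicModel) -> Constraints:
    """Compile conservation + complementarity + gap-regulation constraints."""
    pair_choices: dict = {}
    gc_flag: dict = {}
    for five, three in model.paired_element_pairs():
        group = five.name
        gc_flag[group] = five.gc_favored or three.gc_favored
        for k in range(five.length_max):
            allowed_a = five.allowed(k)
            allowed_b = three.allowed(three.length_max - 1 - k)
            choices = [
                (a, b)
                for a in allowed_a
                for b in allowed_b
                if (a, b) in COMPLEMENTARY
            ]
            if not choices:
                raise ModelError(
                    f"contradictory constraints: pair {k} of "
                    f"{five.name}/{three.name} has no complementary letters "
                    f"(masks {allowed_a!r} / {allowed_b!r})"
                )
            pair_choices[(group, k)] = choices
    unpaired_choices: dict = {}
    for el in model.elements:
        if el.is_paired:
            continue
        for k in range(el.length_max):
            letters = el.allowed(k)
            if not letters:
                raise ModelError(
                    f"contradictory constraints: element {el.name!r} "
                    f"position {k} allows no letters"
                )
            unpaired_choices[(el.name, k)] = letters
    return Constraints(model, pair_choices, unpaired_choices, gc_flag)


def _pair_weights(
    cons: Constraints,
    group: str,
    k: int,
    cfg: SamplerConfig,
    em: BasePairEnergyModel,
) -> tuple[list, np.ndarray]:
    choices = cons.pair_choices[(group, k)]
    w = np.array(
        [
            math.exp(-cfg.beta_energy * pair_energy(em, a, b))
            * (cfg.gc_bias if cons.gc_flag[group] and (a, b) in _GC_PAIRS else 1.0)
            for a, b in choices
        ]
    )
    return choices, w


# ---------------------------------------------------------------------------
# Length configuration grid
# ---------------------------------------------------------------------------

def _length_grid(model: SymbolicModel, cfg: SamplerConfig, cons: Constraints,
                 em: BasePairEnergyModel):
    """All valid length configurations with their log-weights.

    Returns (group_keys, combos[n, g], logw[n]); raises if the grid
    exceeds ``cfg.max_length_combos`` or no configuration is valid.
    """
    groups = model.length_groups()
    keys = [g[0] for g in groups]
    ranges = [np.arange(lo, hi + 1) for (_, _, lo, hi) in groups]
    sizes = [r.size for r in ranges]
    n_combos = int(np.prod([float(s) for s in sizes]))
    if n_combos > cfg.max_length_combos:
        raise SamplingError(
            f"length configuration space too large ({n_combos:.3g} combos); "
            f"narrow the element ranges"
        )
    mesh = np.meshgrid(*ranges, indexing="ij")
    combos = np.stack([m.ravel() for m in mesh], axis=1).astype(np.int32)

    mult = np.array(
        [2 if model.element(key).is_paired else 1 for key in keys]
    )
    total = combos @ mult
    lo, hi = model.total_length_range
    valid = (total >= lo) & (total <= hi)

    gidx = {key: i for i, key in enumerate(keys)}

    # structural feasibility: the innermost pair of every duplex must
    # enclose at least MIN_HAIRPIN nucleotides
    from .structure import MIN_HAIRPIN

    order = {el.name: i for i, el in enumerate(model.elements)}
    for five, three in model.paired_element_pairs():
        between = [
            el.name
            for el in model.elements
            if order[five.name] < order[el.name] < order[three.name]
        ]
        gap = np.zeros(combos.shape[0], dtype=np.int64)
        for name in between:
            gap += combos[:, gidx[model.group_of(name)]]
        L = combos[:, gidx[five.name]]
        valid &= (L == 0) | (gap >= MIN_HAIRPIN)

    for corr in model.correlations:
        ga = gidx[model.group_of(corr.element_a)]
        gb = gidx[model.group_of(corr.element_b)]
        slope, intercept = corr.line(model)
        resid = combos[:, gb] - (slope * combos[:, ga] + intercept)
        valid &= np.abs(resid) <= corr.window + 1e-9

    if not valid.any():
        raise SamplingError("constraint set unsatisfiable: no valid lengths")

    # log-weight: length factor + per-group content partition functions
    logw = -cfg.alpha_length * np.abs(total.astype(float) - model.mean_length)
    for i, key in enumerate(keys):
        el = model.element(key)
        lo_g, hi_g = el.length_min, el.length_max
        table = np.zeros(hi_g - lo_g + 1)
        cum = 0.0
        per_k = []
        if el.is_paired:
            for k in range(hi_g):
                _, w = _pair_weights(cons, key, k, cfg, em)
                per_k.append(math.log(w.sum()))
        else:
            for k in range(hi_g):
                per_k.append(math.log(len(cons.unpaired_choices[(key, k)])))
        for L in range(hi_g + 1):
            if L >= lo_g:
                table[L - lo_g] = cum
            if L < hi_g:
                cum += per_k[L]
        logw += table[combos[:, i] - lo_g]

    combos = combos[valid]
    logw = logw[valid]
    return keys, combos, logw


# ---------------------------------------------------------------------------
# Sampling
# ---------------------------------------------------------------------------

def _fill_letters(
    model: SymbolicModel,
    cons: Constraints,
    lengths: dict,
    cfg: SamplerConfig,
    em: BasePairEnergyModel,
    rng: np.random.Generator,
) -> dict:
    letters: dict = {}
    for five, three in model.paired_element_pairs():
        L = lengths[five.name]
        a_letters = [""] * L
        b_letters = [""] * L
        for k in range(L):
            choices, w = _pair_weights(cons, five.name, k, cfg, em)
            a, b = choices[rng.choice(len(choices), p=w / w.sum())]
            a_letters[k] = a
            b_letters[L - 1 - k] = b
        letters[five.name] = a_letters
        letters[three.name] = b_letters
    for el in model.elements:
        if el.is_paired:
            continue
        L = lengths[el.name]
        letters[el.name] = [
            cons.unpaired_choices[(el.name, k)][
                rng.integers(len(cons.unpaired_choices[(el.name, k)]))
            ]
            for k in range(L)
        ]
    return letters


def sample(
    model: SymbolicModel,
    cfg: SamplerConfig,
    energy_model: BasePairEnergyModel = DEFAULT_MODEL,
    rng: np.random.Generator | None = None,
) -> list[SequenceState]:
    """Draw ``cfg.n_samples`` states exactly from the Boltzmann weights."""
    if cfg.n_samples < 1:
        raise SamplingError("requested sample count must be >= 1")
    cons = build_constraints(model)
    keys, combos, logw = _length_grid(model, cfg, cons, energy_model)
    p = np.exp(logw - logw.max())
    p /= p.sum()
    if rng is None:
        rng = np.random.default_rng(cfg.seed)
    draws = rng.choice(combos.shape[0], size=cfg.n_samples, p=p)
    states = []
    for d in draws:
        glens = {key: int(combos[d, i]) for i, key in enumerate(keys)}
        lens = {
            el.name: glens[model.group_of(el.name)] for el in model.elements
        }
        letters = _fill_letters(model, cons, lens, cfg, energy_model, rng)
        states.append(SequenceState(model, glens, letters))
    return states


def concretize(state: SequenceState) -> tuple[str, TargetStructure]:
    return state.concretize()


# ---------------------------------------------------------------------------
# Independent validation and exhaustive enumeration (oracles)
# ---------------------------------------------------------------------------

def hairpin_gaps_ok(model: SymbolicModel, lens: dict) -> bool:
    """True iff every present duplex encloses >= MIN_HAIRPIN nucleotides
    between its innermost pair, at element lengths ``lens``."""
    from .structure import MIN_HAIRPIN

    order = {el.name: i for i, el in enumerate(model.elements)}
    for five, three in model.paired_element_pairs():
        if lens[five.name] == 0:
            continue
        gap = sum(
            lens[el.name]
            for el in model.elements
            if order[five.name] < order[el.name] < order[three.name]
        )
        if gap < MIN_HAIRPIN:
            return False
    return True


def validate_state(state: SequenceState) -> None:
    """Check a state against the full constraint set from first principles.

    Deliberately independent of the sampler's own bookkeeping: recomputes
    masks, complementarity, ranges, correlation windows and the total
    length directly from the model.
    """
    model = state.model
    for el in model.elements:
        L = state.length_of(el.name)
        if not (el.length_min <= L <= el.length_max):
            raise SamplingError(f"element {el.name!r}: length {L} out of range")
        body = state.letters_by_element.get(el.name, [])
        if len(body) != L:
            raise SamplingError(f"element {el.name!r}: letters/length mismatch")
        for pos, letter in enumerate(body):
            mask_idx = (el.length_max - L + pos) if el.is_three_prime_strand else pos
            if letter not in el.allowed(mask_idx):
                raise SamplingError(
                    f"element {el.name!r} position {pos}: letter {letter!r} "
                    f"violates mask {el.allowed(mask_idx)!r}"
                )
    for five, three in model.paired_element_pairs():
        L = state.length_of(five.name)
        if state.length_of(three.name) != L:
            raise SamplingError(
                f"strands {five.name}/{three.name} have unequal gap counts"
            )
        a = state.letters_by_element.get(five.name, [])
        b = state.letters_by_element.get(three.name, [])
        for k in range(L):
            if (a[k], b[L - 1 - k]) not in COMPLEMENTARY:
                raise SamplingError(
                    f"pair {k} of {five.name}/{three.name} not complementary: "
                    f"{a[k]}-{b[L - 1 - k]}"
                )
    for corr in model.correlations:
        la = state.length_of(corr.element_a)
        lb = state.length_of(corr.element_b)
        slope, intercept = corr.line(model)
        if abs(lb - (slope * la + intercept)) > corr.window + 1e-9:
            raise SamplingError(
                f"correlation window violated: ({corr.element_a}, "
                f"{corr.element_b}) lengths ({la}, {lb})"
            )
    lo, hi = model.total_length_range
    if not lo <= state.total_length <= hi:
        raise SamplingError(f"total length {state.total_length} out of range")


def state_log_weight(
    state: SequenceState,
    cfg: SamplerConfig,
    energy_model: BasePairEnergyModel = DEFAULT_MODEL,
) -> float:
    """log w(s): direct evaluation of the sampling weight of a state."""
    from .folding import target_energy

    seq, ts = state.concretize()
    e = target_energy(seq, ts, energy_model)
    logw = -cfg.beta_energy * e
    logw += -cfg.alpha_length * abs(state.total_length - state.model.mean_length)
    if cfg.gc_bias != 1.0:
        cons = build_constraints(state.model)
        for five, three in state.model.paired_element_pairs():
            if not cons.gc_flag[five.name]:
                continue
            L = state.length_of(five.name)
            a = state.letters_by_element[five.name]
            b = state.letters_by_element[three.name]
            for k in range(L):
                if (a[k], b[L - 1 - k]) in _GC_PAIRS:
                    logw += math.log(cfg.gc_bias)
    return logw


def count_states(model: SymbolicModel, cfg: SamplerConfig | None = None) -> int:
    """Number of valid assignments (for enumerability checks)."""
    cfg = cfg or SamplerConfig()
    cons = build_constraints(model)
    keys, combos, _ = _length_grid(model, cfg, cons, DEFAULT_MODEL)
    total = 0
    for row in combos:
        count = 1
        for i, key in enumerate(keys):
            el = model.element(key)
            L = int(row[i])
            if el.is_paired:
                for k in range(L):
                    count *= len(cons.pair_choices[(key, k)])
            else:
                for k in range(L):
                    count *= len(cons.unpaired_choices[(key, k)])
        total += count
    return total


def enumerate_states(
    model: SymbolicModel,
    cfg: SamplerConfig | None = None,
    max_states: int = 200_000,
):
    """Yield every valid SequenceState (exhaustive; toy models only)."""
    cfg = cfg or SamplerConfig()
    n = count_states(model, cfg)
    if n > max_states:
        raise SamplingError(f"state space too large to enumerate ({n})")
    cons = build_constraints(model)
    keys, combos, _ = _length_grid(model, cfg, cons, DEFAULT_MODEL)
    for row in combos:
        glens = {key: int(row[i]) for i, key in enumerate(keys)}
        lens = {el.name: glens[model.group_of(el.name)] for el in model.elements}
        slots = []  # (kind, element(s), k)
        domains = []
        for five, three in model.paired_element_pairs():
            for k in range(lens[five.name]):
                slots.append(("pair", five.name, three.name, k))
                domains.append(cons.pair_choices[(five.name, k)])
        for el in model.elements:
            if el.is_paired:
                continue
            for k in range(lens[el.name]):
                slots.append(("pos", el.name, None, k))
                domains.append(list(cons.unpaired_choices[(el.name, k)]))
        for assignment in iproduct(*domains):
            letters = {
                el.name: [""] * lens[el.name] for el in model.elements
            }
            for slot, value in zip(slots, assignment):
                kind, a_name, b_name, k = slot
                if kind == "pair":
                    L = lens[a_name]
                    letters[a_name][k] = value[0]
                    letters[b_name][L - 1 - k] = value[1]
                else:
                    letters[a_name][k] = value
            yield SequenceState(model, dict(glens), letters)
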