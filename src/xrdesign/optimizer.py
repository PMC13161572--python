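"""Two-step Monte Carlo refinement of sampled xrRNA candidates.

Sampling favors low target-structure energy but not specificity; the
post-sampling optimization sharpens sequences toward the target fold in
two stages: (1) ensemble-defect minimization, steering the whole
thermodynamic ensemble toward the target, then (2) maximization of the
Boltzmann probability of the exact target structure.  Moves are point
mutations (paired positions mutated jointly, preserving complementarity)
and gap toggles that grow or shrink a variable element by one position
at its canonical end — so sequence length can change during
optimization while every intermediate state satisfies the full
constraint set by construction.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .folding import BasePairEnergyModel, DEFAULT_MODEL, ensemble_defect, target_probability
from .sampler import (
    Constraints,
    SamplerConfig,
    SequenceState,
    build_constraints,
    sample,
    validate_state,
)


@dataclass(frozen=True)
class OptimizerConfig:
    """Move budgets and Metropolis schedule for the two stages."""

    steps_stage1: int = 3000
    steps_stage2: int = 3000
    temperature_stage1: float = 1.0
    temperature_stage2: float = 0.3
    cooling: float = 1.0
    #: relative rates of (point-mutation, gap-toggle) moves
    move_weights: tuple = (3.0, 1.0)
    patience: int = 500
    greedy: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.steps_stage1 < 0 or self.steps_stage2 < 0:
            raise ValueError("step counts must be >= 0")
        if self.temperature_stage1 <= 0 or self.temperature_stage2 <= 0:
            raise ValueError("temperatures must be > 0")
        if any(w < 0 for w in self.move_weights) or not any(self.move_weights):
            raise ValueError("move_weights must be non-negative, not all zero")


@dataclass
class OptimizationTrace:
    records: list = field(default_factory=list)  # (step, objective, accepted, move)
    best_objective: float = math.inf
    best_step: int = -1
    stopped_early: bool = False

    def add(self, step: int, objective: float, accepted: bool, move: str) -> None:
        self.records.append((step, objective, accepted, move))


# ---------------------------------------------------------------------------
# Move proposal
# ---------------------------------------------------------------------------

def _mutation_slots(state: SequenceState, cons: Constraints) -> list:
    slots = []
    model = state.model
    for five, three in model.paired_element_pairs():
        L = state.length_of(five.name)
        for k in range(L):
            if len(cons.pair_choices[(five.name, k)]) > 1:
                slots.append(("pair", five.name, three.name, k))
    for el in model.elements:
        if el.is_paired:
            continue
        for k in range(state.length_of(el.name)):
            if len(cons.unpaired_choices[(el.name, k)]) > 1:
                slots.append(("pos", el.name, None, k))
    return slots


def _length_move_ok(state: SequenceState, group: str, new_len: int) -> bool:
    model = state.model
    el = model.element(group)
    if not (el.length_min <= new_len <= el.length_max):
        return False
    mult = 2 if el.is_paired else 1
    total = state.total_length + mult * (new_len - state.lengths[group])
    lo, hi = model.total_length_range
    if not lo <= total <= hi:
        return False
    lens = dict(state.lengths)
    lens[group] = new_len
    from .sampler import hairpin_gaps_ok

    full = {el.name: lens[model.group_of(el.name)] for el in model.elements}
    if not hairpin_gaps_ok(model, full):
        return False
    for corr in model.correlations:
        ga = model.group_of(corr.element_a)
        gb = model.group_of(corr.element_b)
        slope, intercept = corr.line(model)
        if abs(lens[gb] - (slope * lens[ga] + intercept)) > corr.window + 1e-9:
            return False
    return True


def _gap_slots(state: SequenceState) -> list:
    slots = []
    for group, _, lo, hi in state.model.length_groups():
        if lo == hi:
            continue
        L = state.lengths[group]
        if _length_move_ok(state, group, L + 1):
            slots.append((group, +1))
        if _length_move_ok(state, group, L - 1):
            slots.append((group, -1))
    return slots


def propose_move(
    state: SequenceState,
    rng: np.random.Generator,
    cons: Constraints | None = None,
    move_weights: tuple = (3.0, 1.0),
) -> tuple[SequenceState, str]:
    """Constraint-preserving neighbor of ``state``.

    Returns ``(neighbor, move_kind)``; ``move_kind`` is ``"none"`` when
    the model admits no legal move (fully constrained).
    """
    model = state.model
    if cons is None:
        cons = build_constraints(model)
    mut = _mutation_slots(state, cons)
    gap = _gap_slots(state)
    w_mut = move_weights[0] if mut else 0.0
    w_gap = move_weights[1] if gap else 0.0
    if w_mut + w_gap == 0.0:
        return state.copy(), "none"
    new = state.copy()
    if rng.random() < w_mut / (w_mut + w_gap):
        kind, a_name, b_name, k = mut[rng.integers(len(mut))]
        if kind == "pair":
            L = new.length_of(a_name)
            cur = (
                new.letters_by_element[a_name][k],
                new.letters_by_element[b_name][L - 1 - k],
            )
            options = [c for c in cons.pair_choices[(a_name, k)] if c != cur]
            a, b = options[rng.integers(len(options))]
            new.letters_by_element[a_name][k] = a
            new.letters_by_element[b_name][L - 1 - k] = b
        else:
            cur = new.letters_by_element[a_name][k]
            options = [
                c for c in cons.unpaired_choices[(a_name, k)] if c != cur
            ]
            new.letters_by_element[a_name][k] = options[rng.integers(len(options))]
        return new, "mutate"

    group, delta = gap[rng.integers(len(gap))]
    el = model.element(group)
    L = new.lengths[group]
    new.lengths[group] = L + delta
    if el.is_paired:
        partner = el.partner
        a = new.letters_by_element[group]
        b = new.letters_by_element[partner]
        if delta > 0:  # new pair at index L (5' strand 3' end / 3' strand 5' end)
            choices = cons.pair_choices[(group, L)]
            na, nb = choices[rng.integers(len(choices))]
            a.append(na)
            b.insert(0, nb)
        else:
            a.pop()
            b.pop(0)
    else:
        body = new.letters_by_element[group]
        if delta > 0:
            letters = cons.unpaired_choices[(group, L)]
            body.append(letters[rng.integers(len(letters))])
        else:
            body.pop()
    return new, "grow" if delta > 0 else "shrink"


# ---------------------------------------------------------------------------
# Metropolis walk
# ---------------------------------------------------------------------------

def _metropolis(
    state: SequenceState,
    objective,
    steps: int,
    temperature: float,
    cooling: float,
    patience: int,
    move_weights: tuple,
    greedy: bool,
    rng: np.random.Generator,
    validate_each: bool = False,
) -> tuple[SequenceState, OptimizationTrace]:
    cons = build_constraints(state.model)
    trace = OptimizationTrace()
    cur = state.copy()
    cur_obj = objective(cur)
    best, best_obj, best_step = cur.copy(), cur_obj, -1
    trace.best_objective = best_obj
    T = temperature
    since_best = 0
    for step in range(steps):
        prop, move = propose_move(cur, rng, cons, move_weights)
        if move == "none":
            trace.add(step, cur_obj, False, move)
            break
        prop_obj = objective(prop)
        delta = prop_obj - cur_obj
        accept = delta <= 0 or (
            not greedy and rng.random() < math.exp(-delta / T)
        )
        if accept:
            cur, cur_obj = prop, prop_obj
            if validate_each:
                validate_state(cur)
            if cur_obj < best_obj - 1e-12:
                best, best_obj, best_step = cur.copy(), cur_obj, step
                since_best = 0
            else:
                since_best += 1
        else:
            since_best += 1
        trace.add(step, cur_obj, accept, move)
        T *= cooling
        if patience and since_best >= patience:
            trace.stopped_early = True
            break
    trace.best_objective = best_obj
    trace.best_step = best_step
    return best, trace


def optimize_defect(
    state: SequenceState,
    model=None,
    foldm: BasePairEnergyModel = DEFAULT_MODEL,
    cfg: OptimizerConfig = OptimizerConfig(),
    pk_credit: float = 1.0,
    rng: np.random.Generator | None = None,
    validate_each: bool = False,
) -> tuple[SequenceState, OptimizationTrace]:
    """Stage 1: minimize the ensemble defect of the candidate."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)

    def objective(s: SequenceState) -> float:
        seq, ts = s.concretize()
        return ensemble_defect(seq, ts, foldm, pk_credit=pk_credit)

    return _metropolis(
        state, objective, cfg.steps_stage1, cfg.temperature_stage1,
        cfg.cooling, cfg.patience, cfg.move_weights, cfg.greedy, rng,
        validate_each,
    )


def optimize_probability(
    state: SequenceState,
    model=None,
    foldm: BasePairEnergyModel = DEFAULT_MODEL,
    cfg: OptimizerConfig = OptimizerConfig(),
    rng: np.random.Generator | None = None,
    validate_each: bool = False,
) -> tuple[SequenceState, OptimizationTrace]:
    """Stage 2: maximize the Boltzmann probability of the exact target."""
    rng = rng if rng is not None else np.random.default_rng(cfg.seed)

    def objective(s: SequenceState) -> float:
        seq, ts = s.concretize()
        return -target_probability(seq, ts, foldm)

    best, trace = _metropolis(
        state, objective, cfg.steps_stage2, cfg.temperature_stage2,
        cfg.cooling, cfg.patience, cfg.move_weights, cfg.greedy, rng,
        validate_each,
    )
    return best, trace


def design(
    model,
    sampler_cfg: SamplerConfig = SamplerConfig(),
    opt_cfg: OptimizerConfig = OptimizerConfig(),
    foldm: BasePairEnergyModel = DEFAULT_MODEL,
    pk_credit: float = 1.0,
    thresholds=None,
    min_thread: int = 4,
    validate_each: bool = False,
) -> list:
    """Full pipeline: sample -> defect stage -> probability stage -> evaluate.

    Returns DesignCandidates sorted by (target probability desc, defect
    asc); candidate ids record their position in the sorted list, the
    ``provenance`` dict the seeds and configs.
    """
    from .evaluation import evaluate_candidate

    ss = np.random.SeedSequence(opt_cfg.seed)
    child_seeds = ss.spawn(sampler_cfg.n_samples + 1)
    rng_sample = np.random.default_rng(child_seeds[0])
    states = sample(model, sampler_cfg, foldm, rng=rng_sample)
    candidates = []
    for idx, st in enumerate(states):
        rng = np.random.default_rng(child_seeds[idx + 1])
        st1, tr1 = optimize_defect(
            st, model, foldm, cfg=opt_cfg, pk_credit=pk_credit, rng=rng,
            validate_each=validate_each,
        )
        st2, tr2 = optimize_probability(
            st1, model, foldm, cfg=opt_cfg, rng=rng,
            validate_each=validate_each,
        )
        seq, ts = st2.concretize()
        cand = evaluate_candidate(
            seq, ts, foldm, thresholds=thresholds, pk_credit=pk_credit,
            min_thread=min_thread,
        )
        cand.provenance = {
            "sample_index": idx,
            "seed": opt_cfg.seed,
            "sampler": sampler_cfg,
            "optimizer": opt_cfg,
            "stage1_best": tr1.best_objective,
            "stage2_best": tr2.best_objective,
        }
        cand.state = st2
        candidates.append(cand)
    candidates.sort(key=lambda c: (-c.target_probability, c.defect))
    for rank, cand in enumerate(candidates, start=1):
        cand.id = f"cand{rank:03d}"
    return candidates
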