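"""Monte Carlo move proposal, Metropolis stages, and the design pipeline."""

import numpy as np
import pytest

import xrdesign as xd
from xrdesign.model_io import ElementSpec, SymbolicModel


def fully_fixed_model():
    return SymbolicModel(
        elements=[
            ElementSpec("Ha", "helix", 2, 2, "Hb", conserved_mask=["G", "G"]),
            ElementSpec("L", "loop", 3, 3, conserved_mask=list("AAA")),
            ElementSpec("Hb", "helix", 2, 2, "Ha", conserved_mask=["C", "C"]),
        ],
    )


class TestProposeMove:
    def test_no_legal_move_flagged(self):
        m = fully_fixed_model()
        st = xd.sample(m, xd.SamplerConfig(n_samples=1, seed=0))[0]
        new, kind = xd.propose_move(st, np.random.default_rng(0))
        assert kind == "none"
        assert new.concretize()[0] == st.concretize()[0]

    def test_single_free_pair_proposals(self, toys):
        st = xd.sample(toys["single_pair"], xd.SamplerConfig(n_samples=1, seed=0))[0]
        start = st.concretize()[0]
        rng = np.random.default_rng(1)
        seen = set()
        for _ in range(200):
            new, kind = xd.propose_move(st, rng)
            assert kind == "mutate"
            seq = new.concretize()[0]
            assert seq != start
            seen.add(seq[0] + seq[4])
            xd.validate_state(new)
        # all five alternative canonical pairs reachable in one move
        assert len(seen) == 5

    def test_variable_loop_at_max_only_shrinks(self, toys):
        m = toys["var_loop_hairpin"]
        st = xd.SequenceState(
            m, {"Ha": 3, "L": 7},
            {"Ha": list("GGG"), "L": list("AAAAAAA"), "Hb": list("CCC")},
        )
        rng = np.random.default_rng(2)
        for _ in range(100):
            new, kind = xd.propose_move(st, rng, move_weights=(0.0, 1.0))
            assert kind == "shrink"
            assert new.length_of("L") == 6

    def test_moves_preserve_constraints(self, toys):
        st = xd.sample(toys["mini_xr"], xd.SamplerConfig(n_samples=1, seed=5))[0]
        rng = np.random.default_rng(5)
        for _ in range(100):
            st, kind = xd.propose_move(st, rng)
            xd.validate_state(st)


class TestStages:
    def test_zero_steps_identity(self, toys):
        st = xd.sample(toys["hairpin"], xd.SamplerConfig(n_samples=1, seed=0))[0]
        cfg = xd.OptimizerConfig(steps_stage1=0, steps_stage2=0)
        best, trace = xd.optimize_defect(st, cfg=cfg)
        assert best.concretize()[0] == st.concretize()[0]
        assert trace.records == []

    def test_best_defect_not_worse_than_initial(self, toys):
        st = xd.sample(toys["hairpin"], xd.SamplerConfig(n_samples=1, seed=7))[0]
        seq, ts = st.concretize()
        d0 = xd.ensemble_defect(seq, ts)
        best, trace = xd.optimize_defect(
            st, cfg=xd.OptimizerConfig(steps_stage1=400, patience=200, seed=7)
        )
        assert trace.best_objective <= d0 + 1e-12

    def test_best_so_far_probability_monotone(self, toys):
        st = xd.sample(toys["hairpin"], xd.SamplerConfig(n_samples=1, seed=3))[0]
        _, trace = xd.optimize_probability(
            st, cfg=xd.OptimizerConfig(steps_stage2=400, patience=400, seed=3)
        )
        best = -np.inf
        for _, obj, accepted, _ in trace.records:
            if accepted:
                best = max(best, -obj)
        assert best == pytest.approx(
            -trace.best_objective if trace.best_objective != np.inf else best
        )

    def test_identical_seed_identical_traces(self, toys):
        st = xd.sample(toys["hairpin"], xd.SamplerConfig(n_samples=1, seed=4))[0]
        cfg = xd.OptimizerConfig(steps_stage1=300, patience=300, seed=11)
        _, t1 = xd.optimize_defect(st, cfg=cfg)
        _, t2 = xd.optimize_defect(st, cfg=cfg)
        assert t1.records == t2.records

    def test_intermediate_states_always_valid(self, toys):
        st = xd.sample(toys["mini_pk"], xd.SamplerConfig(n_samples=1, seed=1))[0]
        cfg = xd.OptimizerConfig(steps_stage1=150, patience=150, seed=1)
        xd.optimize_defect(st, cfg=cfg, validate_each=True)  # raises on violation


class TestOptimality:
    def test_single_pair_probability_optimum(self, toys):
        """The optimum assigns the strongest (G-C) pair: p = e^3/(1+e^3)."""
        import math

        target = math.exp(3) / (1 + math.exp(3))
        hits = 0
        for seed in range(20):
            st = xd.sample(
                toys["single_pair"], xd.SamplerConfig(n_samples=1, seed=seed)
            )[0]
            _, tr = xd.optimize_probability(
                st, cfg=xd.OptimizerConfig(steps_stage2=200, patience=100, seed=seed)
            )
            if -tr.best_objective >= target - 1e-9:
                hits += 1
        assert hits >= 19

    def test_two_stage_at_least_as_reliable_as_single_stage(
        self, toys, hairpin_optima
    ):
        """Regression guard for the convergence claim: with equal stage-2
        budgets, the two-stage pipeline reaches the enumerated optimum at
        least as often as probability-only optimization."""
        _, pmax = hairpin_optima
        hp = toys["hairpin"]
        cfg = xd.OptimizerConfig(
            steps_stage1=1500, steps_stage2=1500, patience=500
        )
        two = single = 0
        for seed in range(15):
            st = xd.sample(
                hp, xd.SamplerConfig(n_samples=1, seed=seed, alpha_length=0.0)
            )[0]
            rng = np.random.default_rng(seed)
            s1, _ = xd.optimize_defect(st, cfg=cfg, rng=rng)
            _, t2 = xd.optimize_probability(s1, cfg=cfg, rng=rng)
            two += -t2.best_objective >= pmax - 1e-9
            rng = np.random.default_rng(seed)
            _, tb = xd.optimize_probability(st, cfg=cfg, rng=rng)
            single += -tb.best_objective >= pmax - 1e-9
        assert two >= single


class TestDesignPipeline:
    def test_seeded_pipeline_deterministic(self, toys):
        scfg = xd.SamplerConfig(n_samples=2, seed=6)
        ocfg = xd.OptimizerConfig(steps_stage1=100, steps_stage2=100,
                                  patience=100, seed=6)
        a = xd.design(toys["mini_pk"], scfg, ocfg)
        b = xd.design(toys["mini_pk"], scfg, ocfg)
        assert [c.sequence for c in a] == [c.sequence for c in b]
        assert [c.defect for c in a] == [c.defect for c in b]

    def test_default_model_candidates_valid_and_ring_closed(self, default_model):
        scfg = xd.SamplerConfig(n_samples=4, seed=13)
        ocfg = xd.OptimizerConfig(steps_stage1=120, steps_stage2=120,
                                  patience=120, seed=13)
        cands = xd.design(default_model, scfg, ocfg, validate_each=False)
        assert len(cands) == 4
        for c in cands:
            xd.validate_state(c.state)
            assert c.topology.ring_closed
        probs = [c.target_probability for c in cands]
        assert probs == sorted(probs, reverse=True)

    def test_denovo_model_junction_gc_enriched(self):
        """With the relaxed model, junction pairs are G-C enriched relative
        to unbiased/energy-free sampling."""
        m = xd.denovo_mbf_model()

        def gc_fraction(cfg):
            total = gc = 0
            for st in xd.sample(m, cfg):
                for grp in ("P1a", "P2a", "P3a"):
                    L = st.length_of(grp)
                    a = st.letters_by_element[grp]
                    b = st.letters_by_element[st.model.element(grp).partner]
                    for k in range(L):
                        total += 1
                        gc += (a[k], b[L - 1 - k]) in {("G", "C"), ("C", "G")}
            return gc / total

        rich = gc_fraction(xd.SamplerConfig(n_samples=40, seed=21))
        flat = gc_fraction(
            xd.SamplerConfig(n_samples=40, seed=21, beta_energy=0.0, gc_bias=1.0)
        )
        assert rich > flat + 0.1
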