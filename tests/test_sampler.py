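"""Constraint compilation and exactness of Boltzmann sequence sampling."""

import math
from collections import Counter

import numpy as np
import pytest
import scipy.stats

import xrdesign as xd
from xrdesign.model_io import ElementSpec, SymbolicModel

#: pair-energy table re-declared here so expected weights are computed
#: independently of the package's folding module
E = {
    ("G", "C"): -3.0, ("C", "G"): -3.0,
    ("A", "U"): -2.0, ("U", "A"): -2.0,
    ("G", "U"): -1.0, ("U", "G"): -1.0,
}


def single_pair_key(state):
    seq, _ = state.concretize()
    return seq[0] + seq[4]


class TestBuildConstraints:
    def test_partner_forced_by_mask(self):
        m = SymbolicModel(
            elements=[
                ElementSpec("Ha", "helix", 2, 2, "Hb", conserved_mask=["G", "C"]),
                ElementSpec("L", "loop", 3, 3, conserved_mask=list("AAA")),
                ElementSpec("Hb", "helix", 2, 2, "Ha"),
            ],
        )
        cons = xd.build_constraints(m)
        # pair 0: G with Hb mask open -> {C, U}; pair 1: C -> {G}
        assert set(cons.pair_choices[("Ha", 0)]) == {("G", "C"), ("G", "U")}
        assert cons.pair_choices[("Ha", 1)] == [("C", "G")]

    def test_variable_helix_strands_share_length_group(self, toys):
        hp = toys["hairpin"]
        groups = dict(
            (key, members) for key, members, _, _ in hp.length_groups()
        )
        assert groups["Ha"] == ("Ha", "Hb")

    def test_conserved_contradiction_detected(self):
        m = SymbolicModel(
            elements=[
                ElementSpec("Ha", "helix", 1, 1, "Hb", conserved_mask=["A"]),
                ElementSpec("L", "loop", 3, 3, conserved_mask=list("AAA")),
                ElementSpec("Hb", "helix", 1, 1, "Ha", conserved_mask=["C"]),
            ],
        )
        with pytest.raises(xd.ModelError, match="contradict"):
            xd.build_constraints(m)


class TestSample:
    def test_fully_constrained_model_unique_sequence(self):
        m = SymbolicModel(
            elements=[
                ElementSpec("Ha", "helix", 2, 2, "Hb", conserved_mask=["G", "G"]),
                ElementSpec("L", "loop", 3, 3, conserved_mask=list("AAA")),
                ElementSpec("Hb", "helix", 2, 2, "Ha", conserved_mask=["C", "C"]),
            ],
        )
        states = xd.sample(m, xd.SamplerConfig(n_samples=5, seed=0))
        seqs = {s.concretize()[0] for s in states}
        assert seqs == {"GGAAACC"}

    def test_zero_samples_rejected(self, toys):
        with pytest.raises(Exception):
            xd.sample(toys["single_pair"], xd.SamplerConfig(n_samples=0, seed=0))

    def test_seeded_runs_bit_reproducible(self, toys):
        cfg = xd.SamplerConfig(n_samples=8, seed=42)
        a = [s.concretize()[0] for s in xd.sample(toys["hairpin"], cfg)]
        b = [s.concretize()[0] for s in xd.sample(toys["hairpin"], cfg)]
        assert a == b

    def test_all_samples_satisfy_constraints_default_model(self, default_model):
        states = xd.sample(
            default_model, xd.SamplerConfig(n_samples=10, seed=9)
        )
        for s in states:
            xd.validate_state(s)  # independent validator

    def test_single_pair_uniform_at_zero_beta(self, toys):
        """With no energy or length weight, the six pairable assignments
        are equiprobable (chi-square over 6000 draws)."""
        cfg = xd.SamplerConfig(
            beta_energy=0.0, alpha_length=0.0, n_samples=6000, seed=0
        )
        states = xd.sample(toys["single_pair"], cfg)
        counts = Counter(single_pair_key(s) for s in states)
        assert set(counts) == set("".join(p) for p in E)
        chi = scipy.stats.chisquare(list(counts.values()))
        assert chi.pvalue > 1e-3

    def test_single_pair_boltzmann_at_unit_beta(self, toys):
        """With beta_energy=1, assignments follow weights exp(3), exp(3),
        exp(2), exp(2), exp(1), exp(1) (enumerated independently)."""
        cfg = xd.SamplerConfig(
            beta_energy=1.0, alpha_length=0.0, n_samples=6000, seed=1
        )
        states = xd.sample(toys["single_pair"], cfg)
        counts = Counter(single_pair_key(s) for s in states)
        keys = sorted("".join(p) for p in E)
        w = np.array([math.exp(-E[(k[0], k[1])]) for k in keys])
        expected = 6000 * w / w.sum()
        observed = np.array([counts.get(k, 0) for k in keys])
        chi = scipy.stats.chisquare(observed, expected)
        assert chi.pvalue > 1e-3

    def test_length_weight_monotone_decay(self, toys):
        """With alpha_length > 0 on a symmetric variable-loop toy, length
        frequency decays monotonically with |len - mean|."""
        m = toys["var_loop_hairpin"]
        cfg = xd.SamplerConfig(
            beta_energy=0.0, alpha_length=1.0, n_samples=4000, seed=2
        )
        counts = Counter(s.total_length for s in xd.sample(m, cfg))
        by_dev = {}
        for length, c in counts.items():
            by_dev.setdefault(abs(length - m.mean_length), []).append(c)
        devs = sorted(by_dev)
        means = [np.mean(by_dev[d]) for d in devs]
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_gc_bias_enriches_gc_pairs(self):
        m = SymbolicModel(
            elements=[
                ElementSpec("Ha", "helix", 1, 1, "Hb", gc_favored=True),
                ElementSpec("L", "loop", 3, 3, conserved_mask=list("AAA")),
                ElementSpec("Hb", "helix", 1, 1, "Ha", gc_favored=True),
            ],
        )
        base = xd.SamplerConfig(
            beta_energy=0.0, alpha_length=0.0, n_samples=4000, seed=3,
            gc_bias=1.0,
        )
        biased = xd.SamplerConfig(
            beta_energy=0.0, alpha_length=0.0, n_samples=4000, seed=3,
            gc_bias=4.0,
        )
        def gc_frac(cfg):
            states = xd.sample(m, cfg)
            return np.mean(
                [single_pair_key(s) in ("GC", "CG") for s in states]
            )
        assert gc_frac(biased) > gc_frac(base) + 0.2


class TestConcretize:
    def test_gap_removal_and_remapping(self):
        m = SymbolicModel(
            elements=[
                ElementSpec("Ha", "helix", 1, 2, "Hb"),
                ElementSpec("L", "loop", 3, 3, conserved_mask=list("AAA")),
                ElementSpec("Hb", "helix", 1, 2, "Ha"),
            ],
        )
        state = xd.SequenceState(
            m, {"Ha": 1, "L": 3}, {"Ha": ["G"], "L": list("AAA"), "Hb": ["C"]}
        )
        assert state.letters == "G-AAA-C"
        seq, ts = state.concretize()
        assert seq == "GAAAC"
        assert ts.to_dotbracket() == "(...)"

    def test_no_gaps_identity(self, toys):
        state = xd.sample(toys["mini_xr"], xd.SamplerConfig(n_samples=1, seed=0))[0]
        assert "-" not in state.letters
        seq, ts = state.concretize()
        assert len(seq) == ts.length == state.total_length

    def test_fully_gapped_optional_element_absent(self, default_model):
        lens = {
            "S5": 4, "PK1a": 2, "J5": 1, "P1a": 3, "J12": 0, "P2a": 0,
            "L2": 3, "J23": 1, "P3a": 5, "L3a": 2, "PK2a": 5, "L3b": 0,
            "J31": 0, "J1pk": 2, "S3": 0,
        }
        ts = xd.instantiate_target(default_model, lens)
        assert "P2a" not in set(ts.element_of.values())


class TestEnumerationHelpers:
    def test_single_pair_state_count(self, toys):
        assert xd.count_states(toys["single_pair"]) == 6

    def test_enumeration_matches_count(self, toys):
        states = list(xd.enumerate_states(toys["single_pair"]))
        assert len(states) == 6
        seqs = {s.concretize()[0] for s in states}
        assert seqs == {"GAAAC", "CAAAG", "AAAAU", "UAAAA", "GAAAU", "UAAAG"}

    def test_mini_xr_enumerable(self, toys):
        assert xd.count_states(toys["mini_xr"]) <= 100_000
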