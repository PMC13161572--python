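"""Symbolic model definition, YAML round-trip, alignment derivation,
Pearson correlation, and pseudoknot perturbation."""

import numpy as np
import pytest
import scipy.stats
from hypothesis import given, settings, strategies as st

import xrdesign as xd
from xrdesign.model_io import ElementSpec, SymbolicModel


def minimal_hairpin_dict():
    return {
        "schema": "xrdesign-model/1",
        "name": "mini",
        "elements": [
            {"name": "Ha", "kind": "helix", "length": [3, 5], "partner": "Hb"},
            {"name": "L", "kind": "loop", "length": [3, 4]},
            {"name": "Hb", "kind": "helix", "length": [3, 5], "partner": "Ha"},
        ],
    }


class TestLoadValidate:
    def test_minimal_hairpin(self, tmp_path):
        import yaml

        p = tmp_path / "m.yaml"
        p.write_text(yaml.safe_dump(minimal_hairpin_dict()))
        m = xd.load_model(p)
        assert len(m.elements) == 3
        assert m.total_length_range == (9, 14)

    def test_asymmetric_partner(self, tmp_path):
        import yaml

        d = minimal_hairpin_dict()
        d["elements"][2]["partner"] = ""
        d["elements"][2]["kind"] = "loop"
        p = tmp_path / "bad.yaml"
        p.write_text(yaml.safe_dump(d))
        with pytest.raises(xd.ModelError, match="[Aa]symmetric partner"):
            xd.load_model(p)

    def test_inverted_range(self):
        with pytest.raises(xd.ModelError, match="inverted"):
            ElementSpec("L", "loop", 5, 3)

    def test_mask_length_must_match(self):
        with pytest.raises(xd.ModelError, match="mask length"):
            ElementSpec("L", "loop", 1, 3, conserved_mask=["A"])

    def test_builtin_default_mbf_facts(self):
        m = xd.load_builtin_model("default_mbf")
        pk2 = m.element("PK2a")
        assert (pk2.length_min, pk2.length_max) == (3, 8)
        p1 = m.element("P1a")
        assert p1.length_min == p1.length_max  # fully length-conserved
        assert all(len(a) == 1 for a in p1.conserved_mask)  # fully fixed
        assert all(len(a) == 1 for a in m.element("P1b").conserved_mask)
        assert m.element("P2a").length_min == 0  # P2 optional
        # negative P3/L3 length correlation encoded
        assert any(
            {c.element_a, c.element_b} == {"P3a", "L3a"} and c.rho < 0
            for c in m.correlations
        )

    def test_builtin_files_match_builders(self):
        assert xd.load_builtin_model("default_mbf").name == "default_mbf"
        from xrdesign.model_io import model_to_dict

        assert model_to_dict(xd.load_builtin_model("default_mbf")) == (
            model_to_dict(xd.default_mbf_model())
        )
        assert model_to_dict(xd.load_builtin_model("denovo_mbf")) == (
            model_to_dict(xd.denovo_mbf_model())
        )

    def test_denovo_model_relaxed(self):
        m = xd.denovo_mbf_model()
        # PK1 stays fully fixed, junction helices open but G-C favored
        assert all(len(a) == 1 for a in m.element("PK1a").conserved_mask)
        assert all(a == "ACGU" for a in m.element("P1a").conserved_mask)
        assert m.element("P1a").gc_favored

    def test_save_load_roundtrip(self, tmp_path, default_model):
        from xrdesign.model_io import model_to_dict

        p = tmp_path / "round.yaml"
        xd.save_model(default_model, p)
        assert model_to_dict(xd.load_model(p)) == model_to_dict(default_model)


class TestPearson:
    def test_perfect_anticorrelation(self):
        assert xd.pearson([1, 2, 3], [3, 2, 1]) == pytest.approx(-1.0)

    def test_perfect_correlation(self):
        assert xd.pearson([1, 2, 3], [2, 4, 6]) == pytest.approx(1.0)

    def test_zero_variance_error(self):
        with pytest.raises(xd.ModelError, match="zero variance"):
            xd.pearson([1, 1, 1], [1, 2, 3])

    def test_planted_bivariate_recovery(self):
        rng = np.random.default_rng(0)
        cov = [[1.0, -0.9], [-0.9, 1.0]]
        xy = rng.multivariate_normal([0, 0], cov, size=50)
        assert xd.pearson(xy[:, 0], xy[:, 1]) == pytest.approx(-0.9, abs=0.1)

    @given(st.integers(0, 10_000))
    @settings(max_examples=50, deadline=None)
    def test_agrees_with_scipy(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 30))
        x = rng.normal(size=n)
        y = rng.normal(size=n) + 0.5 * x
        expected = scipy.stats.pearsonr(x, y).statistic
        assert xd.pearson(x, y) == pytest.approx(expected, abs=1e-12)


def column_alignment(columns, element="L1"):
    """Alignment whose i-th column is the i-th string in ``columns``."""
    n = len(columns[0])
    rows = [
        (f"s{i}", "".join(col[i] for col in columns)) for i in range(n)
    ]
    annotation = [(1, len(columns), element)]
    return rows, annotation


class TestDeriveModel:
    def test_strict_conservation_threshold(self):
        col_fix = "A" * 19 + "G"          # 0.95 > 0.9 -> fixed
        col_open = "A" * 18 + "G" * 2     # exactly 0.90 -> open
        rows, ann = column_alignment([col_fix, col_open])
        m = xd.derive_model(rows, ann, threshold=0.9)
        mask = m.element("L1").conserved_mask
        assert mask[0] == "A"
        assert mask[1] == "ACGU"

    def test_gappy_columns_left_open(self):
        col = "A" * 8 + "-" * 12  # >50% gaps: variable region
        rows, ann = column_alignment([col])
        m = xd.derive_model(rows, ann, threshold=0.9)
        # only 8 of 20 sequences have the position; column stays open
        assert m.element("L1").conserved_mask[0] == "ACGU"
        assert m.element("L1").length_min == 0

    def test_unannotated_columns_rejected(self):
        rows, _ = column_alignment(["A" * 20, "C" * 20])
        with pytest.raises(xd.ModelError, match="unannotated"):
            xd.derive_model(rows, [(1, 1, "L1")])

    def test_empty_alignment_rejected(self):
        with pytest.raises(xd.ModelError, match="empty"):
            xd.derive_model([], [(1, 1, "L1")])

    def test_planted_correlation_sign_recovered(self):
        spec = xd.planted_mbf_spec(n_sequences=50, rho=-0.9, seed=0)
        rows, ann = xd.generate_alignment(spec)
        m = xd.derive_model(rows, ann)
        entry = [
            c for c in m.correlations
            if {c.element_a, c.element_b} & {"P3a", "P3b"}
            and "L3a" in (c.element_a, c.element_b)
        ]
        assert entry and entry[0].rho < 0
        # matches a direct Pearson computation on the realized lengths
        summ = xd.summarize_alignment(rows, ann)
        direct = xd.pearson(
            summ.element_lengths["P3a"], summ.element_lengths["L3a"]
        )
        assert entry[0].rho == pytest.approx(direct, abs=1e-12)

    def test_sampling_from_derived_model_stays_in_observed_ranges(self):
        spec = xd.planted_mbf_spec(n_sequences=40, rho=-0.9, seed=3)
        rows, ann = xd.generate_alignment(spec)
        m = xd.derive_model(rows, ann)
        summ = xd.summarize_alignment(rows, ann)
        states = xd.sample(m, xd.SamplerConfig(n_samples=5, seed=1))
        for stt in states:
            xd.validate_state(stt)
            for el in m.elements:
                L = stt.length_of(el.name)
                obs = summ.element_lengths[el.name]
                lo, hi = int(obs.min()), int(obs.max())
                if el.partner:  # strand ranges reconciled across partners
                    obs2 = summ.element_lengths[el.partner]
                    lo = max(lo, int(obs2.min()))
                    hi = min(hi, int(obs2.max()))
                assert lo <= L <= hi


class TestSummarizeAlignment:
    def test_frequencies_and_matrix_invariants(self):
        spec = xd.planted_mbf_spec(n_sequences=20, rho=-0.8, seed=5)
        rows, ann = xd.generate_alignment(spec)
        s = xd.summarize_alignment(rows, ann)
        assert s.n_sequences == 20
        sums = s.per_column_frequencies.sum(axis=1)
        assert np.allclose(sums, 1.0)
        mat = s.correlation_matrix.values
        finite = np.isfinite(mat)
        assert np.allclose(mat[finite], mat.T[finite])
        assert np.allclose(np.diag(mat), 1.0)


class TestPerturbPseudoknot:
    def test_remove_pairs_arithmetic(self, default_model):
        from conftest import pin_pk2

        m = pin_pk2(default_model, bp=5)
        w = xd.perturb_pseudoknot(m, "PK2a", "remove_pairs", k=2)
        for name in ("PK2a", "PK2b"):
            el = w.element(name)
            assert (el.length_min, el.length_max) == (3, 3)
            assert len(el.conserved_mask) == 3

    def test_remove_all_pairs_is_error(self, default_model):
        from conftest import pin_pk2

        m = pin_pk2(default_model, bp=5)
        with pytest.raises(xd.ModelError, match="delete"):
            xd.perturb_pseudoknot(m, "PK2a", "remove_pairs", k=5)

    def test_delete_zeroes_both_strands(self, default_model):
        d = xd.perturb_pseudoknot(default_model, "PK1a", "delete")
        for name in ("PK1a", "PK1b"):
            el = d.element(name)
            assert (el.length_min, el.length_max) == (0, 0)

    def test_delete_idempotent(self, default_model):
        from xrdesign.model_io import model_to_dict

        once = xd.perturb_pseudoknot(default_model, "PK2a", "delete")
        twice = xd.perturb_pseudoknot(once, "PK2a", "delete")
        d1, d2 = model_to_dict(once), model_to_dict(twice)
        d1.pop("name"), d2.pop("name")
        assert d1 == d2

    def test_remove_pairs_composable(self, default_model):
        from xrdesign.model_io import model_to_dict

        from conftest import pin_pk2

        m = pin_pk2(default_model, bp=5)
        a = xd.perturb_pseudoknot(
            xd.perturb_pseudoknot(m, "PK2a", "remove_pairs", k=1),
            "PK2a", "remove_pairs", k=1,
        )
        b = xd.perturb_pseudoknot(m, "PK2a", "remove_pairs", k=2)
        da, db = model_to_dict(a), model_to_dict(b)
        da.pop("name"), db.pop("name")
        assert da == db

    def test_non_pseudoknot_rejected(self, default_model):
        with pytest.raises(xd.ModelError, match="not a pseudoknot"):
            xd.perturb_pseudoknot(default_model, "P1a", "delete")
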