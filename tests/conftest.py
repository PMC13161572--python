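import numpy as np
import pytest

import xrdesign as xd


@pytest.fixture(scope="session")
def toys():
    return xd.toy_models()


@pytest.fixture(scope="session")
def default_model():
    return xd.default_mbf_model()


#: element lengths used to instantiate the default MBF model in tests
#: (L3a=3 keeps the P3 hairpin loop legal across the whole PK2
#: perturbation series, including full deletion)
DEFAULT_LENS = {
    "S5": 5, "PK1a": 2, "J5": 1, "P1a": 3, "J12": 0, "P2a": 2, "L2": 4,
    "J23": 1, "P3a": 5, "L3a": 3, "PK2a": 5, "L3b": 0, "J31": 0,
    "J1pk": 3, "S3": 1,
}


@pytest.fixture(scope="session")
def default_lens():
    return dict(DEFAULT_LENS)


def pin_pk2(model, bp=5):
    """Copy of ``model`` with PK2 fixed at ``bp`` base pairs, so the
    progressive-weakening series can remove pairs one at a time."""
    import copy

    m = copy.deepcopy(model)
    for name in ("PK2a", "PK2b"):
        el = m.element(name)
        el.length_min = el.length_max = bp
        el.conserved_mask = (
            el.conserved_mask[-bp:]
            if el.is_three_prime_strand
            else el.conserved_mask[:bp]
        )
    return xd.SymbolicModel(
        elements=m.elements,
        correlations=m.correlations,
        conservation_threshold=m.conservation_threshold,
        base_triples=m.base_triples,
        name=model.name + "_pk2pinned",
    )


@pytest.fixture(scope="session")
def hairpin_optima(toys):
    """Enumerated optimum defect and target probability of the hairpin toy.

    Exhaustive, independent of the optimizer: every valid assignment is
    folded and scored.
    """
    hp = toys["hairpin"]
    dmin, pmax = np.inf, 0.0
    for state in xd.enumerate_states(hp):
        seq, ts = state.concretize()
        ens = xd.partition_function(seq)
        dmin = min(dmin, xd.ensemble_defect(seq, ts, ensemble=ens))
        pmax = max(pmax, xd.target_probability(seq, ts))
    return dmin, pmax
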