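"""Synthetic data generators: planted alignments and enumerable toy models.

The planted-alignment generator emulates the inputs from which an xrRNA
family model is built — a set of representative sequences with variable
element lengths, conserved cores and correlated element lengths — with
every planted property known exactly, so model derivation can be tested
as a parameter-recovery problem.  The toy-model catalog provides
miniature symbolic models whose full sequence spaces are enumerable,
serving as exact oracles for the sampler and optimizer.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm

from .model_io import (
    BaseTriple,
    Correlation,
    ElementSpec,
    ModelError,
    NUCS,
    SymbolicModel,
    default_mbf_model,
)

_COMPLEMENT_CHOICES = {
    "A": ["U"],
    "U": ["A", "G"],
    "G": ["C", "U"],
    "C": ["G"],
}


class FixtureError(ValueError):
    pass


@dataclass
class PlantedAlignmentSpec:
    """Recipe for a synthetic annotated alignment with known ground truth.

    Lengths are drawn per element group from discretized uniforms over
    the model ranges, coupled through a Gaussian copula for the planted
    correlation pairs.  Conserved (single-letter-mask) positions carry
    the planted letter with probability ``conserved_identity``; an
    additional uniform ``mutation_rate`` noise is applied everywhere.
    """

    model: SymbolicModel
    n_sequences: int = 50
    planted_correlations: list = field(default_factory=list)  # (a, b, rho)
    #: probability a conserved (single-letter-mask) position carries the
    #: planted letter before mutation noise; the uniform mutation_rate is
    #: the primary noise source, so identity defaults to 1
    conserved_identity: float = 1.0
    mutation_rate: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_sequences < 2:
            raise FixtureError("need at least 2 sequences (correlations undefined)")
        if not 0 <= self.conserved_identity <= 1:
            raise FixtureError("conserved_identity must be in [0, 1]")
        if not 0 <= self.mutation_rate <= 1:
            raise FixtureError("mutation_rate must be in [0, 1]")
        for a, b, rho in self.planted_correlations:
            if abs(rho) > 1:
                raise FixtureError("|rho| must be <= 1")


def _copula_lengths(spec: PlantedAlignmentSpec, rng) -> dict:
    """Per-sequence element-group lengths with planted correlations."""
    model = spec.model
    groups = model.length_groups()
    keys = [g[0] for g in groups]
    gidx = {k: i for i, k in enumerate(keys)}
    cov = np.eye(len(keys))
    for a, b, rho in spec.planted_correlations:
        ia, ib = gidx[model.group_of(a)], gidx[model.group_of(b)]
        cov[ia, ib] = cov[ib, ia] = rho
    eig = np.linalg.eigvalsh(cov)
    if eig.min() < -1e-9:
        raise FixtureError("planted correlation matrix not positive semi-definite")
    cov += np.eye(len(keys)) * max(0.0, -eig.min() + 1e-12)
    z = rng.multivariate_normal(np.zeros(len(keys)), cov, size=spec.n_sequences,
                                method="cholesky")
    u = norm.cdf(z)
    lengths = {}
    for i, (key, _, lo, hi) in enumerate(groups):
        k = hi - lo + 1
        lengths[key] = np.clip((lo + np.floor(u[:, i] * k)).astype(int), lo, hi)
    return lengths


def _sample_letters(el: ElementSpec, mask_idx: int, rng,
                    identity: float) -> str:
    allowed = el.allowed(mask_idx)
    if len(allowed) == 1 and rng.random() < identity:
        return allowed
    if len(allowed) == 1:  # planted "mutation" away from the conserved letter
        others = [c for c in NUCS if c != allowed]
        return others[rng.integers(3)]
    return allowed[rng.integers(len(allowed))]


def generate_alignment(spec: PlantedAlignmentSpec):
    """Generate a gapped, element-annotated alignment.

    Returns ``(rows, annotation)`` where ``rows`` is a list of
    ``(id, aligned_sequence)`` and ``annotation`` a list of
    ``(col_start, col_end, element)`` 1-based inclusive ranges.  Gaps
    follow the canonical placement (3' end of 5'/unpaired elements,
    5' end of partner strands), so alignment columns line up with model
    mask indices.  Seed-deterministic.
    """
    model = spec.model
    rng = np.random.default_rng(spec.seed)
    glens = _copula_lengths(spec, rng)

    annotation = []
    col = 1
    for el in model.elements:
        annotation.append((col, col + el.length_max - 1, el.name))
        col += el.length_max

    rows = []
    for s in range(spec.n_sequences):
        lens = {el.name: int(glens[model.group_of(el.name)][s])
                for el in model.elements}
        letters: dict = {}
        for el in model.elements:
            if el.is_paired and el.is_three_prime_strand:
                continue
            L = lens[el.name]
            if el.is_paired:
                mate = model.element(el.partner)
                a_body, b_body = [""] * L, [""] * L
                for k in range(L):
                    a = _sample_letters(el, k, rng, spec.conserved_identity)
                    b_mask = mate.allowed(mate.length_max - 1 - k)
                    comp = [c for c in _COMPLEMENT_CHOICES[a] if c in b_mask]
                    b = (
                        comp[rng.integers(len(comp))]
                        if comp
                        else b_mask[rng.integers(len(b_mask))]
                    )
                    a_body[k] = a
                    b_body[L - 1 - k] = b
                letters[el.name] = a_body
                letters[mate.name] = b_body
            else:
                letters[el.name] = [
                    _sample_letters(el, k, rng, spec.conserved_identity)
                    for k in range(L)
                ]
        # uniform mutation noise
        if spec.mutation_rate > 0:
            for name, body in letters.items():
                for k in range(len(body)):
                    if rng.random() < spec.mutation_rate:
                        others = [c for c in NUCS if c != body[k]]
                        body[k] = others[rng.integers(3)]
        aligned = []
        for el in model.elements:
            L = lens[el.name]
            body = "".join(letters[el.name])
            gaps = "-" * (el.length_max - L)
            aligned.append(gaps + body if el.is_three_prime_strand else body + gaps)
        rows.append((f"seq{s:03d}", "".join(aligned)))
    return rows, annotation


def write_alignment_fasta(rows, path) -> None:
    with open(path, "w") as fh:
        for name, seq in rows:
            fh.write(f">{name}\n{seq}\n")


def write_alignment_stockholm(rows, path) -> None:
    width = max(len(name) for name, _ in rows) + 2
    with open(path, "w") as fh:
        fh.write("# STOCKHOLM 1.0\n")
        for name, seq in rows:
            fh.write(f"{name:<{width}}{seq.replace('-', '.')}\n")
        fh.write("//\n")


def planted_mbf_spec(
    n_sequences: int = 50,
    rho: float = -0.9,
    mutation_rate: float = 0.01,
    seed: int = 0,
) -> PlantedAlignmentSpec:
    """MBF-like planting recipe: widened P3/L3 ranges (more length levels
    reduce discretization attenuation of the planted correlation) and
    the correlation window removed so the copula alone controls rho."""
    base = default_mbf_model()
    elements = []
    for el in base.elements:
        e = ElementSpec(
            name=el.name,
            kind=el.kind,
            length_min=el.length_min,
            length_max=el.length_max,
            partner=el.partner,
            conserved_mask=list(el.conserved_mask),
            gc_favored=el.gc_favored,
            pk_layer=el.pk_layer,
        )
        if el.name in ("P3a", "P3b"):
            e.length_max = 10
            e.conserved_mask = list(el.conserved_mask) + [NUCS] * 3
        if el.name == "L3a":
            e.length_max = 8
            e.conserved_mask = [NUCS] * 8
        elements.append(e)
    model = SymbolicModel(
        elements=elements,
        correlations=[],
        conservation_threshold=base.conservation_threshold,
        base_triples=base.base_triples,
        name="planted_mbf",
    )
    return PlantedAlignmentSpec(
        model=model,
        n_sequences=n_sequences,
        planted_correlations=[("P3a", "L3a", rho)],
        mutation_rate=mutation_rate,
        seed=seed,
    )


# ---------------------------------------------------------------------------
# Enumerable toy models
# ---------------------------------------------------------------------------

def _el(name, kind, lo, hi, partner="", mask="", gc=False, layer=0):
    return ElementSpec(
        name=name, kind=kind, length_min=lo, length_max=hi, partner=partner,
        conserved_mask=list(mask), gc_favored=gc, pk_layer=layer,
    )


def toy_models() -> dict:
    """Catalog of miniature symbolic models with enumerable state spaces.

    - ``single_pair``: one free base pair + fixed AAA loop (6 sequences);
    - ``hairpin``: 3-5 bp free helix + fixed AAA loop;
    - ``var_loop_hairpin``: fixed-content helix, loop length 3-7 (for
      length-weight checks);
    - ``mini_pk``: hairpin crossed by a 2-bp ring-closing pseudoknot;
    - ``mini_xr``: three-way junction + 1-bp PK1 + 2-bp PK2, 33 nt.
    """
    cat = {}
    cat["single_pair"] = SymbolicModel(
        elements=[
            _el("Ha", "helix", 1, 1, "Hb", "N"),
            _el("L", "loop", 3, 3, "", "AAA"),
            _el("Hb", "helix", 1, 1, "Ha", "N"),
        ],
        name="single_pair",
    )
    cat["hairpin"] = SymbolicModel(
        elements=[
            _el("Ha", "helix", 3, 5, "Hb", "NNNNN"),
            _el("L", "loop", 3, 3, "", "AAA"),
            _el("Hb", "helix", 3, 5, "Ha", "NNNNN"),
        ],
        name="hairpin",
    )
    cat["var_loop_hairpin"] = SymbolicModel(
        elements=[
            _el("Ha", "helix", 3, 3, "Hb", "GGG"),
            _el("L", "loop", 3, 7, "", "AAAAAAA"),
            _el("Hb", "helix", 3, 3, "Ha", "CCC"),
        ],
        mean_length=11.0,
        name="var_loop_hairpin",
    )
    cat["mini_pk"] = SymbolicModel(
        elements=[
            _el("S5", "linker", 4, 4, "", "AAAA"),
            _el("Ha", "helix", 3, 3, "Hb", "NNN"),
            _el("La", "loop", 1, 2, "", "AA"),
            _el("PK2a", "pseudoknot", 2, 2, "PK2b", "NN", layer=2),
            _el("Lb", "loop", 1, 2, "", "AA"),
            _el("Hb", "helix", 3, 3, "Ha", "NNN"),
            _el("J", "linker", 1, 1, "", "A"),
            _el("PK2b", "pseudoknot", 2, 2, "PK2a", "NN", layer=2),
        ],
        name="mini_pk",
    )
    cat["mini_xr"] = SymbolicModel(
        elements=[
            _el("S5", "linker", 4, 4, "", "AAAA"),
            _el("PK1a", "pseudoknot", 1, 1, "PK1b", "N", layer=1),
            _el("J5", "linker", 1, 1, "", "A"),
            _el("P1a", "helix", 2, 2, "P1b", "GC"),
            _el("P2a", "helix", 2, 2, "P2b", "GC"),
            _el("L2", "loop", 3, 3, "", "AAA"),
            _el("P2b", "helix", 2, 2, "P2a", "NN"),
            _el("J23", "linker", 1, 1, "", "A"),
            _el("P3a", "helix", 2, 2, "P3b", "NN"),
            _el("L3a", "loop", 1, 1, "", "A"),
            _el("PK2a", "pseudoknot", 2, 2, "PK2b", "NN", layer=2),
            _el("L3b", "loop", 1, 1, "", "A"),
            _el("P3b", "helix", 2, 2, "P3a", "NN"),
            _el("PK1b", "pseudoknot", 1, 1, "PK1a", "N", layer=1),
            _el("J31", "linker", 1, 1, "", "A"),
            _el("P1b", "helix", 2, 2, "P1a", "NN"),
            _el("J1pk", "linker", 2, 2, "", "AA"),
            _el("PK2b", "pseudoknot", 2, 2, "PK2a", "NN", layer=2),
            _el("S3", "linker", 1, 1, "", "A"),
        ],
        name="mini_xr",
    )
    return cat
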