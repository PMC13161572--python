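# Methods

## Scope and model class

`xrdesign` designs exoribonuclease-resistant RNAs (xrRNAs) of the
class-1, mosquito-borne-flavivirus type: a three-way junction (P1–P3)
with two pseudoknots, PK2 closing the protective ring around the
threaded 5′ end and PK1 stabilizing it. Everything is computed at the
secondary-structure-plus-pseudoknot level; 3D modelling, molecular
dynamics, and wet-lab validation are outside the package's scope. The
consequence is stated explicitly where it matters: ring closure is a
topological (crossing-rule) approximation of a 3D threading property,
and candidate filters rank designs rather than guarantee function.

## Symbolic family model

An xrRNA family is an ordered 5′→3′ list of elements. Paired elements
(helices, pseudoknot strands) appear as two entries with symmetric
`partner` references; the strand listed first is the 5′ strand. Each
element carries:

- a length range (bp for paired elements, nt otherwise; a minimum of 0
  marks optional elements such as P2);
- a conservation mask of allowed nucleotides per position, with length
  equal to `length_max`;
- optionally a `gc_favored` flag (a sampling bias, not a constraint)
  and, for pseudoknots, the layer (1 = PK1, 2 = PK2).

Variable lengths are realized by a canonical gap placement: trimmed
positions sit at the 3′ end of 5′/unpaired elements and at the 5′ end
of 3′ partner strands. This makes the letters-representation of every
concrete sequence unique (non-ambiguous sampling) and keeps mask
indices stable across lengths: pair *k* of a duplex always uses mask
index *k* of the 5′ strand and `length_max − 1 − k` of the 3′ strand.

Length correlations are pairwise constraints `(a, b, ρ, window)`
enforced as `|len_b − (slope·len_a + intercept)| ≤ window`. When a
model is derived from an alignment the line is the least-squares fit
through the observed joint lengths (window = max(1, 2·residual SD));
in hand-written models the line is derived from ρ and the ranges
assuming uniform marginals.

### Shipped defaults

The published facts pinned in the `default_mbf` model: P1 fixed at 3 bp
with fully fixed C/G composition; the junction-closing pairs of P1, P2
and P3 are C-G; P2 optional (0–3 bp); PK2 3–8 bp; PK1 fixed at 2 bp
with the junction-side strand fixed to "CU"; a strong negative P3/L3
length correlation (ρ = −0.9, window 1). Every other range and mask is
a package choice calibrated to give a ~54-nt family mean within a
34–74-nt total range; they live in `data/default_mbf.yaml` and can be
overridden freely. The `denovo_mbf` variant keeps the same architecture
and length constraints but fixes only PK1 and the base-triple
nucleotides, setting `gc_favored` on the junction helices instead of
hard C-G masks.

Base triples (BT1, BT2) are carried as position-triple annotations, not
as pairs, so the one-pair-per-position invariant of structures stays
testable.

## Model derivation from alignments

A column's nucleotide is fixed iff its frequency among non-gap
characters is **strictly** greater than the conservation threshold
(default 0.9); columns with more than 50% gaps belong to variable
regions and stay open. Element length ranges are the observed min/max
(partner strands reconciled by intersection); correlations are retained
when |ρ| exceeds a cutoff (default 0.5). Element kinds and partners are
inferred from a naming convention (`P3a`/`P3b`, `PK2a`/`PK2b`,
`*_5p`/`*_3p`) or supplied explicitly.

## Folding engine

The energy model is additive over canonical pairs (G-C −3, A-U −2,
G-U −1, arbitrary units; β = 1; minimum hairpin 3 nt) — the
conventional model of constraint-based RNA design, chosen deliberately
over nearest-neighbour parameters for speed and analytical
transparency. Consequences worth knowing:

- MFE structures are massively tie-degenerate (no stacking bonus), so
  the MFE is made deterministic by a fixed traceback (prefer leaving
  the interval's closing base unpaired; otherwise pair it with the
  leftmost admissible partner) and should be read as "one optimal
  structure", not "the" structure.
- Ensemble quantities (partition function, pair probabilities) are the
  robust objects; filters and the leader-interference guard are
  therefore ensemble-based.

The inside recursion runs in log space (`logaddexp`), so partition
functions of arbitrarily long sequences cannot overflow. The
outside/pair-probability pass is formulated directly on probability
ratios, each bounded by 1, and evaluated with linear-domain matrix
contractions per span (O(n³)–O(n⁴) work, BLAS-dominated; ~10 ms at
n = 60). Correctness of `Z`, every `p(i,j)` and the MFE energy is
pinned to an exhaustive enumeration oracle (all nested structures,
n ≤ 12, 1000 random sequences, agreement to 1e-9).

Pseudoknot pairs cannot enter a nested-structure ensemble. They
contribute (a) additively to the target energy used for sampling
weights, and (b) a complementarity credit in the ensemble defect:
`defect = n − Σ_{layer0} 2·p(i,j) − Σ_{unpaired} q(i) −
Σ_{PK pairs} 2·pk_credit·[pairable]`, with PK positions excluded from
the unpaired sum when credited. `pk_credit ∈ {0, 1}` exposes both
conventions (default 1); with 0, PK positions are scored like layer-0
unpaired positions. The defect uses the standard nucleotide-counting
(factor-2) form of ensemble defect.

For a pseudoknotted target the nested ensemble is intrinsically
frustrated: the PK2/PK1 strand pairs compete with the junction helices
inside the nested ensemble, so even well-optimized default-model
candidates plateau around a defect of ~0.35·n and exact-target
probabilities of 1e-7–1e-9 at ~40–55 nt. These numbers rank candidates;
they are not commensurate with defect values of pseudoknot-free
designs.

## Sampler

The sampling weight factorizes over (i) element lengths and (ii) pair /
unpaired-position contents given lengths. Sampling is therefore exact
in two stages: the element-length configuration space is enumerated
wholesale (vectorized; ~10⁶ configurations for the default model, with
masks for total-length range, correlation windows, and hairpin
feasibility — every present duplex must enclose ≥3 nt), a
configuration is drawn from the exact marginal, and contents are drawn
per pair slot / position from their categorical Boltzmann weights.
This is variable elimination in degenerate form; a model whose length
grid exceeds ~5·10⁶ configurations is rejected with advice to narrow
ranges. Distributional exactness is verified against full enumeration
(chi-square on toy models at 10⁴ draws).

Defaults: `beta_energy = 1`, `gc_bias = 2` (applied only at
`gc_favored` elements), `alpha_length = 3`. The length weight must
outweigh the per-position content entropy (≈2 nats/nt under this
energy model), otherwise sampled lengths drift to the top of the range;
α = 3 keeps default-model samples at the family mean (54 ± 1 nt).

## Optimizer

Two Metropolis stages: (1) ensemble-defect minimization, (2)
exact-target-probability maximization. Defaults: 3000 steps per stage,
temperatures 1.0 / 0.3, no cooling, patience 500 (early stop after that
many non-improving steps), move mix 3:1 point-mutations to gap-toggles,
optional greedy mode. Moves preserve the constraint set by
construction; gap toggles insert/remove positions only at the canonical
ends and re-check ranges, total length, correlation windows and hairpin
feasibility. Budgets were set so that the enumerable toy suite reaches
its exhaustively enumerated optima reliably (≥95/100 seeded runs) at
desk scale. On the toy suite the defect stage does not speed up the
probability stage (the toys are trivially optimizable), but it makes
convergence more dependable — stage-2-only runs occasionally stall in
local optima; the regression test guards exactly that reliability
property.

## Leader design

A degradation-assay substrate needs a 5′ leader: 25 nt, at least 4
unpaired 5′ positions in the leader's own MFE (XRN1 loading), and a
single helix of 3–5 bp. Leaders are built from an A-filler with one
G/C stem (`A⁴ Aᵖ Gʰ A-loop Cʰ Aᵗ`), which satisfies the hard
constraints by construction (verified by folding anyway). Structural
interference with the xrRNA is controlled at the ensemble level: under
the additive energy model any 25-nt extension can pair somewhere in the
xrRNA at zero cost, so the MFE pair set is not a stable reference;
instead the retention of the xrRNA's own pair probabilities in the
concatenated ensemble is computed, the best of 5 candidate geometries
is returned (early accept at retention 0.4), and retention below 0.1
is an error. Measured retention across seeds is 0.24–0.69.

## Quantification and stop points

Relative resistance of a lane: `r = product / (substrate −
unphosphorylated)` — the background correction accounts for incomplete
5′ phosphorylation — normalized so the wild-type lane is exactly 100%.
The measure is scale-invariant (property-tested). Stop-point
arithmetic: a stop position `s` (1-based, 5′-most nucleotide of the
resistant fragment, on the full leader+xrRNA substrate) gives a product
of `L − s + 1` nt; `stop_offset` reports the signed distance to PK1's
5′ strand (positive = upstream), the convention in which natural MBF
xrRNAs stop two positions upstream of PK1. The shipped
`stop_points_synthetic.tsv` is a synthetic stand-in reconstructed to be
consistent with the published substrate/product lengths of the two
validated synthetic constructs (85→61 nt, 83→63 nt).

## Synthetic data

The planted-alignment generator emulates a set of representative family
sequences: lengths drawn per element from discretized uniforms coupled
by a Gaussian copula (so a planted correlation ρ is controlled
exactly, up to discretization attenuation of a few percent), conserved
positions carrying their planted letter, paired strands complementary
by construction, and uniform per-position mutation noise on top. It
does **not** emulate phylogenetic structure, indel processes beyond the
canonical gap placement, covariation of unpaired regions, or realistic
base composition — so parameter-recovery tests demonstrate that the
derivation machinery is correct, not that it is robust to real
alignment pathologies. The toy-model catalog (single pair, 3–5 bp
hairpin, variable-loop hairpin, hairpin+pseudoknot, 33-nt mini
three-way junction with both PKs) keeps full state spaces below 10⁵ so
sampler and optimizer can be checked against exhaustive enumeration.

## Numerical and degenerate-input choices

- Probabilities are clipped to [0, 1] and the defect to [0, n] against
  1e-12-scale numerical residue; oracle agreement is asserted at 1e-9.
- Empty elements (length 0) simply vanish from concrete layouts;
  structures validate one-pair-per-position, nestedness of layer 0 and
  the 3-nt minimum hairpin for every pair, pseudoknots included.
- Deleting PK2 can make a previously valid length combination
  infeasible (the P3 loop may drop below the hairpin minimum); the
  sampler's grid masks such combinations out rather than producing
  invalid structures.
- All randomness flows from one integer seed per entry point
  (`numpy.random.SeedSequence` spawning); identical seed + config is
  bit-reproducible, and CLI runs write a manifest with the config hash.

## Known limitations

- The additive energy model has no stacking, loop penalties or
  coaxial terms; absolute defect/probability values are not comparable
  to nearest-neighbour-model numbers.
- Ring closure is a necessary-condition topology check, not a 3D
  verdict; candidates passing it still require structural validation.
- The exact sampler enumerates the length grid; models with many more
  variable elements than the shipped ones need coarser ranges.
- Filter thresholds (defect ≤ 0.15·n, probability floor 1e-12) are
  package defaults for ranking; the probability floor in particular is
  length-dependent by nature.
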