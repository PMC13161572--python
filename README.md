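# xrdesign

Mechanics-aware design of exoribonuclease-resistant RNAs (xrRNAs).

xrRNAs are structured RNA elements — best known from the 3′ UTR of
mosquito-borne flaviviruses — that stall the processive 5′→3′
exoribonuclease XRN1. Their function is mechanical rather than
catalytic: the RNA folds into a ring-like topology in which a pseudoknot
(PK2) closes a ring through which the molecule's own 5′ end is
threaded, so the enzyme cannot pull the strand through. A second
pseudoknot (PK1) and base triples stabilize the ring. `xrdesign` treats
the design of such elements as a constrained search over topologies: it
models the xrRNA family symbolically (variable-length elements with
conservation masks and length-correlation constraints), samples
sequences from a Boltzmann distribution under those constraints,
refines them by two-stage Monte Carlo optimization, and checks the
ring-closure topology that underlies exonuclease resistance. It also
implements the computational side of the validation assays:
5′-leader design, densitometric quantification of XRN1 resistance, and
stop-point/product-length arithmetic.

## The model

**Symbolic family model.** An xrRNA family is an ordered list of
elements (helices P1–P3 of the three-way junction, loops, linkers,
pseudoknots PK1/PK2), each with a length range, a per-position
conservation mask (a nucleotide is fixed iff observed in >90% of
non-gap characters of an alignment column), and partner references for
paired strands. Length correlations between elements (notably the
strong negative P3-stem / L3-loop correlation) are enforced as joint
windows around a regression line. Two models ship with the package:
`default_mbf` (consensus-constrained) and `denovo_mbf` (only PK1 and
base-triple nucleotides fixed; junction pairs merely *biased* toward
G-C).

**Sampling.** Each model position takes a value in {A, C, G, U, ε};
the empty letter ε lets lengths vary. Valid assignments are drawn
exactly from the Boltzmann distribution with weight

```
w(s) = exp(−β · E(s, target)) · exp(−α · |len(s) − mean_length|) · (GC bias terms)
```

where `E` is an additive base-pair energy (`e_GC = −3`, `e_AU = −2`,
`e_GU = −1` by default) over all target pairs, including pseudoknots.

**Folding.** A McCaskill-style partition function over the nested
(layer-0) structures gives `Z`, base-pair probabilities `p(i,j)` and
per-position unpaired probabilities `q(i)`; a Nussinov-style dynamic
program gives the MFE. From these the package computes the ensemble
defect `n − Σ_pairs 2·p(i,j) − Σ_unpaired q(i)` (pseudoknot pairs enter
as complementarity credits) and the Boltzmann probability
`exp(−β·E(target)) / Z` of the exact layer-0 target.

**Optimization.** Stage 1 minimizes the ensemble defect; stage 2
maximizes the exact-target probability. Moves are joint point mutations
(complementarity-preserving) and gap toggles that grow/shrink a
variable element — sequence length changes during optimization while
every intermediate state satisfies all constraints.

**Topology.** `check_ring_closure` is a 2D operationalization of the
ring: closed iff PK2 exists, some PK2 pair crosses the P1 helix set,
and ≥4 nt remain unpaired upstream of the first paired position (the
threaded 5′ end XRN1 would engage). It reproduces the perturbation
hierarchy: weakening PK2 keeps the ring closed while at least one pair
remains, deleting PK2 opens it, deleting PK1 only lowers the
stabilization flag.

## Worked example

```python
import xrdesign as xd

model = xd.default_mbf_model()
candidates = xd.design(
    model,
    xd.SamplerConfig(n_samples=3, seed=7),
    xd.OptimizerConfig(steps_stage1=800, steps_stage2=800, patience=300, seed=7),
)
best = candidates[0]
print(best.sequence)
print(best.structure.to_dotbracket())
leader = xd.design_leader(best.sequence, seed=1)
```

prints

```
AAUAAGAGCGGAGAGAGUGCGGCCGGCACCUACGCGGCGGA
....[[.(((......((((..{{{))))]].)))..}}}.
```

a 41-nt candidate whose extended dot-bracket shows the nested junction
helices (`()`), PK1 (`[]`) and PK2 (`{}`); its topology report is
ring-closed with 2 PK1 and 3 PK2 pairs, the ensemble defect is 16.77
and the exact-target probability 2.4e-08 (tiny in absolute terms — the
exact probability of any one structure decays exponentially with
length; it is used to *rank* candidates). The designed leader
`AAAAAAGGGGAAAACCCCAAAAAAA` is 25 nt, starts with ≥4 unpaired
positions and folds into a single 4-bp helix, giving a 66-nt substrate
for a degradation assay.

The same workflow is available from the shell:

```sh
xrdesign design --model default_mbf --n 10 --seed 7 --outdir run/
xrdesign quantify --lanes lanes.tsv --wt WT
xrdesign stoppoint --stops stops.tsv
```

Quantification follows the assay convention: the product/substrate
ratio is background-corrected by subtracting the non-phosphorylated
band, and the wild-type lane is set to 100%. A lane with half the
wild-type product at equal corrected substrate reports 50.0%; a stop
position of 25 on an 85-nt substrate converts to a 61-nt resistant
product.

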