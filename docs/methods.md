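# Methods

## The model

`pleurosim` implements an in-silico analysis of basidiocarp (fruit-body)
formation in *Pleurotus* (oyster mushroom): a curated multi-compartment
regulatory/kinetic model, automatic rate-law generation, stiff ODE
simulation with initial-condition scans, and directed-network topology
analysis of the bipartite species–reaction graph.

The curated model (`build_fruiting_model`) places 53 typed species —
11 genes, 11 mRNAs, 16 protein-class species (15 proteins plus the
PoWC1–FAD photoreceptor complex), 10 simple molecules, one membrane
receptor and 4 developmental phenotypes — in four compartments
(environment, fungal cell, mitochondria, substrate), wired by 39
irreversible reactions in six pathway arms:

* **differentiation** — OLYA6 → Pleurotolysin; Pleurotolysin binds a
  membrane receptor, triggering the vegetative→reproductive switch that
  feeds mycelium aggregation;
* **pinhead** — humidity-driven Fbh1 expression; hydrophobin catalyses
  the aggregation→pinhead conversion (re6) with the Pofst protein as
  inhibitor;
* **light signaling** — blue light drives PoWC1; PoWC1 + FAD form a
  complex (re37) that activates transcription of GAPDH, 6PGD and PEPCK;
* **respiration** — G6PD/PFK-driven PEP formation; PEP → TCA/ETC in the
  mitochondria yielding ATP with a reactive-oxygen byproduct; PEP + DAHP
  synthase → shikimic acid;
* **biosynthesis** — ATP-driven structural-protein assembly (re13,
  coupled to laccase and PAL1) catalysing pinhead → fruit-body
  development (re16); PAL1/PAL2-driven pigment formation amplified in
  the developing fruit body;
* **lignin degradation** — laccase (PoLac) acting on lignin in the
  substrate.

The source network diagram is not machine readable, so this wiring is a
**constrained reconstruction**: the arms above are fixed by the
described biology, the remainder (annotated "reconstruction filler":
enzyme/receptor turnover, transcript decay, cofactor consumption) is
curated against the published summary statistics, which act as a
checksum (below). Three species are deliberately isolated — the vmh3
vegetative-phase hydrophobin gene, its mRNA, and environmental oxygen —
reflecting elements that the network names but does not wire; their
identity is not inferable from the source and is a documented choice.

## Rate laws

Every reaction receives a symbolic law generated from structure alone
(`assign_rate_law` / `assign_all`), in the style of SBO-driven kinetics
generators:

    v = k · Π [Rᵢ]^{sᵢ} · Π [Eⱼ] · Π ([Aₐ]/(K_A + [Aₐ])) · Π (K_I/(K_I + [Iᵦ]))

(generalized mass action with saturating activator/inhibitor factors);
an optional Michaelis–Menten policy upgrades single-substrate catalysed
conversions to `v = V_max·[E]·[S]/(K_m+[S])`. All constants default to
1.0 in arbitrary units — no fitted values are published, so the
qualitative dose–response claims are the testable surface, not
parameter values. Laws are non-negative and bounded for non-negative
amounts, non-decreasing in substrates/catalysts/activators and
non-increasing in inhibitors (property-tested on 1000 random states).

## Simulation

State dynamics are `d[X]/dt = Σ_r s_rX · v_r` integrated with LSODA
(stiff-capable), rtol 1e-8 / atol 1e-10, over t ∈ [0, 10] arbitrary
time units with 200 output points (all overridable). Constant species
(blue light, humidity, oxygen) are boundary conditions. Amounts are
clipped at zero inside the right-hand side; excursions below −10·atol
abort with an error. Initial amounts follow the role scheme: genes 0.5,
mRNA 1.0, proteins and complexes 2.0, phenotypes 2.5, simple molecules
and receptors 0.5.

Developmental phenotypes act as *drivers* of the next stage (catalysts)
rather than consumed substrates, with one exception — mycelium
aggregation is consumed by the pinhead-conversion reaction, which is
how that step is described. This makes stage readouts accumulate, so a
terminal amount is a meaningful dose–response readout; the terminal
state is therefore a developmental trajectory endpoint, not a steady
state. Under this scheme the four qualitative claims hold strictly:
more hydrophobin → more pinheads; more Pofst → fewer pinheads; more
PoWC1 → more fruit-body development; more Pleurotolysin → at least as
much mycelium aggregation.

## Network analysis

`to_reaction_graph` maps a model to a directed bipartite graph (species
and reaction nodes; reactant→reaction, reaction→product,
modifier→reaction edges; species in no reaction are dropped, as network
exports omit unconnected elements). The topology suite is implemented
from first principles — BFS all-pairs distances, Brandes betweenness
with exact rational accumulation — and cross-checked in the test suite
against networkx and an independent Floyd–Warshall enumeration on 100+
random graphs. Conventions: path metrics (diameter, radius,
characteristic path length, reachable-pair count) are directed;
components, clustering, degree statistics and neighborhood connectivity
use the undirected skeleton; radius is the minimum eccentricity over
nodes that reach at least one other node; report values round half-up
to 2 decimals at presentation only.

## Reconstruction checksum and its two known gaps

`verify_fidelity` recomputes composition and topology from scratch
(including an internal brute-force oracle) and compares with the
published values. The reconstruction reproduces exactly: the
composition line (4 compartments / 53 species / 11 genes / 11 mRNA /
16 proteins / 39 reactions), 89 nodes, 90 edges, 2 weakly connected
components, clustering coefficient 0.00, diameter 18, radius 1, 747
reachable ordered pairs and 2.02 average neighbors. Two published
observations are *not* reproduced:

1. **Characteristic path length: 5.62 vs 5.63.** At exactly 747
   reachable pairs, printing 5.63 requires a total directed distance of
   4202–4209; the best mandate-respecting wiring reaches 4198. The gap
   is structural: every admissible extra reaction or edge adds
   reachable pairs whose distance contribution is bounded by its
   ancestor-closure size (a k-node closure contributes at most
   k(k+1)/2), and once the other seven metrics are pinned the remaining
   budget cannot supply the missing four distance units. An exhaustive
   search over arm variants, filler placements and edge micro-moves
   confirmed the ceiling.
2. **Reaction hubs.** re16 (pinhead → fruit body) has the highest
   betweenness among reaction nodes, as reported, and PoWC1 is among
   the top-3 protein hubs; but re6 and re37 rank just below the top
   three reaction hubs here (the TCA and assembly steps outrank them).
   Promoting re6 requires coupling respiratory output into the pinhead
   conversion, which adds ~40 reachable pairs and breaks the 747-pair
   checksum.

Both gaps are asserted honestly: the corresponding fidelity check and
acceptance tests fail, and `pleurosim verify` exits nonzero.

## Synthetic models

`generate_model` emulates the curated architecture without copying it:
per-gene transcription/translation chains, a pool of interconverting
molecules with seeded random cross-links, proteins attached as
catalysts or inhibitors, and phenotype sinks each fed by at least one
path. Defaults (11 genes, 8 molecules, 2 phenotypes, cross-link
probability 0.3, inhibitor fraction 0.25) mirror the curated model's
scale. Generation is a pure function of the config; no global random
state is touched. What the generator does *not* emulate: the curated
degree sequence, realistic kinetic constants, compartment-specific
chemistry — so passing tests on synthetic models demonstrate
correctness of the machinery, not biological realism.

## Numerical choices

* Solver LSODA; negative-state guard by clipping inside the RHS; a
  trajectory value below −10·atol is an error, smaller excursions clamp
  to zero.
* Betweenness accumulates shortest-path counts as `fractions.Fraction`,
  so tied path counts split exactly; normalization divides by
  (n−1)(n−2).
* Ties in hub rankings break lexicographically by node id, making every
  ranking deterministic.
* Graph metrics never use a graph library at run time; networkx appears
  only as a test oracle.

## Known limitations

* Kinetic constants are uncalibrated (all 1.0); simulated amounts are
  arbitrary units and only directions of effect are claims.
* The curated wiring is a reconstruction, not a transcription, of the
  source network; per-reaction literature roles are recorded in the
  reaction catalog, and filler reactions are explicitly annotated.
* SBML support covers the subset this package writes (no events, rules
  or unit definitions); unsupported constructs are rejected on read.
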