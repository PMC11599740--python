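# Methods

## The discrete model

`qualdyn` implements the Thomas (kinetic logic) framework. A regulatory
network is a signed, thresholded digraph over named entities; each entity
`v` has a declared maximum level `ℓ_v ≥ 1` (Boolean throughout the packaged
case study, multilevel supported by the engine). `ℓ_v` is a user field, not
derived from out-degree: tying the level range to the successor count would
contradict Boolean case studies in which entities with several targets still
range over {0, 1}. At most one interaction per ordered entity pair is
allowed, since the single `(sign, threshold)` annotation assumes it.

The resource set of `v` in state `E` collects regulators currently acting:
activators at/above threshold and inhibitors *below* threshold (the absence
of an inhibitor is a resource). The logical-parameter table `K_v(ω)` must be
complete — one entry per entity and resource subset; a predecessor-less
entity holds the single constant entry `K_v(∅)`.

Dynamics are **asynchronous and unitary**: in every state, each entity whose
level differs from `K_v(R_v(E))` yields one transition moving that entity
one unit toward the target. For Boolean models unitary and jump-to-target
semantics coincide; unitary is the package's choice for multilevel models.
All iteration orders (entities, states, exports) are fixed by entity order
and lexicographic state order, so every artifact is byte-reproducible. The
exhaustive state-graph builder refuses state spaces above a configurable cap
(default 10⁶) because `Z = Π(ℓ_v + 1)` grows exponentially.

Attractors are formalized as **terminal SCCs** of the state graph — the
standard reading of "stable states and sustained oscillations"; fixed points
are the singleton case with no outgoing transition.

## CTL checking and parameter identification

Formulas follow the dialect used in the wet-lab observation tables: atoms
`NAME = n` (with alias spellings such as `GLUT1`/`P53`/`BCAT`/`CMYC`
normalized to the canonical entity names), `!`, `&`, `|`, right-associative
`->`, the six unary temporal operators and both until forms. `&` binds
tighter than `|`, which binds tighter than `->`; the packaged formulas are
fully parenthesized so precedence never matters for the case study.

Satisfaction sets are computed by fixpoint labeling (EX by preimage, EF/EU
least fixpoints, EG greatest fixpoint, A-operators by duality). CTL
requires a total transition relation, so **fixed points receive an implicit
self-loop**; consequently a deadlock satisfies `AG φ` whenever it satisfies
`φ`, which is precisely how `EF(AG(...))` encodes "can settle into a stable
pattern". The default verdict mode for identification is *all states*
(formulas are implications, vacuously true off their antecedents); the mode
is configurable.

Parameter identification enumerates complete K tables and keeps those whose
state graph satisfies the specification. The raw space is pruned by
**steady-state propagation**: for each `AG(c)` subformula with `c` a
conjunction of atoms, any nonempty AG-closed region keeps the entities
named in `c` steady, so whenever an entity's resource set is identical in
every completion of `c`, the corresponding K entry is forced. The rule
assumes each AG target must be realized somewhere — true whenever the
specification's implications have satisfiable antecedents and are checked
in all-states mode — and surviving candidates are always re-verified
exactly, so propagation can only affect completeness, never soundness, of
the reported catalog. Catalogs are ordered lexicographically over the
flattened K vector, making the `M1…Mn` labels deterministic (they will not
match any externally published column order). Snoussi monotonicity
(`K` non-decreasing under resource-subset inclusion) and observability
(every edge changes some K value) are available as optional structural
filters and validators, **off by default** — see below.

## The HIF-1 case study

The canonical network (9 entities, 14 interactions, all Boolean, all
thresholds 1) is a reconstruction: the pathway wiring is reported in the
literature only as a drawing, so the edge list was assembled from the
described activations/inhibitions and the named feedback circuits, constrained to
exactly fourteen edges. A text-supported alternative reading
(`hif1_alt.json`, HIF-1→ERK in place of p53⊣HIF-1) ships alongside.

The packaged parameter set was selected deterministically: within the
subspace of tables forced by requiring (i) the pathogenic deadlock
`111110111` to be a fixed point, (ii) the twelve reference cycle states to
form a closed walk, and (iii) the recovery state `000001000` to be a fixed
point, the remaining eight free Boolean entries were enumerated
exhaustively, candidates were kept that satisfy all three observation
formulas, have fixed points exactly {deadlock, recovery}, leave every
reference bifurcation state outside all attractors with both fates reachable,
and make `100001100` a strict bifurcation state; the lexicographically
smallest survivor (of 68) was frozen as package data so downstream fixtures
stay stable regardless of later enumeration-option changes.

Two deliberate modeling facts deserve emphasis:

* **The model has two fixed points, not one.** The homeostasis observation
  formula `(c₂) ⇒ EF(AG(c₂))` with
  `c₂ = {VEGF=0, OGT=0, GLUT-1=0, HIF-1=0, AKT=1, p53=0}` *forces* a stable
  state carrying the c₂ labels: its antecedent is satisfiable, so some
  AG-closed region must exist; inside such a region the six constrained
  entities are steady by definition, and the three free ones (ERK,
  β-catenin, C-MYC) all have constant targets there (ERK's resource set is
  always ∅ because VEGF=0, β-catenin's is ∅ because AKT=1, C-MYC's depends
  only on β-catenin, which settles) — so every closed region contains a
  fully settled state, i.e. a fixed point with AKT=1. A model satisfying
  the observations therefore cannot have the pathogenic deadlock as its
  only fixed point; the package embraces the second fixed point as the
  homeostatic recovery state the observations describe.
* **Snoussi monotonicity fails for AKT by design**: the deadlock requires
  `K_AKT({VEGF}) = 0` while the stable recovery region requires
  `K_AKT(∅) = 1`. This is why the structural filters default to off; they
  remain available for synthetic models.

Betweenness centrality is directed, unweighted, unnormalized, with
endpoints excluded and unreachable pairs contributing zero (rankings are
invariant to the omitted normalization constant). On the packaged model the
twelve cycle states all have strictly positive centrality and their mean
exceeds the whole-graph mean (ranks 53–357 of 512); the package asserts
that computed property rather than any literal top-k membership. The
maximal-centrality *cycle* is defined as the simple cycle maximizing an
aggregate (mean by default; min/sum selectable) of member centralities
within a deterministic enumeration cap — "the most central cycle" has no
unique formalization, and the cap plus criterion make the choice explicit.
Maximal-centrality *paths* are restricted to shortest paths before the
centrality criterion is applied; unrestricted maximum-centrality paths are
ill-posed (they can wander arbitrarily). Bifurcation states are
non-attractor states with at least two successors whose reachable-attractor
sets differ; "recovery" attractors are those whose states all satisfy the
homeostatic-region labels of formula 2.

## ODE co-simulation

Each species follows `dx_i/dt = β_i f_i(x) − γ_i x_i` with Hill response
`H(x; θ, h) = xʰ/(xʰ + θʰ)` per edge. Two translations are provided:

* `product`: `f_i` multiplies `H` for activators and `1−H` for inhibitors —
  the direct sign-based reading, AND-like regulator integration (the
  conservative default for bare networks; configurable in spirit via mode).
* `logic` (default for parameterized models): multilinear interpolation of
  the K table with resource probabilities `p_u = H` (activator) or `1−H`
  (inhibitor): `f_i = Σ_ω K(ω)/ℓ_i Π_{u∈ω} p_u Π_{u∉ω} (1−p_u)`. This
  reproduces the discrete targets at saturation, including non-monotone
  rows such as AKT's — which the sign-product form cannot express; that is
  why logical-pattern concordance is checked in logic mode.

Integration uses LSODA (rtol 1e-8, atol 1e-10) with tiny negative solver
noise clipped at zero; equilibria are found by long relaxation followed by
Newton refinement and verified against a residual bound; sensitivities are
central finite differences of the equilibrium (or end-time) value,
reported in relative (logarithmic) units. Time units are abstract;
concentrations inherit the β/γ units (mM/L in the demo calibrations).

Six demo calibrations ship as data. All use β = γ = 1, θ = 0.5, h = 4
unless stated: `pathogenic` and `recovery` start near the corresponding
logical stable states (0.9/0.05 per coordinate) and are the basis of the
concordance check (equilibrium thresholded at each species' half-maximum
β/2γ reproduces the logical pattern); `demo_a` perturbs p53/β-catenin/AKT
with everything else at zero; `demo_b` is a VEGF/ERK/HIF-1 pulse with
faster VEGF clearance (γ_VEGF = 1.5) than ERK degradation (γ_ERK = 0.35),
calibrated so VEGF and HIF-1 rise then decay toward zero with final
VEGF < final ERK; `demo_c` hyperactivates ERK/GLUT-1 inside the pathogenic
basin (used for the positive GLUT-1-vs-β_ERK sensitivity check); `demo_d`
starts with ERK/GLUT-1 inhibited and relaxes to the homeostatic
equilibrium. Exact concentration traces reported for this pathway depend on
rate equations that are not part of the packaged model; the
demo calibrations target the qualitative shapes only, and no quantitative
concentration value is asserted anywhere.

## Synthetic data

The generator emulates the structural class of inputs the analysis assumes:
Erdős–Rényi-style signed digraphs with per-edge thresholds, a guaranteed
regulator for every entity (a random-signed self-input where needed — the
packaged case study also has every entity regulated), complete uniformly
sampled K tables, Snoussi-monotone tables by monotone completion (each K
drawn uniformly above the maximum over strict subsets), positive random
kinetics, and rejection-sampled networks free of positive circuits for the
multistationarity rule. All sampling is integer-based on seeded
`random.Random`, so output is platform-stable. What the generator does
*not* emulate: realistic degree distributions, hub structure, or
biologically curated sign patterns — passing synthetic sweeps demonstrates
algorithmic correctness on the assumed input class, not biological fidelity
of any particular random model.

## Verification strategy and problem sizes

Every nontrivial algorithm is cross-checked against an independent oracle
implemented with different machinery: the CTL labeler against explicit
path/lasso-search semantics on ≥200 random formulas over graphs of ≤16
states; betweenness against exhaustive enumeration of every shortest path
on 100 random digraphs of ≤12 nodes; the fixed-point scanner against the
rule that multistationarity needs a positive circuit (100 Snoussi-valid
circuit-free networks); the integrator against the closed form of the
unregulated species to 10⁻⁶ relative error. Sweep sizes were chosen to
exercise the space thoroughly while keeping the default suite fast
(seconds, not minutes). Exhaustive parameter enumeration for the full
nine-entity network (2²⁴ candidates after propagation) is supported through
the same API but is a long-running batch computation; the packaged
parameter set's membership in its own catalog is verified directly through
the propagation-consistency and exact-CTL checks instead.

## Known limitations

* Only unitary asynchronous semantics; no synchronous or priority-class
  updates, and no symbolic (BDD) state representation — the explicit cap
  bounds model size.
* CTL only: no fairness, CTL*, or LTL; no counterexample extraction
  (trajectory extraction lives in the analysis module instead).
* The canonical edge list is a documented reconstruction, not a published
  artifact; conclusions tied to edge-exact wiring should be re-checked
  against `hif1_alt.json`.
* The ODE stage is a generic qualitative translation; it is not a fitted
  kinetic model and its demo calibrations carry no quantitative authority.
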