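# qualdyn

Qualitative dynamics of biological regulatory networks: logical modeling in
the Thomas (kinetic logic) formalism, CTL-constrained identification of
logical parameters, asynchronous state-graph analysis (fixed points,
attractors, betweenness-centrality trajectories and bifurcation states), and
a Boolean-to-ODE co-simulation stage. The package ships a complete
nine-entity case study of the HIF-1/VEGF/GLUT-1 cancer-signaling network.

## The problem and who this is for

Hypoxia-inducible factor 1 (HIF-1) coordinates the cellular response to low
oxygen; its hyperactivation in tumors upregulates the glucose transporter
GLUT-1 and the angiogenic factor VEGF, driving the Warburg effect and cancer
progression. Kinetic rate constants for such signaling networks are rarely
known, so the network is modeled *qualitatively*: each entity takes discrete
expression levels (here Boolean 0/1) and the dynamics are fixed not by rate
laws but by **logical parameters**. The package is aimed at systems
biologists who want to build such models, identify parameters from observed
behaviors written in temporal logic, and interrogate the resulting state
space for stable states, oscillations and points of no return.

## The formalism

A **biological regulatory network** is a directed graph `G = (V, I)` whose
edges carry a sign (`+` activation, `-` inhibition) and an integer threshold
τ. In a qualitative state `E = (e_v1, …, e_vn)` the **resources** of entity
`v` are the regulators currently acting on it:

    R_v(E) = { u ∈ G⁻(v) :  (σ_uv = + and e_u ≥ τ_uv)
                         or (σ_uv = − and e_u < τ_uv) }

— an active activator, or an *absent* inhibitor. A complete table of
**logical parameters** `K_v(ω)` gives the level `v` is attracted toward
when its resource set is ω. Under asynchronous unitary dynamics, each entity
whose level differs from its target moves one unit toward it, one entity
per transition; the resulting **state graph** over all
`Z = Π_v (ℓ_v + 1)` states is the object every later stage analyzes:

* **fixed points** (deadlocks): states with no outgoing transition;
* **attractors**: terminal strongly connected components;
* **CTL model checking**: observed behaviors written in Computation Tree
  Logic (`EF`, `AG`, `E[· U ·]`, …) are evaluated by fixpoint labeling and
  used to *select* the parameter tables consistent with experiment
  (`qualdyn.enumeration`);
* **betweenness centrality** `BC(s) = Σ σ_uv(s)/σ_uv` over directed
  shortest paths ranks states, and drives extraction of the
  maximal-centrality cycle, maximal-centrality paths and bifurcation
  states (`qualdyn.analysis`);
* **ODE co-simulation**: `dx_i/dt = β_i f_i(x) − γ_i x_i` with Hill-shaped
  regulation functions translates a logical model to a continuous one for
  concentration-level exploration (`qualdyn.ode`).

## Worked example: the HIF-1 case study

```python
import qualdyn as q
from qualdyn import analysis, case_study, io

model = case_study.load_canonical_model()      # 9 entities, 14 interactions
graph = q.build_state_graph(model)
print("states:", len(graph.states))

for s in q.fixed_points(model):
    print("fixed point:", io.state_to_string(s))

for i, f in enumerate(case_study.load_ctl_formulas(model.network), start=1):
    print(f"observation formula {i} holds:", q.holds(graph, f))

cmap = analysis.betweenness_centrality(graph)
fx = case_study.load_fixtures()
cycle_bc = sum(cmap[s] for s in fx.cycle12) / 12
print(f"cycle mean betweenness: {cycle_bc:.1f} "
      f"(graph mean {sum(cmap.values())/512:.1f})")
```

prints

```
states: 512
fixed point: 000001000
fixed point: 111110111
observation formula 1 holds: True
observation formula 2 holds: True
observation formula 3 holds: True
cycle mean betweenness: 4674.1 (graph mean 4219.3)
```

States are digit strings in the entity order
`(HIF-1, ERK, VEGF, p53, β-catenin, AKT, GLUT-1, C-MYC, OGT)`. The model
has two stable states: the **pathogenic deadlock** `111110111` (every
entity on except AKT — sustained HIF-1/GLUT-1/OGT signaling, the Warburg
regime) and the **homeostatic recovery state** `000001000` (only the
survival kinase AKT on). Both are consequences of the temporal-logic
observations used to select the parameters: the homeostasis formula
logically forces the recovery state to be stable (see
`docs/methods.md`). Between the two lies a twelve-state cycle in which
p53, β-catenin and AKT stay active while all other entities oscillate —
the model's picture of healthy homeostasis — and seven reference bifurcation
states from which both fates are still reachable.

The same pipeline is available from the shell:

```
qualdyn reproduce --out report/          # re-check every packaged claim
qualdyn build-graph --model src/qualdyn/data/hif1.json --out g.graphml
qualdyn check-ctl  --model src/qualdyn/data/hif1.json --ctl src/qualdyn/data/observations.ctl
qualdyn simulate-ode --scenario demo_b --out ode/ --plot
```

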