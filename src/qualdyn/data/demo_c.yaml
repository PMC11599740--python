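edges:
- hill: 4.0
  source: AKT
  target: p53
  theta: 0.5
- hill: 4.0
  source: AKT
  target: β-catenin
  theta: 0.5
- hill: 4.0
  source: C-MYC
  target: VEGF
  theta: 0.5
- hill: 4.0
  source: ERK
  target: GLUT-1
  theta: 0.5
- hill: 4.0
  source: ERK
  target: HIF-1
  theta: 0.5
- hill: 4.0
  source: GLUT-1
  target: OGT
  theta: 0.5
- hill: 4.0
  source: HIF-1
  target: GLUT-1
  theta: 0.5
- hill: 4.0
  source: HIF-1
  target: VEGF
  theta: 0.5
- hill: 4.0
  source: OGT
  target: C-MYC
  theta: 0.5
- hill: 4.0
  source: VEGF
  target: AKT
  theta: 0.5
- hill: 4.0
  source: VEGF
  target: ERK
  theta: 0.5
- hill: 4.0
  source: p53
  target: HIF-1
  theta: 0.5
- hill: 4.0
  source: p53
  target: VEGF
  theta: 0.5
- hill: 4.0
  source: β-catenin
  target: C-MYC
  theta: 0.5
species:
  AKT:
    beta: 1.0
    gamma: 1.0
    x0: 0.05
  C-MYC:
    beta: 1.0
    gamma: 1.0
    x0: 0.8
  ERK:
    beta: 1.0
    gamma: 1.0
    x0: 0.9
  GLUT-1:
    beta: 1.0
    gamma: 1.0
    x0: 1.0
  HIF-1:
    beta: 1.0
    gamma: 1.0
    x0: 0.2
  OGT:
    beta: 1.0
    gamma: 1.0
    x0: 0.82
  VEGF:
    beta: 1.0
    gamma: 1.0
    x0: 0.88
  p53:
    beta: 1.0
    gamma: 1.0
    x0: 0.8
  β-catenin:
    beta: 1.0
    gamma: 1.0
    x0: 0.8
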