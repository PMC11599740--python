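{
 "entity_order": [
  "HIF-1",
  "ERK",
  "VEGF",
  "p53",
  "β-catenin",
  "AKT",
  "GLUT-1",
  "C-MYC",
  "OGT"
 ],
 "deadlock": "111110111",
 "recovery": "000001000",
 "cycle12": [
  "101111101",
  "001111101",
  "001111001",
  "011111001",
  "111111001",
  "110111001",
  "100111001",
  "100111011",
  "101111011",
  "101111010",
  "101111000",
  "101111100"
 ],
 "bifurcations": [
  "100001100",
  "001011000",
  "111011000",
  "001111001",
  "001111000",
  "001101000",
  "111101000"
 ],
 "trajectory_source": "101111001",
 "aggressive_state": "011011000"
}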