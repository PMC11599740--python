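# Temporal-logic encoding of the observed behaviors used for parameter
# identification (one formula per line).
# 1: the pathogenic pattern can settle into a stable state
((VEGF=1 & OGT=1 & GLUT1=1 & HIF-1=1 & AKT=0 & P53=1) -> EF(AG(VEGF=1 & OGT=1 & GLUT1=1 & HIF-1=1 & AKT=0 & P53=1)))
# 2: the homeostatic pattern can settle into a stable state
((VEGF=0 & OGT=0 & GLUT1=0 & HIF-1=0 & AKT=1 & P53=0) -> EF(AG(VEGF=0 & OGT=0 & GLUT1=0 & HIF-1=0 & AKT=1 & P53=0)))
# 3: with HIF-1 and VEGF suppressed but GLUT-1 active, the network can reach a fully glycolytic state
((VEGF=0 & HIF-1=0 & GLUT1=1 & AKT=1 & P53=1) -> EX(EF(VEGF=0 & GLUT1=1 & ERK=1 & OGT=1 & CMYC=1 & BCAT=1 & HIF-1=0 & AKT=1 & P53=1)))
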