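identifier	term
ALB	extracellular region
ALB	blood microparticle
COL1A1	collagen-containing extracellular matrix
COL1A1	collagen type I trimer
FN1	extracellular matrix
GAPDH	cytosol
GAPDH	nucleus
ACTB	cytoskeleton
P02452	collagen-containing extracellular matrix
KRT1	cornified envelope
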