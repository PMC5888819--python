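gene	subgroup	fold_change	direction
CACNB4	MSS	0.65	down
MAP3K6	MSS	0.66	down
CD14	MSS	0.66	down
CACNA2D4	MSS	0.66	down
MAP4K4	MSS	1.52	up
RPS6KA6	MSI	0.20	down
PLA2G4E	MSI	0.30	down
RASGFR1	MSI	0.39	down
PLA2G4C	MSI	0.47	down
MAPK8IP1	MSI	0.47	down
PDGFA	MSI	0.53	down
TGFBR2	MSI	0.61	down
DUSP7	MSI	1.57	up
HRAS	MSI	1.92	up
IL1B	MSI	2.06	up
PLA2G4A	MSI	2.70	up
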