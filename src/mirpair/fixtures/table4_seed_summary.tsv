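mirna	n_assoc	with_match	without_match
hsa-let-7i-5p	1	TGFBR1
hsa-miR-1203	1		TGFBR1
hsa-miR-1246	1		MYC
hsa-miR-145-5p	1	PDGFRA
hsa-miR-150-5p	7	PDGFRA;RASGRP3;PRKCB	RASGRP2;MEF2C;MAP4K1;RAC2
hsa-miR-17-5p	3	HSPA8;PDGFRA	MYC
hsa-miR-193b-3p	4	MEF2C;PDGFRB;DUSP4	IL1R
hsa-miR-195-5p	1		MEF2C
hsa-miR-196b-5p	1		DUSP4
hsa-miR-199a-3p	2	TGFBR1	PDGFRB
hsa-miR-199a-5p	2	TGFBR1	PDGFRB
hsa-miR-199b-5p	1		PDGFRB
hsa-miR-19b-3p	2	PDGFRA	MYC
hsa-miR-203a	5	MEF2C;PDGFRA;PRKCB	HSPA8;RAC2
hsa-miR-20a-5p	2	PDGFRA	MYC
hsa-miR-20b-5p	2	PDGFRA	MYC
hsa-miR-2117	1	TGFBR1
hsa-miR-214-3p	3	TGFBR1;PDGFRB;IL1R1
hsa-miR-21-5p	1	TGFBR1
hsa-miR-221-3p	2	HSPA8	MEF2C
hsa-miR-23a-3p	1		TGFBR1
hsa-miR-24-3p	1	TGFBR1
hsa-miR-29b-3p	2	PDGFRA	HSPA8
hsa-miR-331-3p	1	TGFBR1
hsa-miR-3651	1		MYC
hsa-miR-375	1		MYC
hsa-miR-424-3p	1		DUSP4
hsa-miR-429	1	RASGRP3
hsa-miR-501-3p	2	PDGFRA	MYC
hsa-miR-583	1		MYC
hsa-miR-6071	1	TGFBR1
hsa-miR-650	7	PDGFRA	RASGRP1;MEF2C;MAP4K1;RAC2;RASGRP3;PRKCB
hsa-miR-663a	1		MYC
hsa-miR-663b	1		MYC
hsa-miR-92a-3p	1		MYC
hsa-miR-934	1		PDGFRB
hsa-miR-93-5p	1	HSPA8
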