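protein_id	name	architecture	remark
CloalDRAFT_3068	ScaA	SIGN Coh1 Coh1 Coh1 Coh1 CBM3 Coh1 Coh1 Coh1 Coh1 Coh1 Coh1 XDoc2	Sequence homology
CloalDRAFT_3067	ScaB1	SIGN Coh2 Coh2 Coh2	Sequence homology, clustered on the genome following the scaA gene.
CloalDRAFT_3066	ScaB2	Coh1 Coh2 SLH	Sequence homology, clustered on the genome following the scaA gene.
CloalDRAFT_3065	ScaC	Coh2 SLH	Clustered on the genome with the scaA gene.
CloalDRAFT_3064	ScaD	SIGN Coh1 SLH	Single type I cohesin, clustered on the genome with the scaA gene.
CloalDRAFT_0628	ScaE	SIGN Coh2 Coh2 Coh2 Coh2	Similarity of Coh2 sequences with ScaE, lack of SLH
CloalDRAFT_3961	ScaF1	Coh2 SLH	Type II cohesin, SLH
CloalDRAFT_0629	ScaF2	SIGN UNK Coh2	High sequence homology to Ac-ScaF
CloalDRAFT_4206	ScaG	SIGN CSBM Coh1	Sequence homology, CSBM
CloalDRAFT_0457	ScaK	SIGN Coh2 Doc1	Sequence homology
CloalDRAFT_2910	ScaO1	Peptidase PPC Coh1 Doc1 Coh2 RhsA	Modular similarity to Ac-ScaO
CloalDRAFT_1780	ScaO2	SIGN Peptidase Coh2 Doc1 GalOx RhsA	Close sequence homology with Ac-ScaO cohesin
CloalDRAFT_3207	ScaP1	SIGN Doc1 Coh2 Peptidase FN3 WFA	Sequence homology
CloalDRAFT_1967	ScaP2	SIGN Peptidase Coh2 Peptidase XDoc2 GalOx RhsA UNK	Sequence homology, modular similarity to Ac-ScaP
CloalDRAFT_2305	ScaN1	SIGN Coh1 Coh1 Coh1 Doc1	High sequence homology to Ct-ScaA, but containing type I dockerin
CloalDRAFT_0274	ScaN2	SIGN Coh1 Coh1 Doc1	
CloalDRAFT_3567	ScaN3	SIGN Coh1 Coh1 Doc1	
CloalDRAFT_3500	ScaN4	SIGN Coh1 Coh1 Doc1	
CloalDRAFT_3290	ScaN5	Coh1 Coh1 Doc1	
CloalDRAFT_2020	ScaN6	SIGN Coh1 Coh1 Doc1	
CloalDRAFT_0656	ScaN7	SIGN Doc1 Coh1	
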