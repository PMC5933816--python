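subdomain	accession	general
RNase_HI_RT_Ty1	cd09272	RNase
RNase_HI_RT_Ty3	cd09274	RNase
RNase_HI_like	cd09279	RNase
RNase_HI_RT_DIRS1	cd09275	RNase
rve	pfam00665	Integrase
Retrotrans_gag	pfam03732	GAG
Retrotran_gag_2	pfam14223	GAG
Retrotran_gag_3	pfam14244	GAG
gag-asp_proteas	pfam13975	GAG
DUF1759	pfam03564	GAG
retropepsin_like	cd00303	AP
retropepsin_like_LTR_1	cd05481	AP
retropepsin_like_LTR_2	cd05484	AP
RP_Saci_like	cd06094	AP
RVP_2	pfam08284	AP
Peptidase_A17	pfam05380	AP
DUF1758	pfam05585	AP
RT_LTR	cd01647	RT
RT_pepA17	cd01644	RT
RVT_1	pfam00078	RT
RVT_2	pfam07727	RT
RVT_3	pfam13456	RT
RT_DIRS1	cd03714	RT
gag_pre-integrase	pfam13976	Pre-integrase
INT_Cre_C	cd00799	YR
DNA_BRE_C	cd00397	YR
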