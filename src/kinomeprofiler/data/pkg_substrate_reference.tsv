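peptide_id	uniprot_id	protein_name	p_value	pkg1_score	pkg2_score	localisation
IKBA_26_38	P25963	NF-kappa-B inhibitor alpha	0.016	0	0	ONL, INL, GCL
GBRB2_427_439	P47870	Gamma-aminobutyric acid receptor subunit beta-2 precursor	0.026	10	6
PTN12_32_44	Q05209	Tyrosine-protein phosphatase non-receptor type 12	0.031	10	5
KCNA6_504_516	P17658	Potassium voltage-gated channel subfamily A member 6	0.032	9	3	GCL
NCF1_296_308	P14598	Neutrophil cytosol factor 1	0.032	9	7	GCL
CREB1_126_138	P16220	cAMP response element-binding protein	0.034	10	6	ONL, INL, GCL
GRIK2_708_720	Q13002	Glutamate receptor, ionotropic kainate 2 precursor	0.035	10	4	INL, IPL
NCF1_321_333	P14598	Neutrophil cytosol factor 1	0.036	0	0
EPB42_241_253	P16452	Erythrocyte membrane protein band 4.2	0.037	9	7
VTNC_390_402	P04004	Vitronectin precursor	0.037	10	4	RPE, ONL, GCL
ADRB2_338_350	P07550	Beta-2 adrenergic receptor	0.039	8	4	Müller cells
BRCA1_1451_1463	P38398	Breast cancer type 1 susceptibility protein	0.039	0	0
TOP2A_1463_1475	P11388	DNA topoisomerase 2-alpha	0.039	6	5	GCL
MPIP3_208_220	P30307	M-phase inducer phosphatase 3	0.041	0	0
CDC2_154_169	P06493	Cell division control protein 2 homolog	0.046	0	0
KAP3_107_119	P31323	cAMP-dependent protein kinase type II-beta regulatory subunit	0.046	8	4
MYPC3_268_280	Q14896	Myosin-binding protein C, cardiac-type	0.049	10	4
RYR1_4317_4329	P21817	Ryanodine receptor 1	0.053	9	5	ONL, INL, GCL
TY3H_65_77	P07101	Tyrosine 3-monooxygenase	0.054	9	3
KCNA3_461_473	P22001	Potassium voltage-gated channel subfamily A member 3	0.055	8	7	ONL, IPL
F263_454_466	Q16875	6-phosphofructo-2-kinase/fructose-2,6-biphosphatase 3	0.059	10	3
VASP_150_162	P50552	Vasodilator-stimulated phosphoprotein	0.081	8	4	ONL
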