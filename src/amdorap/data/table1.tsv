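metabolite	formula	theoretical_mz	amdorap_mz	amdorap_ppm	mzmine2_mz	mzmine2_ppm	xcms_mz	xcms_ppm
serine	C3H7NO3	106.04987	106.04960	-2.55	106.04955	-3.02	106.04958	-2.68
valine	C5H11NO2	118.08626	118.08604	-1.78	118.08602	-2.01	118.08422	-17.26
glutamine	C5H10N2O3	147.07642	147.07666	1.64	147.07642	0.03	147.14403	459.68
lysine	C6H14N2O2	147.11280	147.11277	-0.23	147.11067	-14.49	147.10871	-27.82
glutamic acid	C5H9NO4	148.06043	148.06055	0.76	148.06042	-0.09	148.05154	-60.10
methionine	C5H11NO2S	150.05833	150.05817	-1.06	150.05818	-0.96	150.04993	-55.93
D-alanyl-D-alanine	C6H12N2O3	161.09207	161.09181	-1.59	161.09197	-0.60	161.08698	-31.61
phenylalanine	C9H11NO2	166.08626	166.08617	-0.53	166.08618	-0.44	166.08285	-20.50
citrulline	C6H13N3O3	176.10297	176.10280	-0.96	176.10281	-0.87	176.11662	77.51
tyrosine	C9H11NO3	182.08117	182.08113	-0.21	182.08110	-0.41	182.08119	0.09
tryptophan	C11H12N2O2	205.09715	205.09732	0.81	205.06284	-167.29	205.09010	-34.38
pantothenate	C9H17NO5	220.11795	220.11798	0.14	220.11414	-17.29	220.12327	24.18
uridine	C9H12N2O6	245.07681	245.07692	0.44	245.10884	130.69	245.08308	25.58
methylthioadenosine	C11H15N5O3S	298.09684	298.09708	0.80	298.08231	-48.72	298.09719	1.18
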