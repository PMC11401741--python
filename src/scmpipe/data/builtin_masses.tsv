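id	name	formula	monoisotopic_mass
DB0001	glycine	C2H5NO2	75.032028
DB0002	alanine	C3H7NO2	89.047678
DB0003	serine	C3H7NO3	105.042593
DB0004	proline	C5H9NO2	115.063329
DB0005	valine	C5H11NO2	117.078979
DB0006	threonine	C4H9NO3	119.058243
DB0007	leucine	C6H13NO2	131.094629
DB0008	asparagine	C4H8N2O3	132.053492
DB0009	aspartate	C4H7NO4	133.037508
DB0010	glutamine	C5H10N2O3	146.069142
DB0011	glutamate	C5H9NO4	147.053158
DB0012	lysine	C6H14N2O2	146.105528
DB0013	histidine	C6H9N3O2	155.069477
DB0014	phenylalanine	C9H11NO2	165.078979
DB0015	arginine	C6H14N4O2	174.111676
DB0016	tyrosine	C9H11NO3	181.073893
DB0017	tryptophan	C11H12N2O2	204.089878
DB0018	pyruvate	C3H4O3	88.016044
DB0019	lactate	C3H6O3	90.031694
DB0020	succinate	C4H6O4	118.026609
DB0021	fumarate	C4H4O4	116.010959
DB0022	malate	C4H6O5	134.021523
DB0023	citrate	C6H8O7	192.027003
DB0024	glucose	C6H12O6	180.063388
DB0025	glutathione	C10H17N3O6S	307.083806
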