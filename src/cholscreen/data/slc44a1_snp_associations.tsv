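variant	phenotype	p_value
rs12686004	alcohol-related disorders	1.54 × 10^−2^
rs2575876	alcohol-related disorders	3.02 × 10^−2^
rs149604610	K70 Alcoholic liver disease	6.94 × 10^−3^
rs112519618	K70 Alcoholic liver disease	1.45 × 10^−2^
rs146633331	K70 Alcoholic liver disease	1.64 × 10^−2^
rs185740504	K70 Alcoholic liver disease	1.65 × 10^−2^
rs116909302	K70 Alcoholic liver disease	1.69 × 10^−2^
rs80013298	K70 Alcoholic liver disease	1.70 × 10^−2^
rs187474970	K70 Alcoholic liver disease	1.70 × 10^−2^
rs74409690	K70 Alcoholic liver disease	1.78 × 10^−2^
rs181319399	K70 Alcoholic liver disease	1.79 × 10^−2^
rs188419287	K70 Alcoholic liver disease	1.79 × 10^−2^
rs138278086	K70 Alcoholic liver disease	1.81 × 10^−2^
rs137912394	K70 Alcoholic liver disease	1.82 × 10^−2^
rs78364414	K70 Alcoholic liver disease	1.82 × 10^−2^
rs143012032	K70 Alcoholic liver disease	1.82 × 10^−2^
rs116866483	K70 Alcoholic liver disease	1.83 × 10^−2^
rs142915188	K70 Alcoholic liver disease	1.84 × 10^−2^
rs117347201	K70 Alcoholic liver disease	1.84 × 10^−2^
rs143713468	K70 Alcoholic liver disease	1.85 × 10^−2^
rs117205874	K70 Alcoholic liver disease	1.86 × 10^−2^
rs191075086	K70 Alcoholic liver disease	1.86 × 10^−2^
rs151236148	K70 Alcoholic liver disease	1.87 × 10^−2^
rs117398101	K70 Alcoholic liver disease	1.87 × 10^−2^
rs117111328	K70 Alcoholic liver disease	1.87 × 10^−2^
rs118046379	K70 Alcoholic liver disease	1.88 × 10^−2^
rs12335477	K70 Alcoholic liver disease	2.02 × 10^−2^
rs191661087	K70 Alcoholic liver disease	2.31 × 10^−2^
rs568438809	K70 Alcoholic liver disease	2.35 × 10^−2^
rs117589569	K70 Alcoholic liver disease	3.29 × 10^−2^
rs71494515	K70 Alcoholic liver disease	3.65 × 10^−2^
rs36019711	K70 Alcoholic liver disease	3.68 × 10^−2^
rs35413260	K70 Alcoholic liver disease	3.70 × 10^−2^
rs7028183	K70 Alcoholic liver disease	3.73 × 10^−2^
rs35825389	K70 Alcoholic liver disease	3.74 × 10^−2^
rs1397666	K70 Alcoholic liver disease	3.77 × 10^−2^
rs13285648	K70 Alcoholic liver disease	3.78 × 10^−2^
rs74807089	K70 Alcoholic liver disease	4.04 × 10^−2^
rs7022737	K70 Alcoholic liver disease	4.33 × 10^−2^
rs7021567	K70 Alcoholic liver disease	4.33 × 10^−2^
rs10120572	K70 Alcoholic liver disease	4.33 × 10^−2^
rs10118989	K70 Alcoholic liver disease	4.34 × 10^−2^
rs71494519	K70 Alcoholic liver disease	4.38 × 10^−2^
rs185433179	K70 Alcoholic liver disease	4.38 × 10^−2^
rs1397665	K70 Alcoholic liver disease	4.41 × 10^−2^
rs36112131	K70 Alcoholic liver disease	4.41 × 10^−2^
rs71494516	K70 Alcoholic liver disease	4.41 × 10^−2^
rs71494518	K70 Alcoholic liver disease	4.41 × 10^−2^
rs13299679	K70 Alcoholic liver disease	4.43 × 10^−2^
rs113771472	K70 Alcoholic liver disease	4.44 × 10^−2^
rs71494517	K70 Alcoholic liver disease	4.45 × 10^−2^
rs13286370	K70 Alcoholic liver disease	4.47 × 10^−2^
rs10114041	K70 Alcoholic liver disease	4.59 × 10^−2^
rs35412407	K70 Alcoholic liver disease	4.89 × 10^−2^
rs145172265	F10 Mental and behavioral disorders due to use of alcohol	1.04 × 10^−3^
rs139882511	F10 Mental and behavioral disorders due to use of alcohol	1.29 × 10^−2^
rs74849027	F10 Mental and behavioral disorders due to use of alcohol	3.39 × 10^−2^
rs28503319	F10 Mental and behavioral disorders due to use of alcohol	3.42 × 10^−2^
rs62575094	F10 Mental and behavioral disorders due to use of alcohol	3.85 × 10^−2^
rs10481710	F10 Mental and behavioral disorders due to use of alcohol	4.33 × 10^−2^
rs72744260	F10 Mental and behavioral disorders due to use of alcohol	4.55 × 10^−2^
rs117265373	F10 Mental and behavioral disorders due to use of alcohol	4.81 × 10^−2^
rs4742971	Disorders of lipid metabolism	4.31 × 10^−2^
rs2515629	secondary liver malignant neoplasm of the liver	4.91 × 10^−3^
rs4743034	Liver abscess and sequelae of chronic liver disease	2.49 × 10^−2^
rs7032034	Total cholesterol levels	1.00 × 10^−22^
rs374445	Triglyceride levels	4.00 × 10^−9^
rs11506820	Low density lipoprotein cholesterol levels	5.00 × 10^−8^
rs7859070	High density lipoprotein cholesterol levels	2.00 × 10^−18^
rs16924584	Total cholesterol levels	1.00 × 10^−20^
rs4742971	Depression	4.31 × 10^−2^
rs7861820	Lack of normal physiological development	5.38 × 10^−3^
rs4149268	Pathological, developmental or recurrent dislocation	2.11 × 10^−2^
rs649891	lack of normal physiology	3.26 × 10^−2^
rs117827556	labor and delivery complications	2.36 × 10^−5^
rs2515629	Disorders of the autonomic nervous system	4.74 × 10^−2^
rs7861820	Dementia with cerebral degenerations	4.58 × 10^−2^
rs7031663	height	4.00 × 10^−10^
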