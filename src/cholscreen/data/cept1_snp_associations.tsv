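variant	phenotype	p_value
rs10494127	K70 Alcoholic liver disease	3.01 × 10^−2^
rs57171998	K70 Alcoholic liver disease	3.32 × 10^−2^
rs75484460	K70 Alcoholic liver disease	3.37 × 10^−2^
rs78334840	K70 Alcoholic liver disease	3.47 × 10^−2^
rs4839101	K70 Alcoholic liver disease	3.53 × 10^−2^
rs1591456	K70 Alcoholic liver disease	3.62 × 10^−2^
rs7514887	K70 Alcoholic liver disease	3.91 × 10^−2^
rs2278578	K70 Alcoholic liver disease	3.95 × 10^−2^
rs56273356	K70 Alcoholic liver disease	4.13 × 10^−2^
rs67493833	K70 Alcoholic liver disease	4.23 × 10^−2^
rs6662965	K70 Alcoholic liver disease	4.24 × 10^−2^
rs61804623	K70 Alcoholic liver disease	4.33 × 10^−2^
rs61804560	K70 Alcoholic liver disease	4.34 × 10^−2^
rs56296601	K70 Alcoholic liver disease	4.34 × 10^−2^
rs4839098	K70 Alcoholic liver disease	4.41 × 10^−2^
rs11805357	K70 Alcoholic liver disease	4.46 × 10^−2^
rs12406191	K70 Alcoholic liver disease	4.53 × 10^−2^
rs10494126	K70 Alcoholic liver disease	4.63 × 10^−2^
rs116484160	K70 Alcoholic liver disease	4.69 × 10^−2^
rs56740658	K70 Alcoholic liver disease	4.69 × 10^−2^
rs7521727	K70 Alcoholic liver disease	4.72 × 10^−2^
rs61808584	K70 Alcoholic liver disease	4.77 × 10^−2^
rs55857873	F10 Mental and behavioral disorders due to use of alcohol	6.78 × 10^−3^
rs626339	F10 Mental and behavioral disorders due to use of alcohol	1.29 × 10^−2^
rs2243393	F10 Mental and behavioral disorders due to use of alcohol	1.44 × 10^−2^
rs183103888	F10 Mental and behavioral disorders due to use of alcohol	1.45 × 10^−2^
rs9429589	F10 Mental and behavioral disorders due to use of alcohol	1.48 × 10^−2^
rs2580040	F10 Mental and behavioral disorders due to use of alcohol	1.49 × 10^−2^
rs325922	F10 Mental and behavioral disorders due to use of alcohol	1.49 × 10^−2^
rs325923	F10 Mental and behavioral disorders due to use of alcohol	1.53 × 10^−2^
rs192792696	F10 Mental and behavioral disorders due to use of alcohol	2.20 × 10^−2^
rs325929	F10 Mental and behavioral disorders due to use of alcohol	2.34 × 10^−2^
rs182732	F10 Mental and behavioral disorders due to use of alcohol	2.53 × 10^−2^
rs532249550	F10 Mental and behavioral disorders due to use of alcohol	2.62 × 10^−2^
rs35041930	F10 Mental and behavioral disorders due to use of alcohol	2.66 × 10^−2^
rs573629054	F10 Mental and behavioral disorders due to use of alcohol	3.25 × 10^−2^
rs146158422	F10 Mental and behavioral disorders due to use of alcohol	3.52 × 10^−2^
Affx-4271322	F10 Mental and behavioral disorders due to use of alcohol	3.59 × 10^−2^
rs608881	F10 Mental and behavioral disorders due to use of alcohol	3.77 × 10^−2^
rs78334840	F10 Mental and behavioral disorders due to use of alcohol	3.80 × 10^−2^
rs7521727	F10 Mental and behavioral disorders due to use of alcohol	3.92 × 10^−2^
rs657605	F10 Mental and behavioral disorders due to use of alcohol	4.17 × 10^−2^
rs629619	F10 Mental and behavioral disorders due to use of alcohol	4.35 × 10^−2^
rs675874	F10 Mental and behavioral disorders due to use of alcohol	4.94 × 10^−2^
rs11590090	Alcoholism	4.28 × 10^−2^
rs1335645	gamma glutamyltransferase activity	1.82 × 10^−19^
rs2296380	gamma glutamyltransferase activity	9.00 × 10^−10^
rs4839104	gamma glutamyltransferase activity	2.00 × 10^−20^
rs77355087	gamma glutamyltransferase activity	3.00 × 10^−21^
rs1335645	gamma glutamyltransferase activity	4.00 × 10^−18^
rs2885805	Psychogenic Disorders	8.02 × 10^−3^
rs958798	schizophrenia	4.85 × 10^−3^
rs17036350	random mental disorders	4.67 × 10^−2^
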