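id	sex	age_at_surgery	height_cm	weight_kg	bmi_pre	weight_loss_12m_kg	bmi_post	charge:preoperative:Clinic	charge:preoperative:Ancillary	charge:preoperative:Diagnostic	charge:perioperative:Ancillary	charge:perioperative:Diagnostic	charge:perioperative:Gen nursing	charge:perioperative:Minimally invasive procedures	charge:perioperative:Pharmacy	charge:perioperative:Surgery and procedures	charge:foundation:Surgical foundation	charge:postoperative:Clinic	charge:postoperative:Ancillary	charge:postoperative:Surgery and procedures
0	F	17.10694407482254	166.55884301986626	140.13982441061503	50.51567705955711	8.270418401979775	47.5344703476256	161.45931496677622	200.55663252847006	4054.720270574981	421.4356005059554	503.44738070125675	3668.485364535426	22.015122660116496	3060.103179041939	28816.47946526916	2299.258373297654	753.2295299037964	1770.267649237646	1007.9499461524019
1	F	16.824851526029676	164.80379668262688	130.56325473761294	48.071374791201386	45.9154565870321	31.166012507302252	181.7350484227432	189.01410630883416	2213.3446788604306	705.8919430704328	1260.471637305559	7827.4253467275885	40.755719972358094	2745.3793129840924	28894.702749118587	3568.8136876700573	1813.419462577228	1770.5483619947793	147.01421910774457
2	F	17.46966656476534	162.89504106340286	161.0134985164882	60.68013796179806	48.60696242312652	42.36193971808238	420.6414664263781	216.21811208817167	4111.707184707192	345.235790650587	1035.7056150147969	7492.835332467303	102.70795791193896	3238.6112704611232	32506.087998691637	3256.9821704308542	968.5260092299635	687.8694497529588	44.80591424259728
3	M	17.85438974065223	164.11185188208557	160.98756335476625	59.77401589299899	59.18582110852212	37.798565505040465	373.17317390165	242.10675378156196	760.7024803014467	331.48619593949	988.7450508155204	5038.423893242214	21.23620900975761	3030.006206162581	27845.369881507337	3803.319712098551	802.2057388235464	284.2778224674712	608.7181755340393
4	F	19.169255680971737	180.1132073683099	132.347448445553	40.79664532414753	36.978218203243614	29.39795747277358	269.5064366978107	224.54212016699296	2531.7193992725183	290.67060357443006	1431.8639638248592	5953.922754062109	17.451213503199977	3401.858928954919	29788.12549457218	3984.8763441625088	1743.2917110985327	3891.9915901605855	223.84546565215314
5	F	17.546890574299717	178.31196285645228	139.29095848976317	43.80886134405486	45.574180623138744	29.475174639366642	414.69937569814573	85.5009396435214	2199.221421255107	289.4180906134419	1462.5667420721986	4006.595043414191	36.09638723043733	3384.040022609428	21829.247878727165	3609.1343260784106	328.95588066007974	1882.2943251467605	346.0470874487685
6	F	19.018329953856988	168.38106643856088	140.44039612206726	49.53424343799183	46.95381678224718	32.97332610183485	50.09440205448584	66.90814785741435	1871.664978542835	121.0203591232148	1145.0237217800595	5358.361098131061	56.31542444038571	3294.879173516996	26513.59153698192	3272.891166455491	274.1285376263882	1591.4882502645607	1223.5360627492444
7	M	16.03830141710545	163.00490218150912	146.26178353076054	55.046477609014936	47.60112681750556	37.131515147391276	479.10242338914543	168.61636950128633	1576.9447939090535	143.19648508676565	844.3743691840428	6392.698648711391	56.944168801675914	2759.6723984647547	23986.744296625584	3557.9468104232205	274.30200317699087	1515.0557261616634	4.89210303774604
8	M	18.602513577257795	159.88373234100476	117.24910645996762	45.86706869944383	28.62094113956821	34.67074735315256	410.9421838954635	114.16507825303081	644.4308934040133	244.44350382334162	1564.556269674125	9230.094602735655	41.08634852857693	3265.7746228891483	26839.442966641862	2961.800242253814	775.0282451048091	3634.296648648665	1005.7528437878366
9	F	15.07106097367995	179.18168811671924	141.66875492016894	44.12521447193158	26.95232142414068	35.73044200409414	260.9112924063948	195.821482597402	3878.611352001764	190.80374392401944	665.8457562167807	5085.504968776299	55.8980132075552	2922.035675078106	24296.628297997064	3930.4934326302264	1638.8885858830913	2544.0365374465846	18.780510821123045
10	F	16.6782415142851	168.99983205838453	137.47622814990518	48.134344519044554	39.89655223715786	34.16542482762415	480.93380392746883	374.14326306778713	1758.2498364996954	272.65462656416423	890.9702514474454	6581.828035149182	16.930016806802925	2773.237866555609	31824.35354334281	3559.9938270293915	169.67544224619212	2682.6322010414597	1257.3921355885543
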