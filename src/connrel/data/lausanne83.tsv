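# synthetic geometry for the 83-node parcellation fixture
# (region names only follow the atlas; centroids/volumes/surfaces are generated)
label	hemisphere	centroid_x	centroid_y	centroid_z	volume_mm3	surface_mm2
bankssts	left	-44.0084	-4.1797	-2.5278	12501.6656	3231.9391
bankssts	right	44.0084	-4.1797	-2.5278	12093.2920	3161.1682
caudalanteriorcingulate	left	-28.5439	-7.2809	-30.3750	17522.0906	4047.7020
caudalanteriorcingulate	right	28.5439	-7.2809	-30.3750	19163.3622	4296.6739
caudalmiddlefrontal	left	-8.6726	14.7161	30.0906	7161.4974	2229.2245
caudalmiddlefrontal	right	8.6726	14.7161	30.0906	7960.4020	2392.0738
cuneus	left	-39.9980	47.4337	2.9724	3386.8682	1353.1630
cuneus	right	39.9980	47.4337	2.9724	2608.4092	1136.9335
entorhinal	left	-25.7025	-24.2551	-27.0064	7740.6162	2347.8388
entorhinal	right	25.7025	-24.2551	-27.0064	7456.0929	2289.9471
fusiform	left	-24.2017	-58.0281	-31.1802	8722.5538	2542.4184
fusiform	right	24.2017	-58.0281	-31.1802	8535.3923	2505.9183
inferiorparietal	left	-32.3139	-4.8533	14.0741	13018.8120	3320.4643
inferiorparietal	right	32.3139	-4.8533	14.0741	14990.1619	3647.7254
inferiortemporal	left	-30.8116	15.7645	38.8560	4826.8101	1713.6603
inferiortemporal	right	30.8116	15.7645	38.8560	4644.8891	1670.3269
isthmuscingulate	left	-13.6807	40.9380	-1.5758	13908.3381	3470.0421
isthmuscingulate	right	13.6807	40.9380	-1.5758	14932.4410	3638.3554
lateraloccipital	left	-23.7950	-41.5682	32.7881	8228.8916	2445.5628
lateraloccipital	right	23.7950	-41.5682	32.7881	8696.2138	2537.2975
lateralorbitofrontal	left	-10.7590	10.2384	24.8259	7128.7006	2222.4133
lateralorbitofrontal	right	10.7590	10.2384	24.8259	7511.2819	2301.2332
lingual	left	-61.0732	9.7062	0.4466	15975.7540	3805.9127
lingual	right	61.0732	9.7062	0.4466	15106.5859	3666.5882
medialorbitofrontal	left	-53.6907	-35.1151	6.2195	6416.2278	2071.7520
medialorbitofrontal	right	53.6907	-35.1151	6.2195	6829.7536	2159.8385
middletemporal	left	-25.1302	8.7620	16.6554	6386.4733	2065.3420
middletemporal	right	25.1302	8.7620	16.6554	6320.4874	2051.0912
parahippocampal	left	-31.1371	8.6428	-5.7874	3847.0908	1473.1248
parahippocampal	right	31.1371	8.6428	-5.7874	4203.6151	1562.7873
paracentral	left	-35.3842	11.5257	31.9098	8353.4265	2470.1748
paracentral	right	35.3842	11.5257	31.9098	8237.4463	2447.2574
parsopercularis	left	-22.7973	-25.1075	5.8500	15451.4652	3722.1828
parsopercularis	right	22.7973	-25.1075	5.8500	15185.5691	3679.3573
parsorbitalis	left	-11.9381	74.4881	-7.0492	2145.2848	998.0245
parsorbitalis	right	11.9381	74.4881	-7.0492	2285.9584	1041.1903
parstriangularis	left	-20.4896	-51.1188	-16.8978	9449.1717	2681.7219
parstriangularis	right	20.4896	-51.1188	-16.8978	9628.3523	2715.5172
pericalcarine	left	-31.4352	-23.7381	-4.4710	9601.7402	2710.5113
pericalcarine	right	31.4352	-23.7381	-4.4710	6989.5179	2193.3910
postcentral	left	-22.0504	19.6463	29.2461	1869.5921	910.5752
postcentral	right	22.0504	19.6463	29.2461	1750.7125	871.5543
posteriorcingulate	left	-36.4744	-17.6750	-5.6046	2895.3598	1218.8575
posteriorcingulate	right	36.4744	-17.6750	-5.6046	3103.5124	1276.5963
precentral	left	-7.5380	27.3115	33.4910	20560.3659	4503.0331
precentral	right	7.5380	27.3115	33.4910	19532.5112	4351.6769
precuneus	left	-7.9468	-38.8792	-12.5256	8217.2534	2443.2564
precuneus	right	7.9468	-38.8792	-12.5256	8628.6415	2524.1367
rostralanteriorcingulate	left	-27.6226	23.5963	-20.8646	4345.2453	1597.6959
rostralanteriorcingulate	right	27.6226	23.5963	-20.8646	4388.5452	1608.2923
rostralmiddlefrontal	left	-14.0272	33.3365	-25.6158	15598.6168	3745.7775
rostralmiddlefrontal	right	14.0272	33.3365	-25.6158	15358.5477	3707.2455
superiorfrontal	left	-15.0647	76.7479	-5.2855	2502.3489	1105.9016
superiorfrontal	right	15.0647	76.7479	-5.2855	2457.8905	1092.7637
superiorparietal	left	-32.1954	14.8544	29.4979	3726.1897	1442.0973
superiorparietal	right	32.1954	14.8544	29.4979	3612.7573	1412.6799
superiortemporal	left	-36.1496	-33.0613	20.0415	7261.9189	2250.0155
superiortemporal	right	36.1496	-33.0613	20.0415	8382.4730	2475.8977
supramarginal	left	-44.6962	-27.6850	22.7709	7235.0622	2244.4646
supramarginal	right	44.6962	-27.6850	22.7709	7050.3099	2206.0908
frontalpole	left	-25.6035	-9.0968	22.9641	6206.0814	2026.2649
frontalpole	right	25.6035	-9.0968	22.9641	6685.3872	2129.2940
temporalpole	left	-30.3556	-37.4451	-39.3327	10145.2449	2811.8551
temporalpole	right	30.3556	-37.4451	-39.3327	10768.9825	2925.9554
transversetemporal	left	-47.8521	26.6946	22.6352	9818.4607	2751.1453
transversetemporal	right	47.8521	26.6946	22.6352	10025.1740	2789.6252
insula	left	-24.4194	30.5275	-19.1501	10971.9519	2962.6057
insula	right	24.4194	30.5275	-19.1501	10727.2162	2918.3851
thalamus	left	-42.9035	-5.8652	-40.6241	6150.9496	2014.2469
thalamus	right	42.9035	-5.8652	-40.6241	5868.0423	1952.0012
caudate	left	-34.2690	58.0205	12.3208	5401.9833	1847.2262
caudate	right	34.2690	58.0205	12.3208	5752.8271	1926.3660
putamen	left	-19.7867	-32.6509	-29.6794	6796.4734	2152.8164
putamen	right	19.7867	-32.6509	-29.6794	5526.7752	1875.5664
pallidum	left	-24.9619	22.6383	-14.3414	8395.4044	2478.4433
pallidum	right	24.9619	22.6383	-14.3414	9436.5670	2679.3366
accumbens	left	-30.2408	-30.7575	40.4351	14274.6832	3530.7115
accumbens	right	30.2408	-30.7575	40.4351	13637.3016	3424.8131
hippocampus	left	-54.6878	32.4526	-3.5405	16179.3983	3838.1873
hippocampus	right	54.6878	32.4526	-3.5405	14410.6694	3553.0994
amygdala	left	-12.3427	52.7474	1.4144	5735.3307	1922.4581
amygdala	right	12.3427	52.7474	1.4144	4551.0300	1647.7490
brainstem	none	0.0000	-27.6801	-34.0821	19828.1727	4395.4807
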