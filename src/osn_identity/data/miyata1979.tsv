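aa	A	C	D	E	F	G	H	I	K	L	M	N	P	Q	R	S	T	V	W	Y
A	0.0000	1.2170	2.3004	2.0703	2.8339	0.4227	1.8006	2.1057	2.1413	2.1971	1.6778	1.7248	0.1435	1.3992	1.9799	0.5737	0.6535	1.3266	4.5296	2.6617
C	1.2170	0.0000	3.5173	3.2709	2.6682	1.6396	2.7903	1.7959	3.1884	1.8120	1.4286	2.9266	1.1593	2.5315	2.9391	1.7688	1.6353	1.0350	4.5232	2.7011
D	2.3004	3.5173	0.0000	0.4696	4.1962	1.8777	1.6224	3.8274	1.4185	3.9590	3.4991	0.6854	2.3711	1.2557	1.7214	1.7643	2.0543	3.3264	5.3214	3.8137
E	2.0703	3.2709	0.4696	0.0000	3.7466	1.6567	1.1547	3.4162	0.9595	3.5504	3.1086	0.3455	2.1630	0.8467	1.2520	1.5031	1.7176	2.9700	4.8522	3.3558
F	2.8339	2.6682	4.1962	3.7466	0.0000	2.9988	2.6266	0.8740	2.9829	0.8850	1.2604	3.5279	2.9334	2.9573	2.6019	2.9015	2.4561	1.6779	1.8607	0.4638
G	0.4227	1.6396	1.8777	1.6567	2.9988	0.0000	1.5279	2.3482	1.8212	2.4542	1.9368	1.3116	0.5063	1.0454	1.7170	0.2161	0.5739	1.6353	4.5988	2.7672
H	1.8006	2.7903	1.6224	1.1547	2.6266	1.5279	0.0000	2.4163	0.4275	2.5550	2.1873	1.0289	1.9380	0.6043	0.1924	1.3118	1.1840	2.1711	3.7140	2.2170
I	2.1057	1.7959	3.8274	3.4162	0.8740	2.3482	2.4163	0.0000	2.8285	0.1391	0.4323	3.1420	2.1840	2.5752	2.4567	2.2981	1.8717	0.8376	2.7340	1.0044
K	2.1413	3.1884	1.4185	0.9595	2.9829	1.8212	0.4275	2.8285	0.0000	2.9675	2.6117	0.9689	2.2722	0.7885	0.3824	1.6092	1.5613	2.5979	3.9203	2.5542
L	2.1971	1.8120	3.9590	3.5504	0.8850	2.4542	2.5550	0.1391	2.9675	0.0000	0.5202	3.2736	2.2694	2.7082	2.5958	2.4117	1.9902	0.9006	2.7423	1.0756
M	1.6778	1.4286	3.4991	3.1086	1.2604	1.9368	2.1873	0.4323	2.6117	0.5202	0.0000	2.8157	1.7531	2.2619	2.2574	1.9020	1.4909	0.4177	3.1005	1.2771
N	1.7248	2.9266	0.6854	0.3455	3.5279	1.3116	1.0289	3.1420	0.9689	3.2736	2.8157	0.0000	1.8179	0.5737	1.1693	1.1582	1.3908	2.6551	4.7386	3.1584
P	0.1435	1.1593	2.3711	2.1630	2.9334	0.5063	1.9380	2.1840	2.2722	2.2694	1.7531	1.8179	0.0000	1.5205	2.1186	0.6844	0.7969	1.3844	4.6480	2.7759
Q	1.3992	2.5315	1.2557	0.8467	2.9573	1.0454	0.6043	2.5752	0.7885	2.7082	2.2619	0.5737	1.5205	0.0000	0.7892	0.8402	0.9122	2.1322	4.2274	2.5959
R	1.9799	2.9391	1.7214	1.2520	2.6019	1.7170	0.1924	2.4567	0.3824	2.5958	2.2574	1.1693	2.1186	0.7892	0.0000	1.5010	1.3527	2.2736	3.6003	2.1764
S	0.5737	1.7688	1.7643	1.5031	2.9015	0.2161	1.3118	2.2981	1.6092	2.4117	1.9020	1.1582	0.6844	0.8402	1.5010	0.0000	0.4454	1.6379	4.4533	2.6440
T	0.6535	1.6353	2.0543	1.7176	2.4561	0.5739	1.1840	1.8717	1.5613	1.9902	1.4909	1.3908	0.7969	0.9122	1.3527	0.4454	0.0000	1.2739	4.0255	2.2024
V	1.3266	1.0350	3.3264	2.9700	1.6779	1.6353	2.1711	0.8376	2.5979	0.9006	0.4177	2.6551	1.3844	2.1322	2.2736	1.6379	1.2739	0.0000	3.5123	1.6690
W	4.5296	4.5232	5.3214	4.8522	1.8607	4.5988	3.7140	2.7340	3.9203	2.7423	3.1005	4.7386	4.6480	4.2274	3.6003	4.4533	4.0255	3.5123	0.0000	1.8784
Y	2.6617	2.7011	3.8137	3.3558	0.4638	2.7672	2.2170	1.0044	2.5542	1.0756	1.2771	3.1584	2.7759	2.5959	2.1764	2.6440	2.2024	1.6690	1.8784	0.0000
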