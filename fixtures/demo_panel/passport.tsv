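id	group	country	longitude	latitude	altitude
L1-001	L1	Georgia	40.9166	36.9997	1250.61
L1-002	L1	Armenia	44.9377	37.6002	1298.13
L1-003	L1	Azerbaijan	40.6927	35.4133	1424.71
L1-004	L1	Georgia	46.8843	38.581	940.637
L1-005	L1	Armenia	41.7011	38.0028	1412.61
L1-006	L1	Georgia	45.4759	39.6393	1304.26
L1-007	L1	China	65.096	35.5457	1365.24
L1-008	L1	Uzbekistan	69.164	38.2369	1395.99
L1-009	L1	Afghanistan	66.1016	32.7707	1306.76
L1-010	L1	China	64.3536	36.3675	1809.29
L1-011	L1	China	73.9848	36.9216	1528.36
L1-012	L1	China	66.0529	36.6936	1515.88
L2-001	L2	Iran	50.0121	39.2382	112.821
L2-002	L2	Azerbaijan	46.9984	38.8274	132.205
L2-003	L2	Iran	49.4052	34.6418	108.586
L2-004	L2	Azerbaijan	48.5318	38.4742	18.2734
L2-005	L2	Iran	49.5726	37.1371	775.664
L2-006	L2	Azerbaijan	49.7231	35.9365	779.997
L2-007	L2	Azerbaijan	49.054	38.4273	598.05
L2-008	L2	Iran	50.979	35.8683	1031.48
F1-001	hybrid				
RIL-001	hybrid				
HG-001	hybrid	Georgia	45.0769	41.3995	721.623
HG-002	hybrid	Georgia	44.6501	41.2644	560.665
HG-003	hybrid	Georgia	44.8932	40.5835	690.238
WH-001	wheat	United States			
WH-002	wheat	United States			
WH-003	wheat	United States			
WH-004	wheat	United States			
WH-005	wheat	United States			
WH-006	wheat	United States			
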