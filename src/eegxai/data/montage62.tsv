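label	x	y	z
Fp1	-28.0880	79.9479	-6.6634
Fp2	28.0880	79.9479	-6.6634
F7	-71.9825	43.6478	-11.7639
F3	-51.0855	53.7559	41.5400
Fz	0.0000	56.1671	63.7985
F4	51.0855	53.7559	41.5400
F8	71.9825	43.6478	-11.7639
FC5	-78.9925	19.4416	24.6418
FC1	-32.3579	24.6513	74.6343
FC2	32.3579	24.6513	74.6343
FC6	78.9925	19.4416	24.6418
T7	-83.1090	-15.2423	-9.2498
C3	-60.6897	-10.3223	58.6107
Cz	0.0000	-7.7407	84.6468
C4	60.6897	-10.3223	58.6107
T8	83.1090	-15.2423	-9.2498
CP5	-70.1307	-39.8846	26.7563
CP1	-28.8224	-36.8056	70.9903
CP2	28.8224	-36.8056	70.9903
CP6	70.1307	-39.8846	26.7563
P7	-59.8738	-60.2980	-2.0688
P3	-41.6344	-60.2820	43.1006
Pz	0.0000	-59.5509	60.6522
P4	41.6344	-60.2820	43.1006
P8	59.8738	-60.2980	-2.0688
PO9	-39.6201	-70.7103	-25.5989
O1	-21.6208	-81.9519	6.4360
Oz	0.0000	-84.3167	10.7564
O2	21.6208	-81.9519	6.4360
PO10	39.6201	-70.7103	-25.5989
AF7	-52.7172	65.8966	-10.1756
AF3	-33.7437	75.1377	20.9925
AF4	33.7437	75.1377	20.9925
AF8	52.7172	65.8966	-10.1756
F5	-66.9945	49.5272	16.8463
F1	-27.6389	55.5265	58.1197
F2	27.6389	55.5265	58.1197
F6	66.9945	49.5272	16.8463
FT9	-72.0967	12.4021	-43.2810
FT7	-82.8689	15.0544	-11.4500
FC3	-60.5947	22.9758	55.0036
FC4	60.5947	22.9758	55.0036
FT8	82.8689	15.0544	-11.4500
FT10	72.0967	12.4021	-43.2810
C5	-79.1480	-12.8272	28.2144
C1	-32.3733	-8.5978	78.1220
C2	32.3733	-8.5978	78.1220
C6	79.1480	-12.8272	28.2144
TP7	-74.6717	-40.1309	-6.2173
CP3	-53.4016	-38.4184	53.8266
CPz	0.0000	-36.5251	76.7523
CP4	53.4016	-38.4184	53.8266
TP8	74.6717	-40.1309	-6.2173
P5	-54.3875	-61.2422	22.7243
P1	-22.4074	-59.5945	56.3152
P2	22.4074	-59.5945	56.3152
P6	54.3875	-61.2422	22.7243
PO7	-41.8705	-73.9424	2.0923
PO3	-27.4610	-75.5725	27.5625
POz	0.0000	-76.1692	37.7260
PO4	27.4610	-75.5725	27.5625
PO8	41.8705	-73.9424	2.0923
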