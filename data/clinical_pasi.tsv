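patient_id	sex	age	BMI	PASI_0	PASI_12
P1	Male	64	21.6	21.6	1.2
P2	Male	55	27.2	32.2	3.7
P3	Male	23	20.1	24.3	2.8
P4	Male	51	22	18.7	2.5
P5	Male	61	27.3	43.6	6
P6	Male	35	21.6	19.9	3
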