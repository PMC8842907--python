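index	system	value	modality	train_frequency
0	ICD9	4019	diagnosis	1
1	ICD9	462	diagnosis	1
2	ICD9	64403	diagnosis	1
3	ICD9	64421	diagnosis	1
4	ICD9	64511	diagnosis	1
5	ICD9	64883	diagnosis	1
6	ICD9	650	diagnosis	1
7	ICD9	V220	diagnosis	1
8	LOINC	18481-2	lab	1
9	LOINC	6559-4	lab	1
10	NDC	00071015523	medication	1
11	NDC	00093505698	medication	1
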