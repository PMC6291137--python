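name	formula	adduct	mz_experimental	brain_reported
Citrulline	C6H13N3O3	+Na	198.0864	0
DAG(35:0)	C38H74O5	+H+NH4	314.7974	0
Monoacylglycerol(18:2)	C21H38O4	+K	393.2330	0
Cholesterol	C27H46O	+Na	409.3409	1
Cholesterol	C27H46O	+K	425.3091	1
Palmitoyl glucuronide	C22H42O7	+Na	441.2787	0
Palmitoyl glucuronide	C22H42O7	+K	457.2581	0
Dimethylphosphatidylethanolamine	C41H78NO8P	+Na	766.5271	0
Phosphatidylcholine(34:4)	C42H76NO8P	+K	792.4857	1
Phosphatidylserine(34:3)	C40H72NO10P	+K	796.4646	1
Phosphatidylethanolamine(40:10)	C45H70NO8P	+Na	806.4772	1
Phosphatidylserine(36:5)	C42H72NO10P	+K	820.4617	0
Phosphatidylcholine(38:3)	C46H88NO7P	+Na	820.6139	0
Phosphatidylserine(36:4)	C42H74NO10P	+K	822.4692	1
Phosphatidylcholine(38:1)	C46H90NO7P	+Na	822.6361	0
Phosphatidylserine(38:7)	C44H72NO10P	+Na	828.4711	0
Phosphatidylethanolamine(42:11)	C47H72NO8P	+Na	832.4840	1
3,4-dihydroxy-5-all-trans-decaprenylbenzoate	C57H85O4	+H	834.6539	0
Phosphatidylglycerol(38:4)	C44H79O10P	+K	837.5056	0
Phosphatidylcholine(38:2)	C46H90NO7P	+K	838.6038	0
Phosphatidylserine(38:7)	C44H72NO10P	+K	844.4639	0
Phosphatidylinositol(32:2)	C41H75O13P	+K	845.4620	1
Glucosylceramide	C48H91NO8	+K	848.6360	1
Triacylglycerol(49:5)	C52H90O6	+K	849.6369	0
DMPE(40:10)	C47H74NO8P	+K	850.4673	0
Phosphatidylcholine(40:2)	C48H94NO7P	+Na	850.6576	0
Phosphatidylserine(40:9)	C46H72NO10P	+Na	852.4730	0
Phosphatidylcholine(40:3)	C48H92NO7P	+K	864.6167	0
Phosphatidylcholine(40:1)	C48H94NO7P	+K	866.6282	0
Phosphatidylserine(40:9)	C46H72NO10P	+K	868.4617	0
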