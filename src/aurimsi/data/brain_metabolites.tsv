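name	formula	tissue
Citrulline	C6H13N3O3
DAG(35:0)	C38H74O5
Monoacylglycerol(18:2)	C21H38O4
Cholesterol	C27H46O	brain
Palmitoyl glucuronide	C22H42O7
Dimethylphosphatidylethanolamine	C41H78NO8P
Phosphatidylcholine(34:4)	C42H76NO8P	brain
Phosphatidylserine(34:3)	C40H72NO10P	brain
Phosphatidylethanolamine(40:10)	C45H70NO8P	brain
Phosphatidylserine(36:5)	C42H72NO10P
Phosphatidylcholine(38:3)	C46H88NO7P
Phosphatidylserine(36:4)	C42H74NO10P	brain
Phosphatidylcholine(38:1)	C46H90NO7P
Phosphatidylserine(38:7)	C44H72NO10P
Phosphatidylethanolamine(42:11)	C47H72NO8P	brain
3,4-dihydroxy-5-all-trans-decaprenylbenzoate	C57H85O4
Phosphatidylglycerol(38:4)	C44H79O10P
Phosphatidylcholine(38:2)	C46H90NO7P
Phosphatidylinositol(32:2)	C41H75O13P	brain
Glucosylceramide	C48H91NO8	brain
Triacylglycerol(49:5)	C52H90O6
DMPE(40:10)	C47H74NO8P
Phosphatidylcholine(40:2)	C48H94NO7P
Phosphatidylserine(40:9)	C46H72NO10P
Phosphatidylcholine(40:3)	C48H92NO7P
Phosphatidylcholine(40:1)	C48H94NO7P
Creatine	C4H9N3O2	brain
Taurine	C2H7NO3S	brain
Glucose	C6H12O6	liver
Arachidonic acid	C20H32O2
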