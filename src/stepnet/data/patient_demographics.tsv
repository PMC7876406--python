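subject_id	sex	age_years	age_months	group	notes
D001	M	14	11	patient	IQ 36; no autism; no seizures; excluded from analysis (task comprehension, visit 1)
D002	M	14	2	patient	IQ 82; autism
D003	M	18	9	patient	IQ 50; no autism
D004	M	15	5	patient	IQ 55; autism; history of frontal lobe epilepsy
D005	M	14	0	patient	IQ 73; autism
D006	M	18	11	patient	IQ 67; autism; history of generalized tonic-clonic seizures
D007	M	14	8	patient	IQ 87; no autism
D008	M	18	8	patient	IQ 59; no autism
D009	M	16	9	patient	IQ 56; autism
D010	F	15	0	patient	IQ 67; no autism; myoclonic jerks
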