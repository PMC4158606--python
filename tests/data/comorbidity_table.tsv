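condition	a	b	ratio_printed
Carpal tunnel syndrome	9	2	56.96
Urinary tract infection site not specified	26	76	4.33
Pneumonitis due to inhalation of food or vomitus	15	21	9.041
Anxiety state unspecified	14	22	8.054
Unspecified essential hypertension	53	305	2.199
Esophageal reflux	19	56	4.294
Unspecified pleural effusion	12	21	7.232
Friedlander's bacillus infection in conditions classified elsewhere and of unspecified site	6	2	37.97
Thyrotoxicosis without goiter or other cause and without thyrotoxic crisis or storm	6	2	37.97
Atrial fibrillation	15	41	4.631
Other specified disorders of pancreatic internal secretion	4	0	-1
Other specified idiopathic peripheral neuropathy	4	0	-1
Pure hypercholesterolemia	20	83	3.05
Hemorrhage complicating a procedure	5	2	31.64
Long-term (current) use of steroids	5	3	21.09
Personal history of noncompliance with medical treatment presenting hazards to health	7	13	6.815
Hematoma complicating a procedure	4	2	25.31
Adrenal cortical steroids causing adverse effects in therapeutic use	5	5	12.66
Nontoxic uninodular goiter	3	0	-1
Chronic lymphocytic thyroiditis	3	0	-1
Personal history of malignant neoplasm of bladder	3	0	-1
Personal history of malignant neoplasm of other endocrine glands and related structures	3	0	-1
Embolism and thrombosis of other specified veins	4	3	16.88
Depressive disorder not elsewhere classified	14	62	2.858
Toxic diffuse goiter without thyrotoxic crisis or storm	3	1	37.97
Unspecified idiopathic peripheral neuropathy	3	1	37.97
Unspecified disorder of optic nerve and visual pathways	3	1	37.97
Personal history of tobacco use	8	24	4.219
Diabetes mellitus without complication type i not stated as uncontrolled	8	25	4.05
Hypertrophy (benign) of prostate without urinary obstruction	5	9	7.032
Bipolar disorder, unspecified	4	5	10.13
Unspecified disorder of thyroid	3	2	18.99
Retention of urine unspecified	3	2	18.99
Other specified retention of urine	3	2	18.99
Migraine unspecified without mention of intractable migraine without mention of status migrainosus	4	6	8.438
Other pulmonary embolism and infarction	4	6	8.438
Unspecified sleep apnea	4	6	8.438
Anemia unspecified	11	53	2.627
Methicillin susceptible staphylococcus aureus	3	3	12.66
Obstructive sleep apnea (adult)(pediatric)	3	3	12.66
Tracheostomy status	4	10	5.063
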