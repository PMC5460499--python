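category,weight
myocardial_infarction,0
congestive_heart_failure,2
peripheral_vascular_disease,0
cerebrovascular_disease,0
dementia,2
chronic_pulmonary_disease,1
rheumatic_disease,1
peptic_ulcer_disease,0
mild_liver_disease,2
diabetes_without_complications,0
diabetes_with_complications,1
hemiplegia_paraplegia,2
renal_disease,1
malignancy,2
moderate_severe_liver_disease,4
metastatic_solid_tumour,6
aids_hiv,4
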