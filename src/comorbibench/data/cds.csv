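condition,ahfs_class,score_1_class,score_2_classes,score_3plus_classes
heart_disease,20:12,3,4,5
heart_disease,24:04,3,4,5
heart_disease,24:12,3,4,5
heart_disease,40:28,3,4,5
respiratory_illness,12:12,2,3,4
respiratory_illness,48:92,2,3,4
respiratory_illness,86:16,2,3,4
asthma_allergy,04:00,2,2,2
cancer,10:00,3,3,3
parkinsons_disease,28:36,3,3,3
hypertension,24:08,1,2,2
hypertension,40:36,1,2,2
diabetes,68:20,2,2,2
epilepsy,28:12,2,2,2
rheumatoid_arthritis,60:00,3,3,3
tuberculosis,08:16,2,2,2
peptic_ulcer,56:28,1,1,1
glaucoma,52:40,1,1,1
gout,92:16,1,1,1
high_cholesterol,24:06,1,1,1
migraine,28:32,1,1,1
acne,84:28,1,1,1
thyroid_disorder,68:36,1,1,1
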