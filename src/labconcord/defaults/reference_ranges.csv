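institution,analyte,age_group,low,high,unit
site_a,creatinine,infant,10,35,umol/L
site_a,potassium,infant,3.5,5.5,mmol/L
site_a,glucose,infant,3.9,7.8,mmol/L
site_a,sodium,infant,135,145,mmol/L
site_a,anc,infant,1.5,8.5,10^9/L
site_a,hemoglobin,infant,110,160,g/L
site_a,platelets,infant,150,400,10^9/L
site_a,creatinine,toddler,15,40,umol/L
site_a,potassium,toddler,3.5,5.5,mmol/L
site_a,glucose,toddler,3.9,7.8,mmol/L
site_a,sodium,toddler,135,145,mmol/L
site_a,anc,toddler,1.5,8.5,10^9/L
site_a,hemoglobin,toddler,110,160,g/L
site_a,platelets,toddler,150,400,10^9/L
site_a,creatinine,early_childhood,20,50,umol/L
site_a,potassium,early_childhood,3.5,5.5,mmol/L
site_a,glucose,early_childhood,3.9,7.8,mmol/L
site_a,sodium,early_childhood,135,145,mmol/L
site_a,anc,early_childhood,1.5,8.5,10^9/L
site_a,hemoglobin,early_childhood,110,160,g/L
site_a,platelets,early_childhood,150,400,10^9/L
site_a,creatinine,middle_childhood,25,60,umol/L
site_a,potassium,middle_childhood,3.5,5.5,mmol/L
site_a,glucose,middle_childhood,3.9,7.8,mmol/L
site_a,sodium,middle_childhood,135,145,mmol/L
site_a,anc,middle_childhood,1.5,8.5,10^9/L
site_a,hemoglobin,middle_childhood,110,160,g/L
site_a,platelets,middle_childhood,150,400,10^9/L
site_a,creatinine,early_adolescence,35,80,umol/L
site_a,potassium,early_adolescence,3.5,5.5,mmol/L
site_a,glucose,early_adolescence,3.9,7.8,mmol/L
site_a,sodium,early_adolescence,135,145,mmol/L
site_a,anc,early_adolescence,1.5,8.5,10^9/L
site_a,hemoglobin,early_adolescence,110,160,g/L
site_a,platelets,early_adolescence,150,400,10^9/L
site_a,creatinine,adult,50,105,umol/L
site_a,potassium,adult,3.5,5.5,mmol/L
site_a,glucose,adult,3.9,7.8,mmol/L
site_a,sodium,adult,135,145,mmol/L
site_a,anc,adult,1.5,8.5,10^9/L
site_a,hemoglobin,adult,110,160,g/L
site_a,platelets,adult,150,400,10^9/L
site_b,creatinine,infant,10,35,umol/L
site_b,potassium,infant,3.5,5.4,mmol/L
site_b,glucose,infant,3.9,7.8,mmol/L
site_b,sodium,infant,135,145,mmol/L
site_b,anc,infant,1.5,8.5,10^9/L
site_b,hemoglobin,infant,115,160,g/L
site_b,platelets,infant,160,400,10^9/L
site_b,creatinine,toddler,15,40,umol/L
site_b,potassium,toddler,3.5,5.4,mmol/L
site_b,glucose,toddler,3.9,7.8,mmol/L
site_b,sodium,toddler,135,145,mmol/L
site_b,anc,toddler,1.5,8.5,10^9/L
site_b,hemoglobin,toddler,115,160,g/L
site_b,platelets,toddler,160,400,10^9/L
site_b,creatinine,early_childhood,20,50,umol/L
site_b,potassium,early_childhood,3.5,5.4,mmol/L
site_b,glucose,early_childhood,3.9,7.8,mmol/L
site_b,sodium,early_childhood,135,145,mmol/L
site_b,anc,early_childhood,1.5,8.5,10^9/L
site_b,hemoglobin,early_childhood,115,160,g/L
site_b,platelets,early_childhood,160,400,10^9/L
site_b,creatinine,middle_childhood,25,60,umol/L
site_b,potassium,middle_childhood,3.5,5.4,mmol/L
site_b,glucose,middle_childhood,3.9,7.8,mmol/L
site_b,sodium,middle_childhood,135,145,mmol/L
site_b,anc,middle_childhood,1.5,8.5,10^9/L
site_b,hemoglobin,middle_childhood,115,160,g/L
site_b,platelets,middle_childhood,160,400,10^9/L
site_b,creatinine,early_adolescence,35,80,umol/L
site_b,potassium,early_adolescence,3.5,5.4,mmol/L
site_b,glucose,early_adolescence,3.9,7.8,mmol/L
site_b,sodium,early_adolescence,135,145,mmol/L
site_b,anc,early_adolescence,1.5,8.5,10^9/L
site_b,hemoglobin,early_adolescence,115,160,g/L
site_b,platelets,early_adolescence,160,400,10^9/L
site_b,creatinine,adult,50,105,umol/L
site_b,potassium,adult,3.5,5.4,mmol/L
site_b,glucose,adult,3.9,7.8,mmol/L
site_b,sodium,adult,135,145,mmol/L
site_b,anc,adult,1.5,8.5,10^9/L
site_b,hemoglobin,adult,115,160,g/L
site_b,platelets,adult,160,400,10^9/L
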