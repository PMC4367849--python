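study_id,species,tumor,diet_code,n_subjects,days_on_diet,glucose_mM,ketone_mM,ketone_source,printed_gki,outcome
1,human,Anaplastic astrocytoma,KD-UR,1,0,5.5,0.2,blood,27.5,No response to standard chemotherapy
1,human,Anaplastic astrocytoma,KD-UR,1,56,5.0,4.6,blood,1.1,FDG uptake at tumor site decreased by 21.77%; tumor margins unchanged
1,human,Cerebellar astrocytoma,KD-UR,1,0,5.5,0.2,blood,27.5,Tumor resected; diet initiated under standard chemotherapy after radiologic stability
1,human,Cerebellar astrocytoma,KD-UR,1,56,4.0,5.5,blood,0.7,FDG uptake at tumor site decreased by 21.84%
2,human,Glioblastoma,KD-R,1,0,7.5,0.2,urine,37.5,Incomplete surgical resection; chemotherapy and radiation concurrent with diet
2,human,Glioblastoma,KD-R,1,21,3.5,2.5,urine,1.4,No evidence of tumor by MRI after concurrent therapy
3,mouse,CT-2A astrocytoma,SD-UR,7,13,9.1,0.6,blood,15.2,Tumor dry weight: 55 +/- 15 mg
3,mouse,CT-2A astrocytoma,SD-R,6,13,5.2,1.4,blood,3.7,Tumor dry weight: 7 +/- 7 mg
3,mouse,CT-2A astrocytoma,KD-UR,14,13,11.4,1.0,blood,11.4,Tumor dry weight: 70 +/- 15 mg
3,mouse,CT-2A astrocytoma,KD-R,6,13,5.7,1.3,blood,4.4,Tumor dry weight: 14 +/- 8 mg
4,mouse,CT-2A astrocytoma,SD-UR,12-14,8,14.0,0.2,blood,70.0,Tumor dry weight: 95 +/- 25 mg
4,mouse,CT-2A astrocytoma,KD-UR,12-14,8,13.5,0.6,blood,22.5,Tumor dry weight: 90 +/- 15 mg
4,mouse,CT-2A astrocytoma,KD-R,12-14,8,8.0,1.8,blood,4.4,Tumor dry weight: 35 +/- 5 mg
4,mouse,U87-MG glioma xenograft,SD-UR,12-14,8,11.5,0.5,blood,23.0,Tumor dry weight: 60 +/- 10 mg
4,mouse,U87-MG glioma xenograft,KD-UR,12-14,8,11.5,1.2,blood,9.6,Tumor dry weight: 60 +/- 7 mg
4,mouse,U87-MG glioma xenograft,KD-R,12-14,8,5.5,3.0,blood,1.8,Tumor dry weight: 37 +/- 5 mg
5,mouse,GL261 glioma,SD-UR,19,13,10.0,0.2,blood,50.0,Median survival: 23 days
5,mouse,GL261 glioma,KD-UR,19,13,8.9,1.4,blood,6.4,Median survival: 28 days
5,mouse,GL261 glioma,SD-UR+Rad,11,13,9.7,0.3,blood,32.3,Median survival: 41 days
5,mouse,GL261 glioma,KD-UR+Rad,11,13,9.7,1.7,blood,5.7,Median survival: 200+ days
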