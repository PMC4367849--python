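label,glucose_mM,glucose_sem,ketone_mM,ketone_sem,printed_gki,printed_gki_sem,n_subjects
AL,11.2,0.6,0.7,0.09,15.3,0.9,3-7
CR,8.3,0.8,1.32,0.1,6.5,0.9,3-7
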