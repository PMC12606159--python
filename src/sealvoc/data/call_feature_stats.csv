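vocal_type,n,DUR_mean,DUR_sd,DUR90_mean,DUR90_sd,F5_mean,F5_sd,F25_mean,F25_sd,Fcenter_mean,Fcenter_sd,BDW50_mean,BDW50_sd,F75_mean,F75_sd,F95_mean,F95_sd,BDW90_mean,BDW90_sd,Fpeak_mean,Fpeak_sd,AE_mean,AE_sd,SNRNIST_mean,SNRNIST_sd,harmonics_present,n_harmonics_mean,n_harmonics_sd
Croak,82,0.33,0.12,0.18,0.08,137,46,198,39,233,46,77,81,275,72,363,94,226,118,230,63,4.0,0.7,21,3,absent,,
Growl,102,2.94,1.44,2.29,1.17,138,48,201,34,237,49,79,47,280,63,387,90,249,97,246,64,4.2,0.7,19,5,absent,,
GrowlRumbleWhoop,7,3.25,1.35,2.76,1.17,105,23,162,33,229,26,117,19,279,32,410,73,306,79,158,48,4.9,0.6,24,4,absent,,
Moan,40,0.67,0.32,0.49,0.22,36,15,59,12,78,19,44,42,103,46,249,202,212,206,80,24,3.3,0.7,22,4,present,5,2
MoanGrowl,24,4.01,1.54,3.17,1.19,94,55,168,78,245,79,137,92,306,91,425,74,331,85,188,104,4.5,0.6,20,4,present,4,2
MoanGrowlRumbleWhoop,5,3.00,1.05,2.39,1.16,77,51,152,85,237,97,159,61,312,111,450,105,373,137,277,186,4.8,0.5,26,3,present,4,1
MoanHumGrowl,5,2.94,0.61,2.43,0.66,124,29,176,8,192,13,54,47,230,53,293,102,169,93,188,8,3.6,0.7,20,3,present,3,2
MoanWhine,8,1.17,0.37,0.95,0.32,45,8,83,59,132,77,135,63,218,62,379,126,334,127,151,96,4.1,0.4,19,2,present,4,2
MoanWhoop,7,1.79,0.80,1.46,0.68,44,6,74,19,107,27,94,75,167,89,316,125,273,130,144,118,4.1,0.7,23,3,present,4,1
Whoop,114,0.14,0.05,0.08,0.03,162,56,227,52,273,66,95,56,322,84,408,130,246,138,270,86,4.4,0.6,22,3,absent,,
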