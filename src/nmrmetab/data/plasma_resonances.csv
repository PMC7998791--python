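metabolite,delta_ppm,multiplicity,j_hz,rel_amplitude,linewidth_ppm
Total TAGs,0.92,broad,,413,0.02
Isoleucine,0.926,t,7.4,82,0.002
Leucine,0.949,t,7.4,108,0.002
Valine,0.98,d,7.0,226,0.002
Isoleucine,0.997,d,7.0,118,0.002
Valine,1.03,d,7.0,253,0.002
3-AIB,1.19,d,7.3,40,0.002
Total TAGs,1.20,broad,,599,0.025
Lactate,1.32,d,6.9,501,0.002
Threonine,1.335,d,6.6,35,0.002
Alanine,1.48,d,7.2,382,0.002
Total TAGs,1.55,broad,,157,0.02
Arg/Lys protein residues,1.74,m,,94,0.004
Acetate,1.92,s,,198,0.002
APG-I,2.03,broad,,281,0.02
APG-II,2.07,broad,,386,0.02
Glutamine,2.12,m,,122,0.004
Total TAGs,2.21,m,,111,0.004
Glutamate,2.34,m,,90,0.004
Glutamine,2.43,m,,169,0.004
Citrate,2.53,dd,16.0,107,0.002
3-AIB,2.60,m,,30,0.004
Total TAGs,2.75,d,6.0,89,0.002
Albumin lysine residues,2.97,broad,,82,0.02
Creatinine,3.02,s,,151,0.002
HDL-PLs,3.19,broad,,459,0.02
Glucose,3.22,m,,478,0.004
Taurine,3.39,m,,279,0.004
Glucose,3.41,m,,463,0.004
Glucose,3.43,m,,473,0.004
Glucose,3.57,m,,539,0.004
Unassigned 3.62,3.62,m,,133,0.004
Glucose,3.71,m,,434,0.004
Glucose,3.78,m,,451,0.004
Glucose,3.82,m,,444,0.004
Glucose,3.89,m,,421,0.004
Cr/PCr,3.94,s,,151,0.002
Aromatic alpha-CH,3.99,m,,80,0.004
Creatinine,4.05,s,,133,0.002
Lactate,4.14,q,6.9,135,0.002
Threonine,4.25,m,,35,0.004
Glucose,4.63,d,7.9,594,0.002
Water,4.80,s,,800,0.01
Glucose,5.25,d,3.7,341,0.002
Total TAGs,5.27,broad,,555,0.02
Urea,5.80,broad,,49,0.02
Tyrosine,6.89,m,,57,0.004
Phenylalanine,7.01,m,,34,0.004
Histidine,7.08,s,,83,0.002
Tyrosine,7.19,m,,63,0.004
Phenylalanine,7.30,m,,50,0.004
Phenylalanine,7.41,m,,30,0.004
Histidine,7.80,s,,79,0.002
PAAR,8.07,broad,,45,0.02
Formate,8.45,s,,63,0.002
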