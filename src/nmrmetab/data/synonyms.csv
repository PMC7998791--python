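3-aminoisobutyrate,3-AIB
3-aminoisobutyric acid,3-AIB
beta-aminoisobutyric acid,3-AIB
cn,Creatinine
creatinine,Creatinine
lactic acid,Lactate
l-lactic acid,Lactate
acetic acid,Acetate
citric acid,Citrate
l-valine,Valine
l-leucine,Leucine
l-isoleucine,Isoleucine
l-alanine,Alanine
l-glutamine,Glutamine
l-glutamic acid,Glutamate
glutamic acid,Glutamate
l-threonine,Threonine
l-tyrosine,Tyrosine
l-phenylalanine,Phenylalanine
l-histidine,Histidine
formic acid,Formate
d-glucose,Glucose
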