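product-a	Treatment
product-b	Treatment
curadol	Treatment
zenatex	Treatment
mabrivan	Treatment
oxitrel	Treatment
allergies	Condition
rash	Condition
headache	Condition
nausea	Condition
migraine	Condition
hypertension	Condition
diabetes	Condition
asthma	Condition
documentation	Document
publication	Document
poster	Document
article	Document
brochure	Document
monograph	Document
msl	Professional
medical advisor	Professional
medical science liaison	Professional
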