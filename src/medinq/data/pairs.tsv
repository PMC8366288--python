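adverse_effect	allergies	product-a
adverse_effect	allergies	product-b
adverse_effect	allergies	curadol
adverse_effect	allergies	zenatex
adverse_effect	allergies	mabrivan
adverse_effect	allergies	oxitrel
adverse_effect	rash	product-a
adverse_effect	rash	product-b
adverse_effect	rash	curadol
adverse_effect	rash	zenatex
adverse_effect	rash	mabrivan
adverse_effect	rash	oxitrel
adverse_effect	headache	product-a
adverse_effect	headache	product-b
adverse_effect	headache	curadol
adverse_effect	headache	zenatex
adverse_effect	headache	mabrivan
adverse_effect	headache	oxitrel
adverse_effect	nausea	product-a
adverse_effect	nausea	product-b
adverse_effect	nausea	curadol
adverse_effect	nausea	zenatex
adverse_effect	nausea	mabrivan
adverse_effect	nausea	oxitrel
adverse_effect	migraine	product-a
adverse_effect	migraine	product-b
adverse_effect	migraine	curadol
adverse_effect	migraine	zenatex
adverse_effect	migraine	mabrivan
adverse_effect	migraine	oxitrel
adverse_effect	hypertension	product-a
adverse_effect	hypertension	product-b
adverse_effect	hypertension	curadol
adverse_effect	hypertension	zenatex
adverse_effect	hypertension	mabrivan
adverse_effect	hypertension	oxitrel
adverse_effect	diabetes	product-a
adverse_effect	diabetes	product-b
adverse_effect	diabetes	curadol
adverse_effect	diabetes	zenatex
adverse_effect	diabetes	mabrivan
adverse_effect	diabetes	oxitrel
adverse_effect	asthma	product-a
adverse_effect	asthma	product-b
adverse_effect	asthma	curadol
adverse_effect	asthma	zenatex
adverse_effect	asthma	mabrivan
adverse_effect	asthma	oxitrel
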