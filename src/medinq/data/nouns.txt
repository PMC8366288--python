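action
allergies
article
asthma
brochure
case
cases
clinic
complaint
data
details
device
diabetes
documentation
dose
doses
education
effect
effects
evidence
form
formulation
half-life
headache
help
hypertension
information
injection
interaction
label
mechanism
message
migraine
monograph
nausea
pack
patient
patients
pen
poster
pregnancy
price
product
publication
rash
rate
references
regimen
region
reimbursement
response
room
sample
samples
side
stock
study
supply
tablet
temperature
treatment
trial
trials
week
world
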