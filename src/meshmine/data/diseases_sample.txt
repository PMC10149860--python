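# Small default disease list for tests and demos.
# A full curated disease vocabulary should be supplied by the user.
Cerebrovascular Disease
Obesity
Asthma
Hypertension
Diabetes
Dementia
Myocardial Infarction
Coronary Artery Disease
Epilepsy Syndrome
Schizophrenia
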