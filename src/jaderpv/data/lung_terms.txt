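# Default lung-toxicity event set: 29 MedDRA-style preferred terms,
# one per line, in descending order of reported bevacizumab case counts
# in JADER (April 2004 - March 2021).  Lines starting with '#' are ignored.
Interstitial lung disease
Pneumonia
Pulmonary embolism
Pulmonary artery thrombosis
Pneumonitis
Lung disorder
Respiratory failure
Dyspnoea
Aspiration pneumonia
Cardiorespiratory arrest
Pneumocystis jirovecii pneumonia
Acute respiratory distress syndrome
Pulmonary haemorrhage
Pulmonary alveolar haemorrhage
Pneumonia bacterial
Pulmonary infarction
Pulmonary thrombosis
Pulmonary tuberculosis
Pulmonary oedema
Acute respiratory failure
Pulmonary hypertension
Eosinophilic pneumonia
Pulmonary cavitation
Pulmonary fibrosis
Lung abscess
Idiopathic pulmonary fibrosis
Organising pneumonia
Pulmonary venous thrombosis
Acute pulmonary oedema
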