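# Adapted LIBRA factor weights (meta-analysis relative-risk derived).
# Negative weights are protective, positive weights are harmful.
version: 1
weights:
  mediterranean_diet: -1.7
  low_moderate_alcohol: -1.0
  physical_inactivity: 1.1
  smoking: 1.5
  obesity: 1.6
  hypertension: 1.6
  high_cholesterol: 1.4
  type2_diabetes: 1.3
  heart_disease: 1.0
  chronic_kidney_disease: 1.1
  depression: 2.1
  cognitive_activity: -3.2
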