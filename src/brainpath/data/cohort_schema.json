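{
  "schema_version": 1,
  "description": "Column dictionary for the per-participant phenotype table consumed and produced by brainpath.",
  "columns": {
    "id": {"type": "integer", "description": "participant identifier"},
    "age": {"type": "number", "units": "years", "description": "calendar age at MRI"},
    "sex": {"type": "string", "levels": ["male", "female"]},
    "education": {"type": "string", "levels": ["low", "medium", "high"]},
    "glucose_status": {"type": "string", "levels": ["normal", "prediabetes", "t2dm", "other"]},
    "diet_score": {"type": "integer", "range": [0, 9], "description": "Mediterranean diet score; >= 6 is adherence"},
    "alcohol_g_week": {"type": "number", "units": "g/week", "description": "self-reported alcohol intake"},
    "mvpa_min_week": {"type": "number", "units": "min/week", "description": "moderate-to-vigorous physical activity"},
    "smoking_status": {"type": "string", "levels": ["never", "former", "current"]},
    "bmi": {"type": "number", "units": "kg/m2"},
    "sbp": {"type": "number", "units": "mmHg", "description": "average systolic blood pressure"},
    "dbp": {"type": "number", "units": "mmHg", "description": "average diastolic blood pressure"},
    "antihypertensive_med": {"type": "integer", "levels": [0, 1]},
    "total_cholesterol": {"type": "number", "units": "mmol/L"},
    "fasting_glucose": {"type": "number", "units": "mmol/L"},
    "ogtt_glucose": {"type": "number", "units": "mmol/L", "description": "2-h oral glucose tolerance test value"},
    "diabetes_med": {"type": "integer", "levels": [0, 1]},
    "heart_disease": {"type": "integer", "levels": [0, 1], "description": "history of cardiovascular disease, stroke excluded"},
    "egfr": {"type": "number", "units": "mL/min/1.73m2"},
    "albuminuria": {"type": "integer", "levels": [0, 1], "description": "micro- or macroalbuminuria"},
    "phq9": {"type": "integer", "range": [0, 27]},
    "mini_depression": {"type": "integer", "levels": [0, 1], "description": "current depressive episode on structured interview"},
    "csf_ml": {"type": "number", "units": "mL", "description": "cerebrospinal fluid volume"},
    "gm_ml": {"type": "number", "units": "mL", "description": "grey matter volume"},
    "wm_ml": {"type": "number", "units": "mL", "description": "white matter volume"},
    "wmh_ml": {"type": "number", "units": "mL", "description": "white matter hyperintensity volume"},
    "cmb_count": {"type": "integer", "minimum": 0, "description": "cerebral microbleed count"},
    "lacunar_infarct_count": {"type": "integer", "minimum": 0},
    "node_degree": {"type": "number", "description": "whole-brain average node degree after the >=2-tract rule"},
    "z_memory": {"type": "number", "description": "memory domain z-score"},
    "z_speed": {"type": "number", "description": "information processing speed domain z-score"},
    "z_executive": {"type": "number", "description": "executive function and attention domain z-score"},
    "months_since_mri": {"type": "number", "units": "months", "description": "time between imaging and cognitive assessment"}
  }
}
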