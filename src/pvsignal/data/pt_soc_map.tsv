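pt	soc
SNEEZING	Respiratory, thoracic and mediastinal disorders
COUGH	Respiratory, thoracic and mediastinal disorders
THROAT IRRITATION	Respiratory, thoracic and mediastinal disorders
NASAL DISCOMFORT	Respiratory, thoracic and mediastinal disorders
RHINORRHOEA	Respiratory, thoracic and mediastinal disorders
EPISTAXIS	Respiratory, thoracic and mediastinal disorders
OROPHARYNGEAL PAIN	Respiratory, thoracic and mediastinal disorders
NASAL CONGESTION	Respiratory, thoracic and mediastinal disorders
NASAL DRYNESS	Respiratory, thoracic and mediastinal disorders
DYSPNOEA	Respiratory, thoracic and mediastinal disorders
RHINALGIA	Respiratory, thoracic and mediastinal disorders
EYE IRRITATION	Eye disorders
LACRIMATION INCREASED	Eye disorders
EYE PAIN	Eye disorders
OCULAR HYPERAEMIA	Eye disorders
VISION BLURRED	Eye disorders
EYE PRURITUS	Eye disorders
PHOTOPHOBIA	Eye disorders
EYE SWELLING	Eye disorders
HEADACHE	Nervous system disorders
DIZZINESS	Nervous system disorders
MIGRAINE	Nervous system disorders
INSOMNIA	Psychiatric disorders
ABNORMAL DREAMS	Psychiatric disorders
ANXIETY	Psychiatric disorders
NAUSEA	Gastrointestinal disorders
DRY MOUTH	Gastrointestinal disorders
VOMITING	Gastrointestinal disorders
RASH	Skin and subcutaneous tissue disorders
PRURITUS	Skin and subcutaneous tissue disorders
URTICARIA	Skin and subcutaneous tissue disorders
ERYTHEMA	Skin and subcutaneous tissue disorders
FATIGUE	General disorders and administration site conditions
PAIN	General disorders and administration site conditions
FEELING ABNORMAL	General disorders and administration site conditions
PRODUCT AFTER TASTE	Product issues
HYPERSENSITIVITY	Immune system disorders
DRUG HYPERSENSITIVITY	Immune system disorders
VERTIGO	Ear and labyrinth disorders
TINNITUS	Ear and labyrinth disorders
SINUSITIS	Infections and infestations
NASOPHARYNGITIS	Infections and infestations
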