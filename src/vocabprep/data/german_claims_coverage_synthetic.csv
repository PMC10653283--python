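vocabulary_name,category,note
ICD-10-GM,available_in_athena,
OPS,available_in_athena,
ATC,available_in_athena,
HMK,athena_ready,
HPNR,athena_ready,
PIA,athena_ready,
EBM,athena_ready,
Inpatient charge types,athena_ready,
Outpatient charge types,athena_ready,
ASV,interim_mapping,
Diagnosis type (inpatient),interim_mapping,
Diagnosis type (outpatient),interim_mapping,
Provider specialty,interim_mapping,
Admission reason,interim_mapping,
Discharge reason,interim_mapping,
Admission type,interim_mapping,
Care level,interim_mapping,
Specialty department,interim_mapping,
G-DRG,not_available,license restriction
PZN,not_available,license restriction
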