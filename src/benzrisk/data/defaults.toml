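# Illustrative default PBPK parameter set for a 6-12-year-old child.
# Every value here is a plausible, literature-informed placeholder intended
# to exercise the pipeline; replace with vetted literature values before any
# substantive use. Each numeric key admits a sibling `<key>_source` string
# recording provenance.

[compartments.richly_perfused]
Q = 1.20
Q_source = "illustrative default — ~44% of child cardiac output"
V = 1.4
V_source = "illustrative default — ~5% of body weight, 27 kg child"
P = 1.6
P_source = "illustrative default — benzene richly-perfused:blood partition"

[compartments.fat]
Q = 0.14
Q_source = "illustrative default — ~5% of child cardiac output"
V = 4.0
V_source = "illustrative default — ~15% of body weight, 27 kg child"
P = 54.0
P_source = "illustrative default — benzene fat:blood partition"

[compartments.poorly_perfused]
Q = 0.70
Q_source = "illustrative default — ~25% of child cardiac output"
V = 16.0
V_source = "illustrative default — ~60% of body weight, 27 kg child"
P = 2.0
P_source = "illustrative default — benzene muscle:blood partition"

[compartments.liver]
Q = 0.72
Q_source = "illustrative default — ~26% of child cardiac output"
V = 0.7
V_source = "illustrative default — ~2.6% of body weight, 27 kg child"
P = 1.7
P_source = "illustrative default — benzene liver:blood partition"

[metabolism]
Vmax = 0.30
Vmax_source = "illustrative default — adult hepatic Vmax scaled to child size"
Km = 0.35
Km_source = "illustrative default — benzene hepatic Michaelis constant, mg/L"
t_half = 30.0
t_half_source = "illustrative default — benzene blood half-life, min (unused by the steady-state chain)"
f_ttma = 0.039
f_ttma_source = "illustrative default — single-digit-percent urinary tt-MA yield; dominant scaling uncertainty"

[physiology]
age = 9.0
age_source = "midpoint of the 6-12-year study age range"
body_weight = 27.0
body_weight_source = "illustrative default — reference weight near age 9"
P_blood_air = 8.19
P_blood_air_source = "illustrative default — benzene human blood:air partition"
Q_alv = 2.0
Q_alv_source = "illustrative default — child alveolar ventilation, L/min"
Q_card = 2.76
Q_card_source = "illustrative default — child cardiac output, L/min"
urine_void_volume = 0.15
urine_void_volume_source = "illustrative default — child bladder void volume, L"
micturition_interval = 180.0
micturition_interval_source = "three hours between successive micturitions (model assumption)"
urinary_creatinine = 1.0
urinary_creatinine_source = "illustrative default — child spot-urine creatinine, g/L"

[constants]
mw_benzene = 78.11
mw_benzene_source = "molar mass of benzene, g/mol"
mw_ttma = 142.11
mw_ttma_source = "molar mass of trans,trans-muconic acid (C6H6O4), g/mol"
molar_volume = 24.45
molar_volume_source = "ideal-gas molar volume at 25 degC, 1 atm, L/mol"
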