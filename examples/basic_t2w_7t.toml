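# T2-weighted 7 T DANTE-SPACE protocol: 300 x 10 deg preparation pulses,
# 73-echo variable-flip-angle readout, equivalent TE 165 ms, TR 2.62 s.
# Basic tissue models: constant literature velocities, no velocity spread,
# pulsation, diffusion, trajectory or B1+ variation.

[protocol]
tr_ms = 2620.0

[dante]
n_pulses = 300
flip_deg = 10.0
spacing_ms = 1.4
shift = 2
rf_phase_scheme = "alternating"

[space]
n_refocus = 73
te_equiv_ms = 165.0
k_ordering = "linear"

[space.prescribed]
start_amplitude = 0.40
shoulder_ms = 180.0
power = 1.5

[execution]
seed = 7

[tissues.vw]
t1_ms = 1628.0
t2_ms = 46.0
pd = 0.72
motion = "static"
n_repetitions = 2

[tissues.csf]
t1_ms = 4019.0
t2_ms = 311.0
pd = 1.0
motion = "basic"        # constant 0.37 cm/s plug flow
diffusion = false
n_repetitions = 2

[tissues.blood]
t1_ms = 2290.0
t2_ms = 100.0
pd = 1.0
motion = "basic"        # constant 24 cm/s inflow, readout nearly perpendicular
diffusion = false
n_repetitions = 1
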