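"""Simulate one heel's stance phase and recover its material properties.

Builds the reference heel (unloaded thickness 15.99 mm, elastic modulus
192.55 kPa, viscous modulus 43.9 kPa*s, peak strain 0.685 — the reported
time-zero medians), forward-simulates a 0.6 s stance at 50 Hz with 1%
stress measurement noise, and runs the full analysis: contact -> primary
thickness -> strain/stress/strain-rate -> Kelvin-Voigt fit -> hysteresis.
"""

from heelpad import GaitConfig, HeelParams, analyze_trial, simulate_stance

heel = HeelParams(
    subject_id="DEMO",
    side="left",
    condition="time_zero",
    age=46.5,
    bmi=24.6,
    h0_true=15.99,
    E_true=192.55,
    eta_true=43.9,
    peak_strain_true=0.685,
    noise_cv=0.01,
)
trial = simulate_stance(heel, GaitConfig(), seed=1)
props = analyze_trial(trial)

print(f"frames analyzed        : {props.fit.n_frames}")
print(f"primary thickness (mm) : {props.primary_thickness:.2f}  (true {heel.h0_true})")
print(f"peak strain            : {props.peak_strain:.3f}  (true {heel.peak_strain_true})")
print(f"peak stress (kPa)      : {props.peak_stress:.2f}")
print(f"elastic modulus (kPa)  : {props.E:.2f}  (true {heel.E_true})")
print(f"viscous modulus (kPa*s): {props.eta:.2f}  (true {heel.eta_true})")
print(f"EDR (%)                : {props.edr:.2f}")
print(f"fit R^2                : {props.fit.r_squared:.5f}")
# The moduli land within ~1% of truth at 1% stress noise; EDR is the
# fraction of loading work lost to the viscous dashpot over the cycle.
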