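"""Energy dissipation from the stress-strain hysteresis loop.

Two loops: a hand-checkable parallelogram (loading sigma = 200*eps up to
eps = 0.5, unloading offset by -20 kPa) whose EDR is exactly 40%, and a
Kelvin-Voigt loop at the reference heel's moduli, where the dissipated
fraction emerges from the viscous term eta*eps*epsdot.
"""

import numpy as np

from heelpad import energy_dissipation_rate

up = np.linspace(0.0, 0.5, 6)
dn = np.linspace(0.5, 0.0, 6)
eps = np.concatenate([up, dn])
sigma = np.concatenate([200 * up, 200 * dn - 20])
d, edr = energy_dissipation_rate(sigma, eps)
print(f"parallelogram: dissipation = {d:.3f} kPa, EDR = {edr:.3f} %")
# loop area 20 kPa x 0.5 strain = 10 kPa; loading area 25 kPa -> 40%

t = np.linspace(0.0, 0.6, 31)
eps_kv = 0.685 * np.sin(np.pi * t / 0.6) ** 2
epsdot = np.gradient(eps_kv, t)
sigma_kv = 192.55 * eps_kv + 43.9 * eps_kv * epsdot
d_kv, edr_kv = energy_dissipation_rate(sigma_kv, eps_kv)
print(f"Kelvin-Voigt : dissipation = {d_kv:.2f} kPa, EDR = {edr_kv:.2f} %")
# At these moduli and a 0.6 s stance most of the loading work is lost in
# the dashpot; EDR falls as eta (or the strain rate) falls.
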