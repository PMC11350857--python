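"""Closed-form concentration profile for one ICU patient.

A 2 g loading dose over 30 min followed by a 6 g/day continuous infusion,
for a patient with the typical clearance and volume.  Prints the profile at
a few clinically interesting times, the half-life, steady state, and the
delay until the 35 mg/L target floor is reached.
"""

from ceftazpk import (
    IndividualParameters,
    Regimen,
    concentration,
    half_life,
    steady_state_concentration,
    time_to_threshold,
)

params = IndividualParameters(CL=4.45, V=88.0)
regimen = Regimen.loading_plus_continuous(loading_mg=2000.0, daily_mg=6000.0)

print(f"half-life: {half_life(params):.1f} h")
print(f"steady state: {steady_state_concentration(250.0, params.CL):.1f} mg/L")

for t in (0.5, 6.0, 24.0, 48.0, 96.0):
    c = concentration(regimen, params, [t])[0]
    print(f"C({t:5.1f} h) = {c:5.1f} mg/L")

delay = time_to_threshold(regimen, params, 35.0)
print(f"time to reach 35 mg/L: {delay:.1f} h")

delay4 = time_to_threshold(Regimen.loading_plus_continuous(4000.0, 6000.0), params, 35.0)
print(f"with a 4 g loading dose instead: {delay4:.1f} h")
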