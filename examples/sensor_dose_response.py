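"""Characterize a sensor strain: time course, steady-state curve, Hill fit.

Simulates the beta-estradiol-repressed GFP sensor across a dose range,
extracts the endpoint dose-response and fits a four-parameter Hill curve,
printing the EC50 (the input concentration at half-maximal response), the
Hill coefficient (steepness / cooperativity) and the ON/OFF fold-change
(dynamic range) — the three numbers that summarize a sensor.
"""
import numpy as np

from yeastcons import default_library, dose_response, fit_hill_dose_response

library = default_library()
sensor = library["bE_rep_GFP"]

doses = np.concatenate([[0.0], np.geomspace(0.01, 100.0, 12)])  # nM
dr = dose_response(sensor.params, sensor.transfer[0], doses, read_time=24.0)

print(f"strain {sensor.id}: {sensor.inputs[0]} {sensor.transfer[0]} -> GFP")
for d, y in zip(dr.dose, dr.response):
    print(f"  {d:8.2f} nM -> {y:7.1f} a.u.")

fit = fit_hill_dose_response(dr)
print(f"\nHill fit: EC50 = {fit.ec50:.2f} nM, n = {fit.n:.2f}, "
      f"fold-change = {fit.fold_change:.1f}x ({fit.mode} in dose)")
print("EC50 is where the response is halfway between its floor and ceiling;")
print("n > 1 indicates an ultrasensitive (switch-like) transition.")
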