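"""Simulate one injection of an erianin-containing extract and inspect it.

An extract of 0.5 g dried *Dendrobium chrysotoxum* eluted into 10 mL
carries 425 mg/kg of erianin, i.e. 21.25 ug/mL in the vial.  The SIM
trace at m/z 341 (the [M+Na]+ channel) shows one Gaussian peak at the
compound's retention time whose integrated area follows the response
model area = slope * concentration.
"""

import phenoscreen as ps

library = ps.make_compound_library()
scenario = ps.ScenarioConfig(compounds={"ER": 425.0}, noise_level=0.0, seed=1)
run, truth = ps.simulate_run(scenario, library)

trace = run.sim_trace(341, "positive")
peak = ps.detect_peaks(trace)[0]

print(f"true extract concentration : {truth.concentration('ER'):.2f} ug/mL")
print(f"true SIM area              : {truth.area('ER'):.0f} counts*min")
print(f"detected peak apex         : {peak.apex_rt:.2f} min  (library RT 7.12)")
print(f"integrated area            : {peak.area:.0f} counts*min")
print(f"relative integration error : {abs(peak.area - truth.area('ER')) / truth.area('ER'):.2e}")
# The apex sits at erianin's retention time and the trapezoidal area
# reproduces the generating response to a few parts per million.
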