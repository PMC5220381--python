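"""Simulate the relay neuron's three signature firing behaviours.

Builds the default thalamocortical relay cell, drives it with the standard
square-wave sensorimotor input in the normal and Parkinsonian states, and
releases it from a hyperpolarizing pulse.  Prints spike counts per condition:
faithful 1:1 relay in the normal state, multi-spike burst events under
pallidal inhibition, and a rebound burst after release.
"""

import numpy as np

import thalatrack.model as tc

params = tc.default_parameters()
rest = tc.rest_state(params)
print(f"resting state: V = {rest.v:.2f} mV, h = {rest.h:.3f}, w = {rest.w:.4f}")

square = tc.StimulusSpec(kind="square_wave", rho_sm=25.0, delta_sm=5.0, i_sm=5.0)
for mode in ("normal", "parkinsonian"):
    traj = tc.simulate(params, tc.GpiInputSpec(mode=mode), square, 1000.0)
    spikes = tc.detect_spikes(traj)
    per_pulse = [np.sum((spikes >= 25 * k) & (spikes < 25 * (k + 1))) for k in range(40)]
    print(f"{mode:>13}: {len(spikes)} spikes over 40 pulses "
          f"(single-spike pulses: {sum(c == 1 for c in per_pulse)}, "
          f"burst pulses: {sum(c > 1 for c in per_pulse)})")

hold = tc.simulate(params, tc.GpiInputSpec(),
                   tc.StimulusSpec(kind="constant", level=-0.6), 150.0, initial=rest)
release = hold.state_at(len(hold) - 1)
post = tc.simulate(params, tc.GpiInputSpec(), tc.StimulusSpec(kind="none"),
                   120.0, initial=release)
n50 = np.sum(tc.detect_spikes(post) < 50.0)
print(f"rebound: w rose to {release.w:.3f} during hyperpolarization; "
      f"{n50} spikes within 50 ms of release")
print("The burst pulses and the rebound cluster are the T-current signature "
      "that distinguishes the Parkinsonian relay failure from faithful relay.")
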