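"""Reconstruct the hidden gating variables from a noisy voltage recording.

Simulates the relay cell under the square-wave protocol, contaminates the
voltage with 1 mV Gaussian measurement noise, and runs the sigma-point filter
(internal model: the piecewise-linear CETC variant) to recover the sodium
inactivation gate h, the calcium gate w, and the pallidal current.  Prints
the post-burn-in root-mean-square errors per variable.
"""

from thalatrack import experiments as ex

result = ex.run_estimation(mode="normal", q=5e-5, r=5.0, seed=1, duration=2000.0)

print("post-burn-in CF_rmse per state component:")
for name, value in result.cf_rmse.items():
    print(f"  {name:>6}: {value:.4f}")
print("V is tracked to a fraction of the noise floor; h and w — the "
      "experimentally inaccessible channel states — come back to within a few "
      "percent of their dynamic range from the voltage alone, and i_ext is "
      "the residual error of the estimated pallidal current (zero in the "
      "normal state).")
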