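"""Blind estimation against a cell the filter has never seen.

The plant's conductances and half-activation voltages are jittered by +/-10%
and it is driven by an irregular gamma pulse train; the filter knows neither
the parameters nor the input and sees only the noisy voltage.  Prints the
slow-gate error against the naive quasi-steady readout w_inf(V_obs) and the
recovered pallidal current level.
"""

from thalatrack import experiments as ex

for mode, r, q in (("normal", 1.0, 0.005), ("parkinsonian", 0.5, 0.5)):
    res = ex.double_blind(seed=3, mode=mode, r=r, q=q)
    ratio = res.extras["cf_w_baseline"] / res.cf_rmse["w"]
    print(f"{mode:>13}: CF_rmse(w) = {res.cf_rmse['w']:.4f} "
          f"(naive baseline {res.extras['cf_w_baseline']:.4f}, "
          f"filter is {ratio:.1f}x better)")
    print(f"{'':>13}  estimated pallidal level "
          f"{res.extras['i_ext_quiet_mean']:+.3f} pA/um^2 "
          f"(true {res.extras['i_ext_quiet_true']:+.3f})")
print("In the Parkinsonian state the slow gate strays far from its "
      "quasi-steady value during rebound bursts, so model-based filtering "
      "pays off most exactly where the hidden dynamics matter.")
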