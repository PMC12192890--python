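"""Recover the feature scaling laws empirically from a parameter sweep.

Fitted log-log slopes should land near the asymptotic exponents:
f6 ~ ng (slope 1), f7 ~ ng**2 (slope 2), f10 ~ ng (slope 1); against the
displacement, f10 ~ |d| and the d-sensitive component of f7 ~ |d|.
"""

from gradtex import fit_scaling_exponent, run_sweep
from gradtex.validate import sv_baseline

by_ng = run_sweep([32, 64, 128, 256], [1], [1], image_size=(4, 600),
                  exact_period=True)
filt = {"grad": 1, "dy": 1}
for feat, expected in [("f6", 1), ("f7", 2), ("f10", 1)]:
    fit = fit_scaling_exponent(by_ng, feat, "ng", filt)
    print(f"{feat} vs ng : fitted slope {fit.slope:6.3f}  (asymptotic {expected})")

by_d = run_sweep([256], [1], list(range(1, 9)), image_size=(4, 600),
                 exact_period=True)
fit10 = fit_scaling_exponent(by_d, "f10", "dy", {"ng": 256, "grad": 1})
fit7 = fit_scaling_exponent(by_d, "f7", "dy", {"ng": 256, "grad": 1},
                            baseline=sv_baseline(256, 1))
print(f"f10 vs |d|: fitted slope {fit10.slope:6.3f}  (asymptotic 1)")
print(f"f7  vs |d|: fitted slope {fit7.slope:6.3f}  (asymptotic 1, after "
      "removing the d-independent pedestal)")
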