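"""Forward-model a tissue curve with the two-compartment exchange model
(2CXM) and recover the parameters by multi-start least squares.

MBF (myocardial blood flow) is the plasma flow parameter Fp in mL/min/mL.
With noiseless data the fit recovers Fp essentially exactly; with noise,
Fp remains the best-determined parameter while vp/PS/ve trade off against
each other (the optional ridge prior stabilizes them).
"""

import numpy as np

from perfusionkit.core import ConcentrationCurve, KineticParams
from perfusionkit.kinetics import fit_2cxm, solve_2cxm
from perfusionkit.phantom import gamma_variate_aif

times = np.arange(0, 60, 1.0)  # one frame per second
aif = ConcentrationCurve(times, gamma_variate_aif(t0=10, alpha=3, beta=3.5, scale=5.0, times=times))

truth = KineticParams(Fp=1.2, vp=0.06, PS=0.9, ve=0.25)
tissue = solve_2cxm(truth, aif)
print(f"tissue curve peaks at t={times[np.argmax(tissue.values)]:.0f}s "
      f"with C={tissue.values.max():.3f} (AIF peak {aif.values.max():.1f} at t=20s)")

fit = fit_2cxm(tissue, aif)
print("\nnoiseless fit (truth -> estimate):")
for name, t in zip(("Fp", "vp", "PS", "ve"), (1.2, 0.06, 0.9, 0.25)):
    print(f"  {name:>2}: {t:6.3f} -> {getattr(fit.params, name):6.3f}")
print(f"  residual norm {fit.residual_norm:.2e}")

rng = np.random.default_rng(0)
noisy = ConcentrationCurve(times, tissue.values + rng.normal(0, 0.05 * tissue.values.max(), len(times)))
plain = fit_2cxm(noisy, aif)
ridged = fit_2cxm(noisy, aif, ridge=0.01)
print(f"\nwith 5% noise:  Fp = {plain.params.Fp:.3f} (plain)  "
      f"{ridged.params.Fp:.3f} (ridge prior)  [truth 1.200]")
print("Fp is identifiable; the ridge tames nuisance-parameter trade-offs.")
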