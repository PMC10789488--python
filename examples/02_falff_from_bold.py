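"""Compute fALFF from synthetic BOLD series with a known in-band share.

Generates band-limited BOLD-like series, prints the spectral ratio on
the raw series (fALFF near 1 when all power lives inside 0.01-0.08 Hz,
near 0 when none does), and then shows the effect of nuisance cleaning:
regressing out the Friston-24 motion expansion plus WM/CSF signals
removes a broadband 26-dimensional subspace, which pulls the amplitude
ratio toward the interior — visible here because these regressors are
pure noise with respect to the signal.
"""

import numpy as np

from neurocoloc.falff import compute_falff, nuisance_regress_timeseries
from neurocoloc.simulate import generate_bold

print("raw series:")
for fraction in (1.0, 0.5, 0.0):
    ts = generate_bold(
        n_voxels=500, n_volumes=300, tr_seconds=2.0,
        band_power_fraction=fraction, seed=11,
    )
    falff = compute_falff(ts)
    print(f"  band power fraction {fraction:.1f}: "
          f"mean fALFF = {np.nanmean(falff):.3f} "
          f"(sd {np.nanstd(falff):.3f} over {ts.n_voxels} voxels)")

ts = generate_bold(500, 300, 2.0, band_power_fraction=1.0, seed=11)
cleaned = nuisance_regress_timeseries(ts, ts.nuisance_regressors())
print("\nafter nuisance regression (26 broadband regressors, all-in-band signal):")
print(f"  mean fALFF = {np.nanmean(compute_falff(cleaned)):.3f}")
print("\nThe raw ratios hit the analytic endpoints; cleaning trades a little "
      "in-band amplitude for the removed nuisance subspace.")
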