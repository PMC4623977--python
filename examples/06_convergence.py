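"""Convergence and sampling-error analysis of an occupancy time series.

Tracks the atom-averaged occupancy R_ave(k) frame by frame, compares block
means for stationarity, and estimates the asymptotic sampling error from
the block-standard-error curve and its saturation fit.
"""

import numpy as np

from pmdmembrane.convergence import (block_means, block_standard_error,
                                     fit_bse, occupancy_timeseries)
from pmdmembrane.synth import ContactPlant, SynthSpec, build_synthetic

spec = SynthSpec(
    seed=13, n_protein_atoms=4, protein_spacing=30.0, n_probes=10,
    box=(120.0, 120.0, 150.0), midplane_z=50.0, n_frames=1024,
    n_lipids_per_leaflet=16,
    contact_schedule=(ContactPlant(atom=0, probe=0, distance=0.0,
                                   probability=0.5),),
)
system, traj, _ = build_synthetic(spec)

series = occupancy_timeseries(system, traj, cutoff=0.05, window=50)
print(f"tracked atoms: {series.atoms.size}; "
      f"<R_ave> over the run: {series.R_ave.mean():.3f}")

print("block means (256-frame blocks):")
for mean, sd in block_means(series.R_ave, 256):
    print(f"  {mean:.3f} +/- {sd:.3f}")

curve = block_standard_error(series.R_ave)
fit = fit_bse(curve)
err = fit.a0 if fit.converged else float(curve.bse.max())
sem = series.R_ave.std(ddof=1) / np.sqrt(series.R_ave.size)
print(f"BSE(b=1) = {curve.bse[0]:.4f}  (= naive SEM {sem:.4f})")
print(f"BSE at the largest block: {curve.bse[-1]:.4f}")
print(f"saturation fit converged: {fit.converged}; "
      f"adopted sampling error: {err:.4f}")
print("This contact schedule is uncorrelated frame to frame, so the BSE "
      "curve is essentially flat and the saturation fit is ill-posed — the "
      "estimator then falls back to the largest observed BSE, a "
      "conservative error bar. Correlated MD data shows the curve rising "
      "to a plateau, and the fitted a0 is the honest sampling error.")
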