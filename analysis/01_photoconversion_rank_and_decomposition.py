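#!/usr/bin/env python
"""Stepwise photoconversion: rank analysis and constrained decomposition.

Generates a synthetic dark-to-light photoconversion series (20 illumination
steps, 0.2% rms noise, 2% unconverted ground state at the photostationary
end), confirms by SVD rank analysis that two components describe it, and
decomposes it into pure species spectra and mole-fraction profiles,
recovering the residual ground-state contamination of the final spectrum.
"""

import json
from pathlib import Path

import numpy as np

import photokin as pk
from photokin import synth

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

series, truth = synth.generate_photoconversion(
    n_steps=20, conversion_per_step=0.25, residual_gs=0.02,
    noise_rms=0.002, seed=1)

svd = pk.compute_svd(series)
rank = pk.estimate_rank(svd)
print(f"SVD rank analysis: {rank} significant components "
      f"(singular values {np.round(svd.W[:4], 3).tolist()} ...)")

res = pk.decompose_photoconversion(series, "fit")
print(f"fitted residual ground state: {100 * res.gs_contamination:.2f}% "
      f"(generator: {100 * truth['residual_gs']:.1f}%)")
print(f"reconstruction rms: {res.residual_rms:.4f} OD")
print(f"final mole fractions (GS, LS): "
      f"{np.round(res.mole_fractions[-1], 4).tolist()}")

np.savetxt(OUT / "photoconversion_mole_fractions.csv",
           np.column_stack([series.time_axis, res.mole_fractions]),
           delimiter=",", header="step,x_GS,x_LS", comments="")
np.savetxt(OUT / "photoconversion_species_spectra.csv",
           np.column_stack([series.wavelength_axis, res.species_spectra.T]),
           delimiter=",", header="wavelength_nm,A_GS,A_LS", comments="")
with open(OUT / "photoconversion_summary.json", "w") as fh:
    json.dump({"rank": rank,
               "gs_contamination": res.gs_contamination,
               "residual_rms_od": res.residual_rms}, fh, indent=2)
print(f"tables written to {OUT}/")
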