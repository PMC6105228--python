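#!/usr/bin/env python
"""Fit the graviproprioception and sine-law models per timepoint.

Regresses dC/dt (and LRL) on sin A and C along the organ at every frame,
compares the models by AIC and adjusted R^2, scans the LRL profiles for
sine-law segments (> 0.76 mm, R^2 > 0.95) and writes the fit tables, the
segment table and the segment beta map under results/.
"""

import numpy as np

from gravikine.config import RunConfig
from gravikine.pipeline import (_fit_table, extract_stage, fit_stage,
                                kinematics_stage, luminescence_stage)
from gravikine.plotting import render_map
from gravikine.simulate import load_fixture


def main():
    frames, _truth, manifest = load_fixture("results/recording")
    cfg = RunConfig(length=manifest["gp_params"]["length"])
    midlines, pairs = extract_stage(frames, cfg, frames.world_to_image(np.zeros(2)))
    fields, *_ = kinematics_stage(midlines, cfg)
    _profiles, lum_maps, _ = luminescence_stage(frames, midlines, pairs,
                                                fields, cfg)
    fits_dcdt, fits_lrl, segments, bmap = fit_stage(fields, lum_maps, cfg)

    _fit_table(fits_dcdt).to_csv("results/fits_dCdt.csv", index=False)
    _fit_table(fits_lrl).to_csv("results/fits_LRL.csv", index=False)
    import pandas as pd
    pd.DataFrame([dict(t=s.t, s_start=s.s_start, s_end=s.s_end,
                       beta=s.beta, r2=s.r2)
                  for segs in segments.values() for s in segs],
                 columns=["t", "s_start", "s_end", "beta", "r2"]
                 ).to_csv("results/sine_segments.csv", index=False)
    bmap.save_csv("results/map_beta_segments.csv")
    render_map(bmap, "results/map_beta_segments.png", cmap="plasma",
               title="sine-law segment beta (LRL)")

    sel = [r["selected"] for r in fits_dcdt]
    n_gp = sel.count("GP")
    print(f"dC/dt fits: GP selected at {n_gp}/{len(sel)} timepoints")

    # pooled fit over the autostraightening-onset window: per-timepoint fits
    # on one recording are unstable here because past ~1 h the curvature sits
    # on its quasi-equilibrium C ~ -(beta/gamma) sinA and the regressors are
    # nearly collinear; pooling the window frames restores identifiability
    from gravikine.model_fit import fit_gp
    d, A, Cp = fields["dCdt"], fields["A"], fields["C_pred"]
    ys, As, Cs, ss = [], [], [], []
    for i, t in enumerate(d.t):
        if not 1.0 <= t <= 2.5:
            continue
        ok = d.mask[i] & A.mask[i] & Cp.mask[i] & (d.s > 0.5)
        ys.append(d.values[i][ok]); As.append(A.values[i][ok])
        Cs.append(Cp.values[i][ok]); ss.append(d.s[ok])
    gp = fit_gp(*map(np.concatenate, (ys, As, Cs, ss)))
    print(f"pooled GP fit over t in [1.0, 2.5] h: beta = {gp.beta:.3f} "
          f"+/- {gp.beta_se:.3f}, gamma = {gp.gamma:.3f} +/- {gp.gamma_se:.3f} "
          f"(simulated: 0.400, 1.500)")
    n_seg = sum(len(v) for v in segments.values())
    print(f"LRL sine-law segments: {n_seg} across "
          f"{sum(bool(v) for v in segments.values())} frames")
    print("fit tables written under results/")


if __name__ == "__main__":
    main()
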