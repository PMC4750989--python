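"""Infer GLV parameters from a daily-sampled taxa count table.

Generates a synthetic longitudinal count table from a known 10-species
community (daily sampling, multinomial read counts, occasional perturbation
restarts), fits the log-difference ridge regression, cross-validates the
regularization weight, and ranks strongly interacting taxa by the spread of
their estimated interaction column.  A day-permuted copy serves as the
negative control.
"""

import numpy as np

from glvtypes import (MetacommunityConfig, build_regression,
                      cross_validate_lambda, generate_metacommunity,
                      permute_days, ridge_fit, sample_local_communities,
                      sis_scores, synth_timeseries)

meta = generate_metacommunity(MetacommunityConfig(n=12, alpha=1.2, seed=9))
lc = sample_local_communities(meta, q=1, p=10, seed=9)[0]
depth = 10**9
ts = synth_timeseries(lc, days=120, depth=depth, seed=1, scheme="euler",
                      count_mode="rounded", restart_every=20)

lam_opt, cv = cross_validate_lambda([ts], grid=np.logspace(-6, 1, 8),
                                    relative=False)
print(f"cross-validated regularization weight: lambda = {lam_opt:g}")

fit = ridge_fit(build_regression(ts, relative=False, count_scale=depth),
                lam_opt)
fit.taxa = list(lc.members)
err = np.linalg.norm(fit.A_hat - lc.A_local) / np.linalg.norm(lc.A_local)
print(f"relative error of the recovered interaction matrix: {err:.2e}")
print("top-3 strongly interacting taxa (column s.d. of the estimate):")
print(sis_scores(fit).head(3).round(3).to_string())

perm = permute_days(ts, seed=5)
pfit = ridge_fit(build_regression(perm, relative=False, count_scale=depth),
                 lam_opt)
perr = np.linalg.norm(pfit.A_hat - lc.A_local) / np.linalg.norm(lc.A_local)
print(f"\nday-permuted control: relative error {perr:.2f} "
      "(temporal structure destroyed, recovery fails -- but note the")
print("column-s.d. spread can stay elevated even on permuted data, so a")
print("heterogeneous ranking alone is weak evidence for real interactions)")
ratio = sis_scores(pfit)
print(f"permuted-data score heterogeneity (max/median): "
      f"{ratio.iloc[0] / ratio.median():.1f}")
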