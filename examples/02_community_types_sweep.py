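"""Community types appear as interaction-strength heterogeneity grows.

Simulates ensembles of local communities (random 80-of-100 species subsets)
to steady state, clusters the relative-abundance profiles with k-medoids
under the Jensen-Shannon distance, and reports the optimal cluster number
and mean silhouette at three heterogeneity levels.  Scaled to 150 local
communities per level so it runs in about a minute.
"""

from glvtypes import run_heterogeneity_sweep

df = run_heterogeneity_sweep(alphas=[7.0, 2.0, 1.01], replicates=1,
                             master_seed=1, n=100, q=150, p=80)
print(df[["alpha", "n_stable", "n_unstable", "k_opt", "best_score",
          "no_clustering"]].to_string(index=False))
print()
print("Reading: at alpha = 7 (near-homogeneous interactions) the winning")
print("silhouette sits below 0.1 -- no community types.  As alpha drops the")
print("strongly interacting species emerge and the silhouette rises; at")
print("alpha = 1.01 a single SIS splits the samples into two distinct types")
print("(the communities that contain it and those that do not).")
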