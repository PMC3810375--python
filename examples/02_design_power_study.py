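"""How many individuals do you need to detect growth autocorrelation?

Runs a small Monte-Carlo power study at rho^2 = 0.64 over a grid of
cohort sizes and interpolates the smallest cohort reaching 80% power.
(Replicates are reduced here for speed; increase n_replicates for
publication-grade numbers.)
"""

from growthcorr import min_individuals_for_power

n_star, table = min_individuals_for_power(
    rho2=0.64, sigma2=16.0, n_t=16,
    grid=[8, 16, 32, 64, 128],
    n_replicates=200, seed=7,
)
print(table.to_string(index=False))
print(f"minimum individuals for 80% power: {n_star}")
# Power rises with cohort size; the crossing of 0.80 is the design
# guidance: sample at least that many unmarked individuals per cohort.
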