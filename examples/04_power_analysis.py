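"""Power analysis: ORA enrichment vs univariate testing.

Fits a Ledoit-Wolf covariance model to (synthetic) connectivity for one
network-pair, estimates ORA power over a (mu, N) grid at alpha=0.95 against
a Bonferroni-level cutoff, translates effect sizes to expected R-squared,
and compares with the closed-form power of the one-sided univariate t test
at the liberal p=1e-3 level.
"""

import numpy as np
from scipy import stats

import fcora
from fcora.power import CovModel, EffectSpec

rng = np.random.default_rng(9)

# a size-105 network-pair with mild exchangeable correlation, "observed" at N=120
atlas = fcora.make_synthetic_atlas(1, (15,))
index = fcora.build_roi_pair_index(atlas)
observed = fcora.sample_connectivity(index, 120, rng, rho_block=0.15, rho_base=0.0)
cov = fcora.fit_cov_model(observed)
S = cov.n_pairs
print(f"network-pair size S={S}, Ledoit-Wolf shrinkage={cov.shrinkage:.3f}")

alpha, sigma = 0.95, 0.2
cutoff = 1 + int(np.argmax(stats.binom.sf(np.arange(S), S, 1 - alpha) <= 1e-4))
print(f"enrichment cutoff at target 1e-4, alpha={alpha}: {cutoff} hits")

grid = [(n, mu, sigma, alpha) for n in (25, 50, 100) for mu in (0.0, 0.1, 0.2, 0.3)]
pg = fcora.estimate_power(cov, grid, {alpha: cutoff}, n_reps=300, seed=1)
print("\nORA power (rows N, columns mu):")
pivot = pg.table.pivot(index="n", columns="mu", values="power")
print(pivot.to_string())

print("\neffect size in variance-explained terms (expected R^2, sigma=0):")
for mu in (0.02, 0.05, 0.1):
    r2 = fcora.expected_r2(cov, EffectSpec(mu, 0.0), n_draws=1, seed=2)
    uni = fcora.univariate_power(mu, float(np.median(np.diag(cov.omega))), 50, 1e-3)
    print(f"  mu={mu:.2f}: E[R^2]={r2:.3f}; univariate power at N=50, p=1e-3: {uni:.3f}")

print("\nEach single edge carries an effect far too small for univariate "
      "testing, but the multiple-R^2 of behavior on all S member edges "
      "grows with the network-pair - ORA exploits exactly that aggregation, "
      "reaching high power where single-edge tests are hopeless.")
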