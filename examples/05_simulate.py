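"""Simulating infinite-sites data from the standard neutral coalescent.

A random tree (uniform merging, exponential waiting times at rate
k(k-1)/2) receives Poisson(theta/2 x branch length) mutations per branch;
each mutation is a new segregating column.  The mean number of
segregating sites across replicates matches Watterson's expectation
theta * sum_{k<n} 1/k.
"""

import numpy as np

import iscoal as ic

rng = np.random.default_rng(0)
d = ic.simulate_dataset(10, 5.0, rng, name="demo")
print(f"one draw at n=10, theta=5: {d.num_sites} segregating sites, "
      f"{d.num_haplotypes} distinct haplotypes, nu={d.nu.tolist()}")
print(f"passes the gamete compatibility test: {ic.four_gamete_test(d).ok}")

reps = 2000
S = [ic.simulate_dataset(10, 5.0, rng).num_sites for _ in range(reps)]
expect = 5.0 * sum(1 / k for k in range(1, 10))
print(f"\nmean segregating sites over {reps} replicates: {np.mean(S):.2f}"
      f"  (Watterson expectation {expect:.2f})")

out = ic.simulate_benchmark_grid([1.0, 3.0], [10, 20], replicates=2, seed=3)
print(f"\nbenchmark grid 2 thetas x 2 sizes x 2 replicates -> "
      f"{len(out)} datasets (deterministic from the seed)")
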