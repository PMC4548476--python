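"""Standard-neutral-coalescent simulator for infinite-sites data.

Generates datasets from the single-population, constant-size coalescent:
a random topology is built by uniform pairwise merging, inter-coalescence
waiting times are exponential with rate k(k-1)/2 while k lineages remain
(time in units of 2N generations), and mutations fall on each branch as a
Poisson process of rate theta/2 per unit time (theta = 4 N mu).  Each
mutation becomes a new binary column carried by the branch's descendant
leaves, so every simulated dataset passes the gamete compatibility test
by construction, and the expected number of segregating sites is
Watterson's theta * sum_{k=1}^{n-1} 1/k.

Columns are ordered oldest mutation first; column order is immaterial
downstream but fixed for determinism.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass

import numpy as np

from .data import K69Dataset, write_dataset

__all__ = [
    "SimulatedTree",
    "simulate_tree",
    "drop_mutations",
    "simulate_dataset",
    "simulate_benchmark_grid",
]


@dataclass
class SimulatedTree:
    """Coalescent tree: leaves 0..n-1, internal nodes n..2n-2 in merge
    order; ``parent[v]`` is -1 for the root, ``time[v]`` the node age."""

    n: int
    parent: np.ndarray
    time: np.ndarray

    @property
    def root(self) -> int:
        return 2 * self.n - 2

    def leaves_below(self, v: int) -> np.ndarray:
        children: dict[int, list[int]] = {}
        for u, p in enumerate(self.parent):
            if p >= 0:
                children.setdefault(int(p), []).append(u)
        out = []
        stack = [v]
        while stack:
            u = stack.pop()
            if u < self.n:
                out.append(u)
            else:
                stack.extend(children.get(u, []))
        return np.array(sorted(out))


def _rng(rng_or_seed) -> np.random.Generator:
    if isinstance(rng_or_seed, np.random.Generator):
        return rng_or_seed
    return np.random.default_rng(rng_or_seed)


def simulate_tree(n: int, rng) -> SimulatedTree:
    """Draw one standard coalescent tree for ``n`` sampled lineages."""
    if n < 2:
        raise ValueError("need at least 2 lineages")
    rng = _rng(rng)
    parent = np.full(2 * n - 1, -1, dtype=np.int64)
    time = np.zeros(2 * n - 1)
    active = list(range(n))
    t = 0.0
    nxt = n
    while len(active) > 1:
        k = len(active)
        t += rng.exponential(2.0 / (k * (k - 1)))
        i, j = rng.choice(k, size=2, replace=False)
        a, b = active[int(i)], active[int(j)]
        parent[a] = parent[b] = nxt
        time[nxt] = t
        active = [x for x in active if x not in (a, b)] + [nxt]
        nxt += 1
    return SimulatedTree(n=n, parent=parent, time=time)


def drop_mutations(tree: SimulatedTree, theta: float, rng,
                   name: str = "") -> K69Dataset:
    """Scatter infinite-sites mutations on a tree and collapse haplotypes.

    Returns the dataset of distinct haplotypes with multiplicities.  At
    theta = 0 this is a single empty haplotype with count n.
    """
    if theta < 0:
        raise ValueError("theta must be nonnegative")
    rng = _rng(rng)
    n = tree.n
    muts: list[tuple[float, np.ndarray]] = []  # (age, carrier leaf mask)
    for v in range(2 * n - 2):  # all non-root nodes
        p = int(tree.parent[v])
        lo, hi = tree.time[v], tree.time[p]
        length = hi - lo
        m = rng.poisson(theta / 2.0 * length) if length > 0 else 0
        if m == 0:
            continue
        ages = lo + rng.random(m) * length
        below = tree.leaves_below(v)
        mask = np.zeros(n, dtype=np.uint8)
        mask[below] = 1
        for a in ages:
            muts.append((float(a), mask))
    muts.sort(key=lambda t: -t[0])  # oldest first
    if muts:
        X_full = np.stack([m for _, m in muts], axis=1)
    else:
        X_full = np.zeros((n, 0), dtype=np.uint8)
    # collapse identical leaf haplotypes, first-seen order
    seen: dict[bytes, int] = {}
    rows: list[np.ndarray] = []
    counts: list[int] = []
    for leaf in range(n):
        key = X_full[leaf].tobytes()
        if key in seen:
            counts[seen[key]] += 1
        else:
            seen[key] = len(rows)
            rows.append(X_full[leaf])
            counts.append(1)
    X = np.stack(rows, axis=0) if rows else np.zeros((1, 0), dtype=np.uint8)
    return K69Dataset(X=X, nu=np.array(counts), name=name)


def simulate_dataset(n: int, theta: float, rng, name: str = "") -> K69Dataset:
    """Convenience: one tree plus mutations in a single call."""
    rng = _rng(rng)
    return drop_mutations(simulate_tree(n, rng), theta, rng, name=name)


def simulate_benchmark_grid(theta_values, n_values, replicates: int, seed: int,
                            out_dir=None, format: str = "xml"):
    """Simulate ``replicates`` datasets per (theta, n) cell.

    Sub-seeds derive deterministically from ``seed`` via SeedSequence
    spawning in fixed cell order, so the same seed reproduces the same
    collection byte for byte.  When ``out_dir`` is given, datasets are
    written there together with a ``manifest.json`` recording seed, theta
    and n per file.  Returns a list of ``(entry, dataset)`` pairs.
    """
    theta_values = list(theta_values)
    n_values = list(n_values)
    if not theta_values or not n_values or replicates < 1:
        raise ValueError("grids must be nonempty and replicates >= 1")
    ss = np.random.SeedSequence(seed)
    children = ss.spawn(len(theta_values) * len(n_values) * replicates)
    out = []
    idx = 0
    for theta in theta_values:
        for n in n_values:
            for rep in range(replicates):
                rng = np.random.default_rng(children[idx])
                nm = f"sim_theta{theta}_n{n}_rep{rep + 1}"
                d = simulate_dataset(int(n), float(theta), rng, name=nm)
                entry = {
                    "file": f"{nm}.{format}",
                    "theta": float(theta),
                    "n": int(n),
                    "replicate": rep + 1,
                    "seed": int(seed),
                    "segregating_sites": d.num_sites,
                    "haplotypes": d.num_haplotypes,
                }
                out.append((entry, d))
                idx += 1
    if out_dir is not None:
        os.makedirs(out_dir, exist_ok=True)
        for entry, d in out:
            write_dataset(d, os.path.join(out_dir, entry["file"]), format=format)
        manifest = {"seed": int(seed), "datasets": [e for e, _ in out]}
        with open(os.path.join(out_dir, "manifest.json"), "w") as fh:
            json.dump(manifest, fh, indent=2, sort_keys=True)
            fh.write("\n")
    return out
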