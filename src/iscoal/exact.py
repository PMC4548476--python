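"""Exact coalescent likelihoods by memoised recursion.

The probability of an ancestral configuration ``C = [X, nu]`` with sample
size ``n`` satisfies

    n (n - 1 + theta) p(C) = sum_coal nu_i (nu_i - 1) p(C_i)
                           + theta sum_{type I} p(C_i)
                           + theta sum_{type II} (nu_b + 1) p(C_i)

with boundary ``p(MRCA) = 1``.  Evaluation is depth-first and iterative
(no call-stack recursion: path lengths reach #sites + n - 1) over
canonical configuration keys, in log space throughout — target
probabilities for realistic samples sit far below linear-space comfort.

The same reachability graph supports counting ancestral configurations
and genealogies, and the exact one-step conditional distribution used by
the exact-singleton proposal.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .data import (
    AncestralConfig,
    EventKind,
    K69Dataset,
    _enumerate_fast,
    _apply_fast,
    canonical_key,
)
from .errors import ExactBudgetExceededError, StuckConfigurationError

__all__ = [
    "ExactCache",
    "exact_log_likelihood",
    "exact_likelihood",
    "exact_likelihood_curve",
    "exact_mle",
    "count_configs",
    "count_genealogies",
    "exact_step_distribution",
]

DEFAULT_MAX_KEYS = 50_000_000


def _step_coefficient(kind, nu, row, merge, theta: float) -> float:
    if kind is EventKind.COALESCENCE:
        v = int(nu[row])
        return float(v * (v - 1))
    if kind is EventKind.MUT_TYPE_I:
        return theta
    return theta * (int(nu[merge]) + 1)


def _events_and_successors(X, nu):
    """Enumerate events with successor arrays, raising on stuck configs."""
    events = _enumerate_fast(X, nu)
    if not events:
        raise StuckConfigurationError(
            "non-MRCA configuration admits no backward event; "
            "data is not a perfect phylogeny rooted at the all-zero sequence"
        )
    succs = []
    for kind, row, col, merge in events:
        Xs, nus, _ = _apply_fast(X, nu, kind, row, col, merge)
        succs.append((Xs, nus))
    return events, succs


def _is_mrca(X, nu) -> bool:
    return X.shape[1] == 0 and X.shape[0] == 1 and int(nu[0]) == 1


@dataclass
class ExactCache:
    """Memo of log p(C; theta) keyed by canonical configuration key.

    theta is baked into the cache instance; sweep a grid with one cache
    per point.  ``max_keys`` caps the memo size; exceeding it raises
    :class:`ExactBudgetExceededError` (consider importance sampling for
    such data).
    """

    theta: float
    max_keys: int = DEFAULT_MAX_KEYS
    _memo: dict = field(default_factory=dict, repr=False)
    hits: int = 0

    def __post_init__(self) -> None:
        if self.theta < 0:
            raise ValueError("theta must be nonnegative")
        mrca = AncestralConfig.mrca()
        self._memo[canonical_key(mrca)] = 0.0  # log 1

    @property
    def entries(self) -> int:
        return len(self._memo)

    def log_prob_config(self, c: AncestralConfig) -> float:
        return self.log_prob(c.X, c.nu)

    def log_prob(self, X: np.ndarray, nu: np.ndarray) -> float:
        """Iterative post-order evaluation of log p([X, nu]; theta)."""
        theta = self.theta
        memo = self._memo
        root_key = canonical_key(AncestralConfig(X=X, nu=nu))
        if root_key in memo:
            self.hits += 1
            return memo[root_key]
        # stack frames: [key, children (key, logcoeff) list or None, X, nu]
        stack = [[root_key, None, X, nu]]
        on_stack = {root_key}
        while stack:
            frame = stack[-1]
            key, children = frame[0], frame[1]
            if children is None:
                events, succs = _events_and_successors(frame[2], frame[3])
                nu_here = frame[3]
                n = int(nu_here.sum())
                children = []
                for (kind, row, col, merge), (Xs, nus) in zip(events, succs):
                    coeff = _step_coefficient(kind, nu_here, row, merge, theta)
                    skey = canonical_key(AncestralConfig(X=Xs, nu=nus))
                    children.append((skey, coeff, Xs, nus))
                frame[1] = (children, n)
                pushed = False
                for skey, coeff, Xs, nus in children:
                    if skey not in memo and skey not in on_stack and coeff > 0:
                        stack.append([skey, None, Xs, nus])
                        on_stack.add(skey)
                        pushed = True
                if pushed:
                    continue
                children = frame[1]
            child_list, n = children
            terms = []
            for skey, coeff, _, _ in child_list:
                if coeff <= 0:
                    continue
                lp = memo.get(skey)
                if lp is None:
                    # a child appeared on-stack earlier (cannot happen: the
                    # reduction is a DAG with strictly decreasing size+n)
                    raise RuntimeError("cycle detected in ancestral graph")
                if lp > -math.inf:
                    terms.append(math.log(coeff) + lp)
            if terms:
                m = max(terms)
                lp_here = m + math.log(sum(math.exp(t - m) for t in terms))
                lp_here -= math.log(n * (n - 1 + theta))
            else:
                lp_here = -math.inf
            if len(memo) >= self.max_keys:
                raise ExactBudgetExceededError(
                    f"exact-recursion memo exceeded {self.max_keys} keys; "
                    "use importance sampling for this dataset"
                )
            memo[key] = lp_here
            on_stack.discard(key)
            stack.pop()
        return memo[root_key]


def exact_log_likelihood(d: K69Dataset, theta: float,
                         max_keys: int = DEFAULT_MAX_KEYS,
                         cache: ExactCache | None = None) -> float:
    """log p(D; theta) by the memoised recursion."""
    if cache is None:
        cache = ExactCache(theta=theta, max_keys=max_keys)
    elif cache.theta != theta:
        raise ValueError("cache was built for a different theta")
    return cache.log_prob(d.X, d.nu)


def exact_likelihood(d: K69Dataset, theta: float, **kw) -> float:
    return math.exp(exact_log_likelihood(d, theta, **kw))


def exact_likelihood_curve(d: K69Dataset, grid, max_keys: int = DEFAULT_MAX_KEYS):
    """Exact log-likelihood at each grid point (one memo per theta).

    Returns a :class:`iscoal.inference.LikelihoodCurve` with zero standard
    errors and undefined ESS (the computation is exact, not Monte Carlo).
    """
    from .inference import LikelihoodCurve

    grid = np.asarray(grid, dtype=float)
    if grid.size == 0 or np.any(np.diff(grid) <= 0):
        raise ValueError("grid must be nonempty and strictly increasing")
    logp = np.array([exact_log_likelihood(d, float(t), max_keys=max_keys) for t in grid])
    return LikelihoodCurve(
        thetas=grid,
        log_estimates=logp,
        ses=np.zeros_like(grid),
        esses=np.full_like(grid, np.nan),
        proposal="exact",
        theta0=float("nan"),
        R=0,
        seed=None,
    )


def exact_mle(curve) -> float:
    """Grid argmax of an exact curve; smallest theta on ties."""
    i = int(np.argmax(curve.log_estimates))
    ties = np.nonzero(curve.log_estimates == curve.log_estimates[i])[0]
    return float(curve.thetas[ties.min()])


# ---------------------------------------------------------------------------
# counting


def _reachable(d: K69Dataset, max_keys: int):
    """Canonical-key graph of all configurations reachable from D.

    Returns ``(root_key, succ_map)`` where succ_map[key] is the list of
    successor keys (with multiplicity one per event).
    """
    root = d.initial_config()
    root_key = canonical_key(root)
    succ_map: dict = {}
    stack = [(root_key, root.X, root.nu)]
    seen = {root_key}
    while stack:
        key, X, nu = stack.pop()
        if _is_mrca(X, nu):
            succ_map[key] = []
            continue
        _, succs = _events_and_successors(X, nu)
        skeys = []
        for Xs, nus in succs:
            skey = canonical_key(AncestralConfig(X=Xs, nu=nus))
            skeys.append((skey, Xs, nus))
        succ_map[key] = [sk for sk, _, _ in skeys]
        for skey, Xs, nus in skeys:
            if skey not in seen:
                seen.add(skey)
                stack.append((skey, Xs, nus))
        if len(seen) > max_keys:
            raise ExactBudgetExceededError(
                f"reachable configuration count exceeded {max_keys}"
            )
    return root_key, succ_map


def count_configs(d: K69Dataset, max_keys: int = DEFAULT_MAX_KEYS) -> int:
    """Number of distinct ancestral configurations reachable from D."""
    _, succ_map = _reachable(d, max_keys)
    return len(succ_map)


def count_genealogies(d: K69Dataset, max_keys: int = DEFAULT_MAX_KEYS) -> int:
    """Number of distinct event paths from D to the MRCA.

    Dynamic program over canonical keys: paths(MRCA) = 1 and
    paths(C) = sum over successors of paths(C').  Exact (big) integers.
    """
    root_key, succ_map = _reachable(d, max_keys)
    mrca_key = canonical_key(AncestralConfig.mrca())
    paths: dict = {}

    def resolve(key):
        # iterative post-order to avoid recursion limits
        stack = [key]
        while stack:
            k = stack[-1]
            if k in paths:
                stack.pop()
                continue
            if k == mrca_key:
                paths[k] = 1
                stack.pop()
                continue
            missing = [s for s in succ_map[k] if s not in paths]
            if missing:
                stack.extend(set(missing))
            else:
                paths[k] = sum(paths[s] for s in succ_map[k])
                stack.pop()

    resolve(root_key)
    return paths[root_key]


# ---------------------------------------------------------------------------
# exact one-step conditionals


def exact_step_distribution(c: AncestralConfig, theta: float, cache: ExactCache):
    """Exact conditional distribution over the backward events of ``c``.

    P(event e) is proportional to coefficient(e) * p(successor; theta);
    this is the target distribution's own one-step conditional, i.e. the
    most efficient proposal possible where it is affordable.  Returns
    ``(events, probabilities)`` with probabilities summing to 1.
    """
    if cache.theta != theta:
        raise ValueError("cache was built for a different theta")
    events, succs = _events_and_successors(c.X, c.nu)
    logs = []
    for (kind, row, col, merge), (Xs, nus) in zip(events, succs):
        coeff = _step_coefficient(kind, c.nu, row, merge, theta)
        if coeff <= 0:
            logs.append(-math.inf)
            continue
        logs.append(math.log(coeff) + cache.log_prob(Xs, nus))
    logs = np.array(logs)
    m = logs.max()
    if m == -math.inf:
        raise StuckConfigurationError("all one-step probabilities are zero")
    p = np.exp(logs - m)
    p /= p.sum()
    from .data import EvolutionEvent

    evs = [EvolutionEvent(kind=k, row=i, column=j, merge_row=mg)
           for k, i, j, mg in events]
    return evs, p
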