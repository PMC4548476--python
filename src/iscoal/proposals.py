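"""Sequential proposal distributions for the genealogy sampler.

Each proposal maps a configuration's applicable events to nonnegative
weights; the sampler normalises them into one-step trial probabilities.
Three published schemes are provided plus a mixed scheme built on exact
conditionals:

* **EGT** (Ethier–Griffiths–Tavaré): weights read directly off the
  recursion — nu_i - 1 for a coalescence, theta / n for a type-I removal,
  theta (nu_b + 1) / n for a type-II removal.
* **SD** (Stephens–Donnelly): weight nu_i for every eligible row,
  independent of theta.
* **HUW** (Hobolth–Uyenoyama–Wiuf): for an eligible row i, the sum over
  current segregating sites m of u_{i,m}(theta0), where u_{i,m} uses the
  probability p_theta0(d_m) that the next backward event involves a
  carrier of mutation m (d_m = multiplicity-weighted carrier count).
* **Exact singleton**: on configurations whose rows are all singletons
  (and whose successors the exact memo can afford), steps are drawn from
  the target's own one-step conditional — the most efficient proposal
  possible there — and from a delegate proposal elsewhere.

All four assign positive weight to every event with positive target
coefficient (for theta > 0), so absolute continuity holds by construction.
"""

from __future__ import annotations

import math
from functools import lru_cache

import numpy as np

from .data import AncestralConfig, EventKind
from .errors import ExactBudgetExceededError
from .exact import ExactCache, _step_coefficient

__all__ = [
    "EGTProposal",
    "SDProposal",
    "HUWProposal",
    "ExactSingletonProposal",
    "huw_p_next",
    "get_proposal",
]


class Proposal:
    """Interface: ``step_weights(node) -> array`` over ``node.events``.

    ``node`` exposes ``X``, ``nu``, ``n`` and ``events`` (tuples of
    ``(kind, row, col, merge_row)``).  ``cache_token`` identifies the
    weight function for per-node memoisation; proposals whose weights
    depend on mutable state must not share a token.
    """

    name: str = "?"

    @property
    def cache_token(self):
        return self.name

    def step_weights(self, node) -> np.ndarray:  # pragma: no cover - interface
        raise NotImplementedError


class EGTProposal(Proposal):
    """Weights proportional to the recursion's own terms.

    One backward step of the recursion assigns mass nu_i (nu_i - 1) to a
    coalescence in row i, theta to a type-I removal and
    theta (nu_b + 1) to a type-II removal (all over the common
    denominator n (n - 1 + theta)); the sequential scheme the recursion
    suggests samples events in exactly those proportions, here written
    with the conventional 1/n scaling that cancels in the
    per-configuration normalisation.
    """

    def __init__(self, theta: float):
        if theta < 0:
            raise ValueError("theta must be nonnegative")
        self.theta = float(theta)
        self.name = "egt"

    @property
    def cache_token(self):
        return ("egt", self.theta)

    def step_weights(self, node) -> np.ndarray:
        th, n = self.theta, node.n
        w = np.empty(len(node.events))
        for idx, (kind, row, col, merge) in enumerate(node.events):
            if kind is EventKind.COALESCENCE:
                w[idx] = node.nu[row] * (node.nu[row] - 1) / n
            elif kind is EventKind.MUT_TYPE_I:
                w[idx] = th / n
            else:
                w[idx] = th * (node.nu[merge] + 1) / n
        return w


class SDProposal(Proposal):
    """Weight nu_i for every eligible row; theta-free."""

    name = "sd"

    def step_weights(self, node) -> np.ndarray:
        return np.array([float(node.nu[row]) for _, row, _, _ in node.events])


def huw_p_next(d: int, n: int, theta: float) -> float:
    """Probability that the next backward event involves a carrier of a
    mutation borne by ``d`` of ``n`` sampled sequences.

    For 1 < d < n this averages, over the level k at which a mutation of
    carrier count d arose (the classical level-size distribution with
    weight C(n-d-1, k-2) / C(n-1, k-1)), the chance (d-1)/(n-k) weighted
    by the waiting factor 1/(k-1+theta); d = 1 has its own closed form and
    d = n gives 1 (every lineage carries the mutation).  Values are
    clamped to [0, 1] against floating-point drift.
    """
    if not (1 <= d <= n) or n < 2:
        raise ValueError("need 1 <= d <= n and n >= 2")
    if theta <= 0:
        raise ValueError("theta must be positive")
    if d == n:
        return 1.0
    if d == 1:
        num = 1.0 / (n - 1 + theta)
        den = sum((k - 1.0) / ((k - 1 + theta) * (n - 1.0)) for k in range(2, n + 1))
        return min(max(num / den, 0.0), 1.0)
    num = 0.0
    den = 0.0
    for k in range(2, n - d + 2):
        a = (
            math.comb(n - d - 1, k - 2)
            / math.comb(n - 1, k - 1)
            / (k - 1 + theta)
        )
        den += a
        num += a * (d - 1.0) / (n - k)
    return min(max(num / den, 0.0), 1.0)


class HUWProposal(Proposal):
    """Mutation-aware weights driven by a fixed theta0.

    For an eligible row i the weight is sum_m u_{i,m}(theta0) over the
    configuration's current segregating columns:

        u_{i,m} = p(d_m) nu_i / d_m            if X_{i,m} = 1
                 = [1 - p(d_m)] nu_i / (n-d_m)  if X_{i,m} = 0

    (the 0-branch is skipped when d_m = n, where no such row exists and
    p is taken as 1).  When no columns remain, the empty sum leaves every
    event weightless; the remaining events are pure coalescences and the
    scheme falls back to SD weights (proportional to nu_i), keeping
    support full — at that point all proposals coincide up to
    normalisation.
    """

    def __init__(self, theta0: float):
        if theta0 <= 0:
            raise ValueError("theta0 must be positive")
        self.theta0 = float(theta0)
        self.name = "huw"

    @property
    def cache_token(self):
        return ("huw", self.theta0)

    @lru_cache(maxsize=100_000)
    def _p(self, d: int, n: int) -> float:
        return huw_p_next(d, n, self.theta0)

    def step_weights(self, node) -> np.ndarray:
        X, nu, n = node.X, node.nu, node.n
        s = X.shape[1]
        if s == 0:
            return np.array([float(nu[row]) for _, row, _, _ in node.events])
        dm = (X.astype(np.int64).T @ nu).astype(np.int64)
        p = np.array([self._p(int(d), n) for d in dm])
        carrier = X.astype(bool)
        u = np.empty_like(carrier, dtype=float)
        nu_f = nu.astype(float)[:, None]
        with np.errstate(divide="ignore", invalid="ignore"):
            u_one = p[None, :] * nu_f / dm[None, :]
            denom0 = (n - dm).astype(float)
            u_zero = (1.0 - p)[None, :] * nu_f / np.where(denom0 > 0, denom0, np.inf)
        u = np.where(carrier, u_one, u_zero)
        row_w = u.sum(axis=1)
        return np.array([row_w[row] for _, row, _, _ in node.events])


class ExactProposal(Proposal):
    """The target distribution's own one-step conditionals, everywhere.

    Sampling from this proposal makes every importance weight exactly
    p(D; theta), so ESS = R; it is the zero-variance reference the mixed
    schemes are measured against, affordable only where the exact memo
    is (small data).
    """

    def __init__(self, theta: float, max_keys: int = 5_000_000):
        if theta <= 0:
            raise ValueError("theta must be positive")
        self.theta = float(theta)
        self.cache = ExactCache(theta=self.theta, max_keys=max_keys)
        self.name = "exact"

    @property
    def cache_token(self):
        return ("exact", self.theta)

    def step_weights(self, node) -> np.ndarray:
        return _exact_step_weights(node, self.theta, self.cache)


def _exact_step_weights(node, theta: float, cache: ExactCache) -> np.ndarray:
    logs = np.empty(len(node.events))
    for idx, ((kind, row, col, merge), (Xs, nus)) in enumerate(
        zip(node.events, node.succ_arrays)
    ):
        coeff = _step_coefficient(kind, node.nu, row, merge, theta)
        logs[idx] = (
            math.log(coeff) + cache.log_prob(Xs, nus) if coeff > 0 else -math.inf
        )
    return np.exp(logs - logs.max())


class ExactSingletonProposal(Proposal):
    """Mixed proposal: exact one-step conditionals on all-singleton
    configurations, a delegate proposal elsewhere.

    The exact memo is filled on demand and capped at ``max_keys``
    canonical keys; a configuration whose successors cannot all be
    evaluated inside the cap falls back to the delegate (the failure is
    remembered, so the cap is probed at most once per configuration).
    log q accumulates consistently across regime switches because both
    regimes are ordinary per-step weight functions.
    """

    def __init__(self, delegate: Proposal, theta: float, max_keys: int = 200_000):
        if theta <= 0:
            raise ValueError("theta must be positive")
        self.delegate = delegate
        self.theta = float(theta)
        self.cache = ExactCache(theta=self.theta, max_keys=max_keys)
        self._uncovered: set = set()
        self.name = f"exact-singleton({delegate.name})"
        self.exact_steps = 0
        self.delegate_steps = 0

    @property
    def cache_token(self):
        return ("exact-singleton", self.theta, self.delegate.cache_token)

    def step_weights(self, node) -> np.ndarray:
        key = (node.X.shape[1], node.X.tobytes(), node.nu.tobytes())
        if np.all(node.nu == 1) and key not in self._uncovered:
            try:
                w = _exact_step_weights(node, self.theta, self.cache)
                self.exact_steps += 1
                return w
            except ExactBudgetExceededError:
                self._uncovered.add(key)
        self.delegate_steps += 1
        return self.delegate.step_weights(node)


def get_proposal(name: str, theta: float | None = None, theta0: float | None = None,
                 delegate: str = "sd", **kw) -> Proposal:
    """Factory for the built-in proposals.

    ``theta`` parameterises EGT and the exact-singleton scheme; ``theta0``
    (defaulting to ``theta``) drives HUW; ``delegate`` names the fallback
    scheme for ``exact-singleton``.
    """
    name = name.lower()
    if name == "egt":
        if theta is None:
            raise ValueError("EGT needs theta")
        return EGTProposal(theta)
    if name == "sd":
        return SDProposal()
    if name == "huw":
        t0 = theta0 if theta0 is not None else theta
        if t0 is None:
            raise ValueError("HUW needs theta0 (or theta)")
        return HUWProposal(t0)
    if name in ("exact-singleton", "exact_singleton", "ess"):
        if theta is None:
            raise ValueError("exact-singleton needs theta")
        return ExactSingletonProposal(
            get_proposal(delegate, theta=theta, theta0=theta0), theta, **kw
        )
    raise ValueError(f"unknown proposal {name!r}")
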