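"""Generic sequential importance sampler for coalescent genealogies.

A *genealogy* here is the ordered chain of backward events (coalescences
and mutation removals, no times) from the sample to the MRCA.  A proposal
assigns a nonnegative weight to every applicable event of the current
configuration; events are drawn with probability proportional to their
weights and the chain's log proposal probability log q(G) is accumulated.
The importance weight of a realization is w(G) = p(G; theta) / q(G), and
the likelihood estimate is the mean of the weights, since summing
p(G)/q(G) over genealogies drawn from q estimates sum_G p(G) = p(D; theta).

Step summaries (event kind, n before the step, the acting multiplicities)
are sufficient to re-evaluate log p(G; theta) at any theta, so one pass of
sampling supports a whole likelihood curve (see :mod:`iscoal.inference`).

Per-configuration event tables are memoised within a run (keyed by the raw
byte representation of the configuration), which makes repeated visits to
the same configuration — the normal case when drawing many genealogies
from one dataset — cheap.
"""

from __future__ import annotations

import math
import time
from dataclasses import dataclass, field

import numpy as np
from scipy.special import logsumexp

from .data import (
    AncestralConfig,
    EventKind,
    EvolutionEvent,
    K69Dataset,
    _apply_fast,
    _enumerate_fast,
)
from .errors import AbsoluteContinuityError, StuckConfigurationError

__all__ = [
    "Budget",
    "Genealogy",
    "SamplerRun",
    "sample_genealogy",
    "genealogy_log_target",
    "run_sampler",
    "likelihood_estimate",
    "standard_error",
    "ess",
]

_KIND_CODE = {EventKind.COALESCENCE: 0, EventKind.MUT_TYPE_I: 1, EventKind.MUT_TYPE_II: 2}


@dataclass(frozen=True)
class Budget:
    """Sampling budget: a number of realizations or a wall-clock allowance."""

    mode: str  # "realizations" | "seconds"
    amount: float

    def __post_init__(self):
        if self.mode not in ("realizations", "seconds"):
            raise ValueError("budget mode must be 'realizations' or 'seconds'")
        if self.amount <= 0:
            raise ValueError("budget amount must be positive")

    @classmethod
    def realizations(cls, R: int) -> "Budget":
        return cls("realizations", int(R))

    @classmethod
    def seconds(cls, s: float) -> "Budget":
        return cls("seconds", float(s))


@dataclass
class Genealogy:
    """One sampled chain of events with its proposal probability.

    ``kinds``/``n_before``/``nu_row``/``nu_merge`` are per-step arrays
    (nu_merge is the pre-event multiplicity of the merge haplotype for
    type-II steps, 0 elsewhere); they suffice to evaluate the target
    log-probability at any theta.
    """

    kinds: np.ndarray
    n_before: np.ndarray
    nu_row: np.ndarray
    nu_merge: np.ndarray
    log_q: float
    events: list[EvolutionEvent] | None = None

    def __len__(self) -> int:
        return len(self.kinds)


def genealogy_log_target(g: Genealogy, theta: float) -> float:
    """log p(G; theta) from the step summaries.

    Each step contributes log[coefficient / (n (n - 1 + theta))]; mutation
    coefficients are theta (type I) or theta (nu_merge + 1) (type II), so
    at theta = 0 any chain containing a mutation step has log target -inf.
    """
    if theta < 0:
        raise ValueError("theta must be nonnegative")
    kinds, n, vr, vm = g.kinds, g.n_before, g.nu_row, g.nu_merge
    n_mut = int(np.count_nonzero(kinds != 0))
    if theta == 0 and n_mut > 0:
        return -math.inf
    coal = kinds == 0
    num = float(np.log(vr[coal] * (vr[coal] - 1.0)).sum())
    num += float(np.log(vm[kinds == 2] + 1.0).sum())
    if n_mut:
        num += n_mut * math.log(theta)
    den = float(np.log(n * (n - 1.0 + theta)).sum())
    return num - den


class _Node:
    """Cached per-configuration step table."""

    __slots__ = ("X", "nu", "n", "events", "_succ_arrays", "succ_nodes", "weights")

    def __init__(self, X, nu):
        self.X = X
        self.nu = nu
        self.n = int(nu.sum())
        events = _enumerate_fast(X, nu)
        if not events and not (X.shape[1] == 0 and X.shape[0] == 1 and self.n == 1):
            raise StuckConfigurationError(
                "non-MRCA configuration admits no backward event; "
                "data is not a perfect phylogeny rooted at the all-zero sequence"
            )
        self.events = events
        self._succ_arrays: list = [None] * len(events)
        self.succ_nodes: list = [None] * len(events)
        self.weights: dict = {}

    def succ_array(self, idx: int):
        sa = self._succ_arrays[idx]
        if sa is None:
            k, r, c, m = self.events[idx]
            sa = _apply_fast(self.X, self.nu, k, r, c, m)[:2]
            self._succ_arrays[idx] = sa
        return sa

    @property
    def succ_arrays(self):
        return [self.succ_array(i) for i in range(len(self.events))]

    @property
    def is_mrca(self) -> bool:
        return not self.events


class _RunCache:
    """Per-dataset node cache shared across realizations of a run."""

    def __init__(self, max_nodes: int = 2_000_000):
        self.nodes: dict = {}
        self.max_nodes = max_nodes

    def node_for(self, X, nu) -> _Node:
        key = (X.shape[1], X.tobytes(), nu.tobytes())
        node = self.nodes.get(key)
        if node is None:
            node = _Node(X, nu)
            if len(self.nodes) < self.max_nodes:
                self.nodes[key] = node
        return node

    def child(self, node: _Node, idx: int) -> _Node:
        ch = node.succ_nodes[idx]
        if ch is None:
            Xs, nus = node.succ_array(idx)
            ch = self.node_for(Xs, nus)
            node.succ_nodes[idx] = ch
        return ch


def _node_weights(node: _Node, proposal):
    """Memoised proposal weights for a node: (w, cumsum, total, log w)."""
    entry = node.weights.get(proposal.cache_token)
    if entry is None:
        w = np.asarray(proposal.step_weights(node), dtype=float)
        if w.shape != (len(node.events),):
            raise ValueError("proposal returned a weight vector of wrong length")
        if np.any(w < 0) or not np.all(np.isfinite(w)):
            raise ValueError("proposal weights must be finite and nonnegative")
        total = float(w.sum())
        if total <= 0:
            raise AbsoluteContinuityError(
                "proposal assigned zero weight to every event of a reachable "
                f"configuration (n={node.n}, sites={node.X.shape[1]}); "
                "q(G) = 0 where p(G) > 0"
            )
        with np.errstate(divide="ignore"):
            logw = np.log(w) - math.log(total)
        entry = (np.cumsum(w), total, logw)
        node.weights[proposal.cache_token] = entry
    return entry


def _draw_chain(cache: _RunCache, proposal, rng, start: _Node):
    """Draw one genealogy; returns per-step summary arrays and log q."""
    kinds: list[int] = []
    ns: list[int] = []
    vrs: list[int] = []
    vms: list[int] = []
    idxs: list[int] = []
    nodes: list[_Node] = []
    log_q = 0.0
    node = start
    while not node.is_mrca:
        cum, total, logw = _node_weights(node, proposal)
        u = rng.random() * total
        i = int(np.searchsorted(cum, u, side="right"))
        if i >= len(cum):  # guard against fp roundoff at the top end
            i = len(cum) - 1
        if logw[i] == -math.inf:  # roundoff landed on a zero-weight event
            pos = np.nonzero(np.isfinite(logw))[0]
            i = int(pos[np.searchsorted(pos, i)]) if np.any(pos >= i) else int(pos[-1])
        log_q += logw[i]
        k, row, col, merge = node.events[i]
        kinds.append(_KIND_CODE[k])
        ns.append(node.n)
        vrs.append(int(node.nu[row]))
        vms.append(int(node.nu[merge]) if merge is not None else 0)
        idxs.append(i)
        nodes.append(node)
        node = cache.child(node, i)
    return (
        np.array(kinds, dtype=np.int8),
        np.array(ns, dtype=np.int32),
        np.array(vrs, dtype=np.int32),
        np.array(vms, dtype=np.int32),
        log_q,
        idxs,
        nodes,
    )


def sample_genealogy(proposal, d: K69Dataset, theta: float, rng,
                     cache: _RunCache | None = None) -> Genealogy:
    """Draw one genealogy for dataset ``d`` from ``proposal``.

    ``theta`` is the driving value the proposal was parameterised with
    (kept for interface symmetry; theta-free proposals ignore it).  ``rng``
    is a :class:`numpy.random.Generator`.
    """
    if isinstance(rng, (int, np.integer)):
        rng = np.random.default_rng(rng)
    if cache is None:
        cache = _RunCache()
    start = cache.node_for(np.ascontiguousarray(d.X), np.asarray(d.nu, dtype=np.int64))
    kinds, ns, vrs, vms, log_q, idxs, nodes = _draw_chain(cache, proposal, rng, start)
    events = [
        EvolutionEvent(kind=nd.events[i][0], row=nd.events[i][1],
                       column=nd.events[i][2], merge_row=nd.events[i][3])
        for nd, i in zip(nodes, idxs)
    ]
    return Genealogy(kinds=kinds, n_before=ns, nu_row=vrs, nu_merge=vms,
                     log_q=log_q, events=events)


@dataclass
class SamplerRun:
    """Result of drawing R genealogies from one proposal.

    ``log_w`` holds per-realization log importance weights at the driving
    theta.  ``mut_counts``, ``log_const`` and ``level_counts`` are
    sufficient statistics for re-evaluating log p(G_r; theta) at any
    theta: log p = log_const + mut_counts * log(theta)
    - sum_n level_counts[:, n] * log(n (n - 1 + theta)).
    """

    proposal: str
    theta: float
    seed: int | None
    R: int
    elapsed_s: float
    log_w: np.ndarray
    log_q: np.ndarray
    log_const: np.ndarray
    mut_counts: np.ndarray
    level_counts: np.ndarray  # shape (R, n0 + 1)

    def log_target(self, theta: float) -> np.ndarray:
        """Vector of log p(G_r; theta) across realizations."""
        if theta < 0:
            raise ValueError("theta must be nonnegative")
        nvals = np.arange(self.level_counts.shape[1], dtype=float)
        with np.errstate(divide="ignore", invalid="ignore"):
            logden = np.log(nvals * (nvals - 1.0 + theta))
        logden[~np.isfinite(logden)] = 0.0  # n=0 never occurs; n=1 only with mutations
        den = self.level_counts @ logden
        if theta == 0:
            # any chain with a mutation step has zero target probability
            return np.where(self.mut_counts > 0, -np.inf, self.log_const - den)
        return self.log_const + self.mut_counts * math.log(theta) - den

    def log_weights(self, theta: float | None = None) -> np.ndarray:
        if theta is None:
            return self.log_w
        return self.log_target(theta) - self.log_q


def run_sampler(proposal, d: K69Dataset, theta: float, budget: Budget,
                seed: int | None = None, cache: _RunCache | None = None) -> SamplerRun:
    """Draw genealogies until the budget is exhausted.

    In ``realizations`` mode exactly R chains are drawn and the run is
    reproducible from the seed; in ``seconds`` mode sampling stops after
    the first realization that completes past the wall-clock allowance
    (whole realizations are never aborted mid-chain), and the realized R
    is reported alongside.
    """
    if theta < 0:
        raise ValueError("theta must be nonnegative")
    rng = np.random.default_rng(seed)
    if cache is None:
        cache = _RunCache()
    start = cache.node_for(np.ascontiguousarray(d.X), np.asarray(d.nu, dtype=np.int64))
    n0 = start.n
    logw_l: list[float] = []
    logq_l: list[float] = []
    const_l: list[float] = []
    mut_l: list[int] = []
    levels_l: list[np.ndarray] = []
    t0 = time.perf_counter()
    r = 0
    while True:
        kinds, ns, vrs, vms, log_q, _, _ = _draw_chain(cache, proposal, rng, start)
        coal = kinds == 0
        const = float(np.log(vrs[coal] * (vrs[coal] - 1.0)).sum())
        const += float(np.log(vms[kinds == 2] + 1.0).sum())
        n_mut = int(np.count_nonzero(~coal))
        counts = np.bincount(ns, minlength=n0 + 1).astype(np.int32)
        if theta == 0 and n_mut > 0:
            log_p = -math.inf
        else:
            log_p = const + (n_mut * math.log(theta) if n_mut else 0.0)
            log_p -= float(np.log(ns * (ns - 1.0 + theta)).sum())
        logw_l.append(log_p - log_q)
        logq_l.append(log_q)
        const_l.append(const)
        mut_l.append(n_mut)
        levels_l.append(counts)
        r += 1
        if budget.mode == "realizations":
            if r >= int(budget.amount):
                break
        elif time.perf_counter() - t0 >= budget.amount:
            break
    elapsed = time.perf_counter() - t0
    return SamplerRun(
        proposal=getattr(proposal, "name", str(proposal)),
        theta=theta,
        seed=seed,
        R=r,
        elapsed_s=elapsed,
        log_w=np.array(logw_l),
        log_q=np.array(logq_l),
        log_const=np.array(const_l),
        mut_counts=np.array(mut_l),
        level_counts=np.vstack(levels_l),
    )


# ---------------------------------------------------------------------------
# estimators


def likelihood_estimate(run_or_logw) -> float:
    """Mean importance weight, R^-1 sum_r w_r, via log-sum-exp."""
    logw = _logw(run_or_logw)
    return float(np.exp(logsumexp(logw) - math.log(len(logw))))


def log10_likelihood_estimate(run_or_logw) -> float:
    logw = _logw(run_or_logw)
    return float((logsumexp(logw) - math.log(len(logw))) / math.log(10))


def standard_error(run_or_logw) -> float:
    """Sample standard deviation of the weights divided by sqrt(R)."""
    logw = _logw(run_or_logw)
    R = len(logw)
    if R < 2:
        raise ValueError("standard error needs at least 2 realizations")
    ls = logsumexp(logw)          # log sum w
    ls2 = logsumexp(2 * logw)     # log sum w^2
    # var = (sum w^2 - (sum w)^2 / R) / (R - 1), computed stably
    log_mean_sq = 2 * ls - math.log(R)
    m = max(ls2, log_mean_sq)
    inner = math.exp(ls2 - m) - math.exp(log_mean_sq - m)
    if inner <= 0:
        return 0.0
    var = math.exp(m + math.log(inner)) / (R - 1)
    return math.sqrt(var / R)


def ess(run_or_logw) -> float:
    """Effective sample size, R / (1 + var_q of mean-normalized weights).

    Evaluated by the scale-invariant plug-in (sum w)^2 / sum w^2 in log
    space; always within [1, R], equal to R iff all weights are equal.
    """
    logw = _logw(run_or_logw)
    val = math.exp(2 * logsumexp(logw) - logsumexp(2 * logw))
    return float(min(max(val, 1.0), len(logw)))


def _logw(run_or_logw) -> np.ndarray:
    if isinstance(run_or_logw, SamplerRun):
        return run_or_logw.log_w
    return np.asarray(run_or_logw, dtype=float)
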