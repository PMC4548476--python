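"""Shared fixtures and independent oracles.

The brute-force likelihood here enumerates every genealogy path by naive
depth-first recursion in exact rational arithmetic — deliberately
independent of the memoised log-space recursion it is used to check.
"""

from fractions import Fraction

import numpy as np
import pytest

import iscoal as ic
from iscoal.data import _apply_fast, _enumerate_fast


@pytest.fixture
def table1():
    return ic.table1()


@pytest.fixture
def identical_pair():
    """Two identical sequences: empty matrix with count 2."""
    return ic.K69Dataset(X=np.zeros((1, 0), dtype=np.uint8), nu=[2], name="pair")


@pytest.fixture
def one_mutation_pair():
    """Two sequences differing by a single mutation."""
    return ic.K69Dataset(X=np.array([[1], [0]], dtype=np.uint8), nu=[1, 1],
                         name="one-mut-pair")


def brute_force_likelihood(d, theta) -> Fraction:
    """Sum of path probabilities over all genealogies, exact rationals."""
    return _brute(d)[0](Fraction(theta))


def brute_force_path_count(d) -> int:
    return _brute(d)[1]


def _brute(d):
    def rec(X, nu):
        if X.shape[1] == 0 and X.shape[0] == 1 and nu[0] == 1:
            return (lambda th: Fraction(1)), 1
        events = _enumerate_fast(X, nu)
        n = int(nu.sum())
        subs = []
        paths = 0
        for k, r, c, m in events:
            if k is ic.EventKind.COALESCENCE:
                coeff = lambda th, v=int(nu[r]): Fraction(v * (v - 1))
            elif k is ic.EventKind.MUT_TYPE_I:
                coeff = lambda th: th
            else:
                coeff = lambda th, v=int(nu[m]): th * (v + 1)
            Xs, nus, _ = _apply_fast(X, nu, k, r, c, m)
            sub, p = rec(Xs, nus)
            subs.append((coeff, sub))
            paths += p

        def total(th, subs=subs, n=n):
            return sum(c(th) / (n * (n - 1 + th)) * s(th) for c, s in subs)

        return total, paths

    return rec(np.ascontiguousarray(d.X), np.asarray(d.nu, dtype=np.int64))


def brute_force_first_step(d, theta):
    """Posterior probability of each first event, by path enumeration."""
    c0 = d.initial_config()
    events = ic.enumerate_events(c0)
    masses = []
    th = Fraction(theta)
    n = d.n
    for e in events:
        coeff = Fraction(ic.target_coefficient(c0, e, theta))
        succ = ic.apply_event(c0, e)
        masses.append(coeff / (n * (n - 1 + th)) * brute_force_likelihood(succ, theta))
    tot = sum(masses)
    return events, [float(m / tot) for m in masses]
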