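"""Proposal-comparison harness.

Runs several proposals on the same dataset under a shared budget (a fixed
number of realizations, a fixed wall-clock allowance, or the
slowest-completes-R variant where every proposal gets the wall time the
slowest needed for R realizations) and reports estimate, standard error,
ESS, realizations, elapsed time, ESS per second, and ESS scaled to the SD
proposal.  Fixed-realizations comparisons are fully reproducible from the
per-proposal seeds; timed results always carry realization counts,
because wall-clock numbers are hardware-dependent and running time
belongs in any honest comparison of proposals.

One proposal's failure annotates the report without aborting the others.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

from .data import K69Dataset
from .errors import IscoalError
from .sampling import Budget, ess, likelihood_estimate, run_sampler, standard_error

__all__ = ["ComparisonReport", "compare_proposals"]


@dataclass
class ComparisonReport:
    dataset: str
    theta: float
    budget: Budget
    rows: list[dict] = field(default_factory=list)
    errors: dict = field(default_factory=dict)

    def to_frame(self):
        import pandas as pd

        cols = ["proposal", "likelihood", "log10_likelihood", "std_error", "ess",
                "realizations", "elapsed_s", "ess_per_s"]
        if any("scaled_ess" in r for r in self.rows):
            cols.append("scaled_ess")
        return pd.DataFrame(self.rows)[cols]

    def to_dict(self) -> dict:
        return {
            "dataset": self.dataset,
            "theta": self.theta,
            "budget": {"mode": self.budget.mode, "amount": self.budget.amount},
            "proposals": self.rows,
            "errors": {k: str(v) for k, v in self.errors.items()},
        }


def compare_proposals(d: K69Dataset, proposals, theta: float, budget: Budget,
                      seeds, match_slowest: bool = False) -> ComparisonReport:
    """Benchmark ``proposals`` on ``d`` at ``theta`` under a shared budget.

    ``proposals`` is a list of parameterised proposal objects; ``seeds``
    one integer per proposal.  With ``match_slowest=True`` (requires a
    realizations budget) every proposal is first run for R realizations,
    then re-run for the wall time the slowest needed, mimicking a
    fixed-time tournament.
    """
    proposals = list(proposals)
    seeds = list(seeds)
    if len(seeds) != len(proposals):
        raise ValueError("need one seed per proposal")
    if match_slowest and budget.mode != "realizations":
        raise ValueError("match_slowest needs a realizations budget")

    report = ComparisonReport(dataset=d.name, theta=theta, budget=budget)
    runs: dict[str, object] = {}
    for prop, seed in zip(proposals, seeds):
        name = getattr(prop, "name", str(prop))
        try:
            runs[name] = run_sampler(prop, d, theta, budget, seed=seed)
        except IscoalError as exc:
            report.errors[name] = exc

    if match_slowest and runs:
        t_max = max(r.elapsed_s for r in runs.values())
        for prop, seed in zip(proposals, seeds):
            name = getattr(prop, "name", str(prop))
            if name not in runs:
                continue
            try:
                runs[name] = run_sampler(prop, d, theta, Budget.seconds(t_max), seed=seed)
            except IscoalError as exc:
                report.errors[name] = exc
                del runs[name]

    for name, run in runs.items():
        e = ess(run)
        row = {
            "proposal": name,
            "likelihood": likelihood_estimate(run),
            "log10_likelihood": float(
                (np.logaddexp.reduce(run.log_w) - math.log(run.R)) / math.log(10)
            ),
            "std_error": standard_error(run) if run.R >= 2 else 0.0,
            "ess": e,
            "realizations": run.R,
            "elapsed_s": run.elapsed_s,
            "ess_per_s": e / run.elapsed_s if run.elapsed_s > 0 else float("inf"),
            "seed": run.seed,
        }
        report.rows.append(row)

    sd_rows = [r for r in report.rows if r["proposal"] == "sd"]
    if sd_rows and len(report.rows) > 1:
        sd_ess = sd_rows[0]["ess"]
        for r in report.rows:
            r["scaled_ess"] = r["ess"] / sd_ess if sd_ess > 0 else float("nan")
    return report
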