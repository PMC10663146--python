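"""Replication harness: bias and coverage of the three emulation methods.

Repeats simulate -> emulate -> fit across many replicates and aggregates,
per method and contrast (loss vs maintenance, gain vs maintenance):

* mean estimate and bias (mean estimate minus the injected truth),
* empirical SD of the estimates,
* coverage of the nominal 95% Wald interval,
* Monte-Carlo standard errors of bias and coverage,
* mean retained sample size and the count of failed replicates
  (non-converged or separated fits are excluded from summaries but
  always reported).

Replicate seeds are spawned from the master seed, so serial and parallel
execution produce identical reports.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field

import numpy as np
from joblib import Parallel, delayed

from .emulation import apply_exclusions, expand_person_periods, method_spec
from .estimators import fit_pooled_logistic
from .simulate import SimParams, simulate_cohort

__all__ = ["ReplicationReport", "run_replications", "summarize_report"]

CONTRASTS = ("loss_vs_maint", "gain_vs_maint")


@dataclass
class CellSummary:
    """Aggregates for one (method, contrast) cell."""

    truth: float
    mean_estimate: float
    bias: float
    empirical_sd: float
    coverage: float
    mc_se_bias: float
    mc_se_coverage: float
    n_effective_reps: int

    def to_dict(self) -> dict:
        return {
            "truth": self.truth,
            "mean_estimate": self.mean_estimate,
            "bias": self.bias,
            "empirical_sd": self.empirical_sd,
            "coverage": self.coverage,
            "mc_se_bias": self.mc_se_bias,
            "mc_se_coverage": self.mc_se_coverage,
            "n_effective_reps": self.n_effective_reps,
        }


@dataclass
class ReplicationReport:
    """Across-replicate summary in the shape of a simulation-study table."""

    n_reps: int
    master_seed: int
    params_digest: str
    methods: tuple[str, ...]
    cells: dict[tuple[str, str], CellSummary]
    mean_n_subjects: dict[str, float]
    n_failed: dict[str, int]
    estimates: dict[str, dict[str, np.ndarray]] = field(repr=False, default_factory=dict)

    def cell(self, method: str, contrast: str) -> CellSummary:
        return self.cells[(method, contrast)]

    def to_dict(self) -> dict:
        return {
            "n_reps": self.n_reps,
            "master_seed": self.master_seed,
            "params_digest": self.params_digest,
            "methods": list(self.methods),
            "cells": {
                f"{m}.{c}": cell.to_dict() for (m, c), cell in self.cells.items()
            },
            "mean_n_subjects": self.mean_n_subjects,
            "n_failed": self.n_failed,
        }


def _params_digest(params: SimParams) -> str:
    blob = json.dumps(params.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:12]


def _one_replicate(params: SimParams, seed_state: tuple, methods: tuple[str, ...]) -> dict:
    """Simulate one cohort and fit every requested method on it."""
    ss = np.random.SeedSequence(
        entropy=seed_state[0], spawn_key=seed_state[1]
    )
    cohort = simulate_cohort(params, ss)
    out: dict[str, dict] = {}
    for name in methods:
        spec = method_spec(name)
        sub, _ = apply_exclusions(cohort, spec)
        records = expand_person_periods(sub, spec)
        try:
            fit = fit_pooled_logistic(records, spec)
        except ValueError:
            out[name] = {"ok": False, "n_subjects": sub.n}
            continue
        out[name] = {
            "ok": fit.converged and not fit.separation_flag,
            "coef_loss": fit.coef_loss,
            "se_loss": fit.se_loss,
            "coef_gain": fit.coef_gain,
            "se_gain": fit.se_gain,
            "n_subjects": fit.n_subjects,
        }
    return out


def run_replications(
    params: SimParams,
    n_reps: int,
    methods: tuple[str, ...] | list[str] = ("method1", "method2", "method3"),
    master_seed: int | None = None,
    n_jobs: int = 1,
    keep_estimates: bool = True,
) -> ReplicationReport:
    """Run the full simulation study.

    Each replicate gets an independent child seed spawned from
    ``master_seed`` before any work starts, so results are identical for
    serial (``n_jobs=1``) and parallel execution.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    methods = tuple(method_spec(m).name for m in methods)
    if not methods:
        raise ValueError("no methods requested")
    if master_seed is None:
        master_seed = params.master_seed
    children = np.random.SeedSequence(master_seed).spawn(n_reps)
    states = [(c.entropy, c.spawn_key) for c in children]

    if n_jobs == 1:
        results = [_one_replicate(params, s, methods) for s in states]
    else:
        results = Parallel(n_jobs=n_jobs)(
            delayed(_one_replicate)(params, s, methods) for s in states
        )

    truths = {
        "loss_vs_maint": params.true_loss_effect,
        "gain_vs_maint": params.true_gain_effect,
    }
    cells: dict[tuple[str, str], CellSummary] = {}
    mean_n: dict[str, float] = {}
    n_failed: dict[str, int] = {}
    estimates: dict[str, dict[str, np.ndarray]] = {}
    for m in methods:
        rows = [r[m] for r in results]
        ok = [r for r in rows if r.get("ok")]
        n_failed[m] = len(rows) - len(ok)
        if not ok:
            raise RuntimeError(f"all {len(rows)} replicates failed for {m}")
        mean_n[m] = float(np.mean([r["n_subjects"] for r in rows]))
        estimates[m] = {}
        for contrast, key in (("loss_vs_maint", "loss"), ("gain_vs_maint", "gain")):
            est = np.array([r[f"coef_{key}"] for r in ok])
            se = np.array([r[f"se_{key}"] for r in ok])
            truth = truths[contrast]
            R = len(est)
            covered = np.abs(est - truth) <= 1.959964 * se
            cov = float(covered.mean())
            sd = float(est.std(ddof=1))
            cells[(m, contrast)] = CellSummary(
                truth=truth,
                mean_estimate=float(est.mean()),
                bias=float(est.mean() - truth),
                empirical_sd=sd,
                coverage=cov,
                mc_se_bias=sd / np.sqrt(R),
                mc_se_coverage=float(np.sqrt(cov * (1 - cov) / R)),
                n_effective_reps=R,
            )
            if keep_estimates:
                estimates[m][contrast] = est

    return ReplicationReport(
        n_reps=n_reps,
        master_seed=int(master_seed),
        params_digest=_params_digest(params),
        methods=methods,
        cells=cells,
        mean_n_subjects=mean_n,
        n_failed=n_failed,
        estimates=estimates if keep_estimates else {},
    )


def summarize_report(report: ReplicationReport) -> str:
    """Render the report as a plain-text grid: one row per contrast,
    estimate / bias / coverage per method."""
    if not report.methods:
        raise ValueError("report contains no methods")
    colw = 30
    head = f"{'contrast':<16}" + "".join(f"{m:^{colw}}" for m in report.methods)
    sub = f"{'':<16}" + "".join(
        f"{'estimate':>10}{'bias':>10}{'cover':>10}" for _ in report.methods
    )
    lines = [
        f"Replication study: {report.n_reps} replicates, seed {report.master_seed}, "
        f"params {report.params_digest}",
        "",
        head,
        sub,
    ]
    for contrast in CONTRASTS:
        row = f"{contrast:<16}"
        for m in report.methods:
            cell = report.cells.get((m, contrast))
            if cell is None:
                row += f"{'failed':^{colw}}"
            else:
                row += (
                    f"{cell.mean_estimate:>10.3f}{cell.bias:>10.3f}"
                    f"{cell.coverage:>10.3f}"
                )
        lines.append(row)
    lines.append("")
    for m in report.methods:
        lines.append(
            f"{m}: mean n after exclusions = {report.mean_n_subjects[m]:.1f}, "
            f"failed replicates = {report.n_failed[m]}"
        )
    return "\n".join(lines)
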