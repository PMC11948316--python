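"""Benchmark bookkeeping: quality-bin counts, success rates, method comparison.

For a set of targets, each contributing the DockQ result of its selected model
plus a docked/misdocked flag, this module computes:

* quality-bin counts among the viable (docked) models;
* the effective success rate — acceptable-or-better models as a fraction of
  viable models, reported to the nearest integer percent;
* the overall success rate — acceptable-or-better models over all targets,
  reported to one decimal percent;
* head-to-head comparisons between two methods, including the "rescue" count:
  targets where one method reaches acceptable quality while the other is
  incorrect.

Misdocked targets count toward the overall denominator but are excluded from
the effective rate's denominator. Rounding is half-up at the stated precision.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal

import pandas as pd

from .dockq import ACCEPTABLE_OR_BETTER, DockQResult
from .errors import ValidationError

CATEGORIES = ("high", "medium", "acceptable", "incorrect")


@dataclass(frozen=True)
class TargetResult:
    """One benchmark target: its selected model's evaluation and docked flag."""

    target_id: str
    result: DockQResult | None
    docked: bool

    def acceptable_or_better(self) -> bool:
        return self.result is not None and self.result.category in ACCEPTABLE_OR_BETTER


@dataclass(frozen=True)
class BenchmarkSummary:
    """Aggregated benchmark outcome over a target set."""

    n_total: int
    n_viable: int
    counts: dict[str, int]              # per-category counts among viable targets
    n_acceptable_or_better: int         # over all targets
    effective_success_rate: float | None  # % of viable, nearest integer; None if no viable
    overall_rate: float                 # % of all targets, one decimal


def _round_half_up(value: float, decimals: int) -> float:
    q = Decimal(1).scaleb(-decimals)
    return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))


def summarize(results: list[TargetResult]) -> BenchmarkSummary:
    """Aggregate per-target results into bin counts and success rates."""
    if not results:
        raise ValidationError("cannot summarize an empty result collection")
    viable = [r for r in results if r.docked]
    counts = {c: 0 for c in CATEGORIES}
    for r in viable:
        if r.result is not None:
            counts[r.result.category] += 1
    viable_success = sum(counts[c] for c in ACCEPTABLE_OR_BETTER)
    overall_success = sum(1 for r in results if r.acceptable_or_better())
    effective = (
        _round_half_up(100.0 * viable_success / len(viable), 0) if viable else None
    )
    overall = _round_half_up(100.0 * overall_success / len(results), 1)
    return BenchmarkSummary(
        n_total=len(results),
        n_viable=len(viable),
        counts=counts,
        n_acceptable_or_better=overall_success,
        effective_success_rate=effective,
        overall_rate=overall,
    )


def compare(a: list[TargetResult], b: list[TargetResult]):
    """Per-target comparison of two methods over the same target set.

    Returns ``(table, rescues_a_over_b, rescues_b_over_a)`` where a rescue by
    method a is a target with a acceptable-or-better while b is incorrect.
    """
    a_by_id = {r.target_id: r for r in a}
    b_by_id = {r.target_id: r for r in b}
    if a_by_id.keys() != b_by_id.keys():
        only_a = sorted(a_by_id.keys() - b_by_id.keys())
        only_b = sorted(b_by_id.keys() - a_by_id.keys())
        raise ValidationError(
            f"target sets differ: only in a {only_a}, only in b {only_b}"
        )
    rows = []
    rescues_ab = rescues_ba = 0
    for tid in sorted(a_by_id):
        ra, rb = a_by_id[tid], b_by_id[tid]
        qa = ra.result.dockq if ra.result else None
        qb = rb.result.dockq if rb.result else None
        rescue_ab = ra.acceptable_or_better() and not rb.acceptable_or_better()
        rescue_ba = rb.acceptable_or_better() and not ra.acceptable_or_better()
        rescues_ab += rescue_ab
        rescues_ba += rescue_ba
        rows.append(
            {
                "target": tid,
                "dockq_a": qa,
                "dockq_b": qb,
                "category_a": ra.result.category if ra.result else None,
                "category_b": rb.result.category if rb.result else None,
                "rescue_a_over_b": rescue_ab,
                "rescue_b_over_a": rescue_ba,
            }
        )
    return pd.DataFrame(rows), rescues_ab, rescues_ba


def summary_table(summary: BenchmarkSummary) -> pd.DataFrame:
    """One-row summary suitable for TSV output."""
    row = {
        "n_total": summary.n_total,
        "n_viable": summary.n_viable,
        **{f"n_{c}": summary.counts[c] for c in CATEGORIES},
        "n_acceptable_or_better": summary.n_acceptable_or_better,
        "effective_success_rate_pct": summary.effective_success_rate,
        "overall_rate_pct": summary.overall_rate,
    }
    return pd.DataFrame([row])


def plot_quality_bins(summaries: dict[str, BenchmarkSummary], ax=None):
    """Stacked-bar chart of quality-bin counts per method (matplotlib Axes)."""
    import matplotlib

    matplotlib.use("Agg", force=False)
    import matplotlib.pyplot as plt

    if ax is None:
        _, ax = plt.subplots(figsize=(1.5 + 1.2 * len(summaries), 4))
    labels = list(summaries)
    bottoms = [0] * len(labels)
    colors = {"high": "#1b9e77", "medium": "#7570b3", "acceptable": "#d95f02"}
    for category in ("high", "medium", "acceptable"):
        heights = [summaries[m].counts[category] for m in labels]
        ax.bar(labels, heights, bottom=bottoms, label=category, color=colors[category])
        bottoms = [b + h for b, h in zip(bottoms, heights)]
    ax.set_ylabel("targets")
    ax.legend(frameon=False)
    return ax
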