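"""League tables, dominance filtering, the constrained expansion path and
budget allocation.

Cost-effectiveness ratios follow the reporting conventions of WHO-CHOICE
league tables: costs are carried in million I$ 2010 per 10 million
population, effects in healthy life years (undiscounted) per 10 million
population, and ratios are rounded half-up — to the integer for league-table
ACERs/ICERs and to two decimals for programme-level ACERs.

The expansion path is a greedy walk along the efficiency frontier under a
technology lock-in constraint: once a technology has been adopted at some
coverage, every later candidate must retain it at the same or higher
coverage (a decision maker does not scale an intervention up only to swap it
out later).  Technology families (e.g. the cervical prevention package, a
treatment programme, palliative care) are independent arms interleaved
purely by ICER order.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from itertools import combinations

import pandas as pd


def round_half_up(x: float, decimals: int = 0) -> float:
    """Decimal-style rounding (0.5 always rounds away from zero)."""
    factor = 10.0**decimals
    return math.floor(abs(x) * factor + 0.5) / factor * (1 if x >= 0 else -1)


class DominatedError(ValueError):
    """Signals a non-positive incremental HLY (dominance, not a crash)."""


@dataclass(frozen=True)
class EvalResult:
    """One evaluated (scenario package, coverage) point versus the null."""

    label: str
    coverages: tuple[tuple[str, float], ...]  # technology -> coverage
    cost_million: float  # total discounted cost, million I$ / 10M pop
    hly: float  # undiscounted HLY gain / 10M pop
    hly_discounted: float = 0.0
    arm: str = ""  # technology-family arm, e.g. "cervical/prevention"
    region: str = ""
    description: str = ""

    def __post_init__(self) -> None:
        if self.cost_million < -1e-9:
            raise ValueError("cost must be >= 0")

    @property
    def coverage_map(self) -> dict[str, float]:
        return dict(self.coverages)


def acer(cost_million: float, hly: float, decimals: int = 0) -> float:
    """Average cost-effectiveness ratio, I$ per HLY gained vs the null."""
    if hly <= 0:
        if cost_million == 0 and hly == 0:
            return 0.0
        raise ValueError("ACER needs a positive HLY gain")
    if cost_million == 0:
        return 0.0
    return round_half_up(cost_million * 1e6 / hly, decimals)


def icer(prev: EvalResult, nxt: EvalResult, decimals: int = 0) -> float:
    """Incremental cost per incremental HLY versus the previous point."""
    d_hly = nxt.hly - prev.hly
    d_cost = nxt.cost_million - prev.cost_million
    if d_hly <= 0:
        raise DominatedError(
            f"{nxt.label} gains no HLY over {prev.label} (dominated)"
        )
    return round_half_up(d_cost * 1e6 / d_hly, decimals)


NULL_POINT = EvalResult("null", (), 0.0, 0.0, 0.0, arm="null")


# ---------------------------------------------------------------------------
# dominance
# ---------------------------------------------------------------------------


def dominance_filter(
    results: list[EvalResult],
) -> tuple[list[EvalResult], list[EvalResult]]:
    """Split results into the efficiency frontier and the dominated set.

    Strict dominance (another point with >= HLY at <= cost, strictly better
    in one) and extended dominance (a convex combination of other points
    dominates) are both removed.  The frontier comes back sorted by HLY with
    non-decreasing ICERs.
    """
    if not results:
        raise ValueError("need at least one result")
    pts = sorted(results, key=lambda r: (r.hly, -r.cost_million))
    dominated: list[EvalResult] = []
    # simple dominance
    keep = []
    for r in pts:
        if any(
            (o.hly >= r.hly and o.cost_million <= r.cost_million)
            and (o.hly > r.hly or o.cost_million < r.cost_million)
            for o in pts
        ):
            dominated.append(r)
        else:
            keep.append(r)
    # extended dominance: walk the cost-sorted survivors keeping the convex
    # lower envelope (non-decreasing incremental ratios from the origin)
    keep.sort(key=lambda r: (r.cost_million, -r.hly))
    frontier: list[EvalResult] = []
    for r in keep:
        while frontier:
            prev = frontier[-1]
            before = frontier[-2] if len(frontier) > 1 else NULL_POINT
            ratio_prev = _raw_icer(before, prev)
            ratio_next = _raw_icer(prev, r)
            if ratio_next < ratio_prev - 1e-12:
                dominated.append(frontier.pop())  # extended-dominated
            else:
                break
        frontier.append(r)
    frontier.sort(key=lambda r: r.hly)
    return frontier, dominated


def _raw_icer(prev: EvalResult, nxt: EvalResult) -> float:
    d_hly = nxt.hly - prev.hly
    if d_hly <= 0:
        return math.inf
    return (nxt.cost_million - prev.cost_million) * 1e6 / d_hly


def dominance_filter_bruteforce(
    results: list[EvalResult],
) -> tuple[list[EvalResult], list[EvalResult]]:
    """O(n^2) + convex-combination oracle used to cross-check the filter."""
    frontier, dominated = [], []
    for r in results:
        simple = any(
            (o.hly >= r.hly and o.cost_million <= r.cost_million)
            and (o.hly > r.hly or o.cost_million < r.cost_million)
            for o in results
        )
        extended = False
        if not simple:
            others = [o for o in results if o is not r] + [NULL_POINT]
            for a, b in combinations(others, 2):
                lo, hi = sorted((a, b), key=lambda x: x.hly)
                if lo.hly <= r.hly <= hi.hly and hi.hly > lo.hly:
                    t = (r.hly - lo.hly) / (hi.hly - lo.hly)
                    mix_cost = lo.cost_million + t * (hi.cost_million - lo.cost_million)
                    if mix_cost < r.cost_million - 1e-12:
                        extended = True
                        break
        (dominated if simple or extended else frontier).append(r)
    frontier.sort(key=lambda r: r.hly)
    return frontier, dominated


# ---------------------------------------------------------------------------
# expansion path
# ---------------------------------------------------------------------------


@dataclass
class PathStep:
    rank: int
    result: EvalResult
    incremental_cost: float  # million I$
    incremental_hly: float
    acer: float  # vs null, integer I$/HLY
    icer: float  # vs previous point on the same arm

    @property
    def label(self) -> str:
        return self.result.label


@dataclass
class ExpansionPath:
    steps: list[PathStep] = field(default_factory=list)
    complete: bool = True

    def final_point(self, arm: str) -> EvalResult:
        for step in reversed(self.steps):
            if step.result.arm == arm:
                return step.result
        return NULL_POINT

    @property
    def arms(self) -> list[str]:
        seen: list[str] = []
        for s in self.steps:
            if s.result.arm not in seen:
                seen.append(s.result.arm)
        return seen

    def total_cost_million(self) -> float:
        return sum(self.final_point(a).cost_million for a in self.arms)

    def total_hly(self) -> float:
        return sum(self.final_point(a).hly for a in self.arms)


def _feasible(current: EvalResult, candidate: EvalResult) -> bool:
    """Lock-in: candidate keeps every adopted technology at >= its coverage."""
    cur = current.coverage_map
    cand = candidate.coverage_map
    return all(cand.get(tech, 0.0) >= cov - 1e-12 for tech, cov in cur.items())


def expansion_path(results_by_arm: dict[str, list[EvalResult]]) -> ExpansionPath:
    """Greedy constrained frontier walk over independent technology arms.

    Each arm starts at the null; at every step the feasible candidates are
    the not-yet-adopted packages of any arm that retain that arm's adopted
    technologies at the same or higher coverage and add health; the candidate
    with the lowest ICER against its arm's current point is adopted.  The
    walk ends when no arm has a feasible health-adding candidate left
    (``complete`` is False if any arm still had candidates that were
    infeasible or health-neutral).
    """
    current: dict[str, EvalResult] = {arm: NULL_POINT for arm in results_by_arm}
    remaining = {arm: list(pts) for arm, pts in results_by_arm.items()}
    steps: list[PathStep] = []
    rank = 1
    while True:
        best: tuple[float, str, EvalResult] | None = None
        for arm, pts in remaining.items():
            cur = current[arm]
            for r in pts:
                if r.hly <= cur.hly or not _feasible(cur, r):
                    continue
                ratio = _raw_icer(cur, r)
                if best is None or ratio < best[0] - 1e-12 or (
                    abs(ratio - best[0]) <= 1e-12 and r.label < best[2].label
                ):
                    best = (ratio, arm, r)
        if best is None:
            break
        _, arm, chosen = best
        cur = current[arm]
        steps.append(
            PathStep(
                rank=rank,
                result=chosen,
                incremental_cost=chosen.cost_million - cur.cost_million,
                incremental_hly=chosen.hly - cur.hly,
                acer=acer(chosen.cost_million, chosen.hly),
                icer=icer(cur, chosen),
            )
        )
        rank += 1
        current[arm] = chosen
        remaining[arm] = [
            r for r in remaining[arm] if r.hly > chosen.hly and r is not chosen
        ]
    leftovers = any(pts for pts in remaining.values())
    return ExpansionPath(steps=steps, complete=not leftovers)


def expansion_path_bruteforce(
    results_by_arm: dict[str, list[EvalResult]],
) -> ExpansionPath:
    """Exhaustive-enumeration oracle for tiny instances (<= ~12 points).

    Enumerates, at every step, *all* remaining packages of all arms, applies
    the lock-in constraint directly and adopts the minimum-ICER candidate;
    written independently of the production walk (no candidate pruning) so
    the two can be compared exactly.
    """
    current = {arm: NULL_POINT for arm in results_by_arm}
    adopted: set[tuple[str, str]] = set()
    steps: list[PathStep] = []
    rank = 1
    while True:
        candidates = []
        for arm, pts in results_by_arm.items():
            for r in pts:
                key = (arm, r.label + repr(sorted(r.coverages)))
                if key in adopted:
                    continue
                cur = current[arm]
                ok = r.hly > cur.hly and all(
                    dict(r.coverages).get(t, 0.0) >= c - 1e-12
                    for t, c in cur.coverages
                )
                if ok:
                    candidates.append((_raw_icer(cur, r), r.label, arm, r, key))
        if not candidates:
            break
        candidates.sort(key=lambda x: (x[0], x[1]))
        ratio, _, arm, chosen, key = candidates[0]
        cur = current[arm]
        steps.append(
            PathStep(
                rank,
                chosen,
                chosen.cost_million - cur.cost_million,
                chosen.hly - cur.hly,
                acer(chosen.cost_million, chosen.hly),
                icer(cur, chosen),
            )
        )
        rank += 1
        current[arm] = chosen
        adopted.add(key)
        for a, pts in results_by_arm.items():
            if a == arm:
                for r in pts:
                    if r.hly <= chosen.hly:
                        adopted.add((a, r.label + repr(sorted(r.coverages))))
    return ExpansionPath(steps=steps)


# ---------------------------------------------------------------------------
# reporting
# ---------------------------------------------------------------------------


def budget_allocation(
    path: ExpansionPath, arm_to_cancer=lambda arm: arm.split("/")[0]
) -> dict[str, int]:
    """Percent budget share per cancer at the end of the expansion path.

    Shares are total discounted cost of each cancer's final adopted packages
    over the grand total, rounded half-up to integer percent (shares sum to
    100 +/- 1 by rounding).
    """
    if not path.steps:
        raise ValueError("cannot allocate a budget over an empty path")
    totals: dict[str, float] = {}
    for arm in path.arms:
        cancer = arm_to_cancer(arm)
        totals[cancer] = totals.get(cancer, 0.0) + path.final_point(arm).cost_million
    grand = sum(totals.values())
    if grand <= 0:
        raise ValueError("zero total cost on the path")
    return {c: int(round_half_up(100.0 * v / grand)) for c, v in totals.items()}


def budget_allocation_from_costs(costs_by_cancer: dict[str, float]) -> dict[str, int]:
    """Same rounding rule applied to externally supplied cost totals."""
    grand = sum(costs_by_cancer.values())
    if grand <= 0:
        raise ValueError("zero total cost")
    return {
        c: int(round_half_up(100.0 * v / grand)) for c, v in costs_by_cancer.items()
    }


def league_table(path: ExpansionPath, dominated: list[EvalResult] | None = None):
    """League-table DataFrame in path order (label, description, coverage,
    cost, HLY, ACER, ICER)."""
    rows = []
    for s in path.steps:
        rows.append(
            {
                "label": s.result.label,
                "description": s.result.description,
                "coverage_pct": int(round_half_up(100 * max(
                    (c for _, c in s.result.coverages), default=0.0
                ))),
                "cost_million_I$": s.result.cost_million,
                "hly_undiscounted": s.result.hly,
                "acer": s.acer,
                "icer": s.icer,
            }
        )
    table = pd.DataFrame(
        rows,
        columns=[
            "label",
            "description",
            "coverage_pct",
            "cost_million_I$",
            "hly_undiscounted",
            "acer",
            "icer",
        ],
    )
    if dominated is None:
        return table
    dom = pd.DataFrame(
        [
            {
                "label": r.label,
                "description": r.description,
                "cost_million_I$": r.cost_million,
                "hly_undiscounted": r.hly,
            }
            for r in dominated
        ],
        columns=["label", "description", "cost_million_I$", "hly_undiscounted"],
    )
    return table, dom


def programme_acer(total_cost: float, total_hly: float) -> float:
    """Full-package ACER: grand cost / grand HLY, two decimals.

    ``total_cost`` here is in plain I$ (the budget tables print plain I$).
    """
    if total_hly <= 0:
        raise ValueError("needs positive HLY")
    return round_half_up(total_cost / total_hly, 2)
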