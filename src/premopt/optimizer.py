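"""Capped-improvement prioritization of experience items.

Given a fitted proportional-odds model and the per-item baseline means x̄_j of
one stratum, the task is to pick percentage improvements δ_j (multiplicative on
the baseline: x_j -> x̄_j (1 + δ_j/100)) that raise model-predicted overall
satisfaction by a target percentage t, at minimum total effort Σ_j δ_j, with
each δ_j capped at ``cap`` percent (default 15) and additionally by the scale
ceiling: an item already at the top of the 1-5 scale has no headroom
(:func:`effective_cap`).

Predicted satisfaction is evaluated at the stratum mean vector ("mean
patient") through either the expected score Σ_k k p_k or the top-box
probability P(Y = 5).  Both are strictly increasing functions of the linear
predictor η = Σ_j b_j x̄_j (1 + δ_j/100), which is *linear* in δ.  The
minimum-effort problem is therefore a continuous knapsack: reaching the target
is equivalent to reaching a required η, each percentage point of δ_j buys
w_j = b_j x̄_j / 100 units of η, and the optimal policy fills items in
decreasing w_j until the requirement is met — several items pinned at the cap
plus one fractional marginal item.  :func:`solve_improvement` implements this
exactly; :func:`brute_force_oracle` provides an independent grid-search check
for small instances.

Targets above :func:`feasibility_bound` (every eligible item at its cap) are
infeasible; because satisfaction baselines sit near the top of the scale, the
bound is small — gains beyond a few percent are typically unreachable.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import json
import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .errors import DomainError
from .ordinal_model import OrdinalFit, category_probs

METRICS = ("expected_score", "top_box")
SELECTION_TOL = 1e-3  # delta below this counts as "not selected"


@dataclass
class ImprovementProblem:
    """One optimization instance: model, baselines, caps and target."""

    fit: OrdinalFit
    baseline: np.ndarray
    target: float = 1.0
    cap: float = 15.0
    scale_max: float = 5.0
    metric: str = "expected_score"
    eligible: tuple[str, ...] | None = None  # default: items with b_j > 0

    def __post_init__(self) -> None:
        self.baseline = np.asarray(self.baseline, float)
        if self.baseline.shape != (len(self.fit.item_ids),):
            raise DomainError(
                f"baseline length {self.baseline.shape} does not match "
                f"{len(self.fit.item_ids)} fitted items"
            )
        if np.any(self.baseline < 1.0) or np.any(self.baseline > self.scale_max):
            raise DomainError(f"baseline values must lie in [1, {self.scale_max}]")
        if self.cap < 0 or self.target < 0:
            raise DomainError("cap and target must be nonnegative")
        if self.metric not in METRICS:
            raise DomainError(f"metric must be one of {METRICS}")
        if self.eligible is not None:
            unknown = [i for i in self.eligible if i not in self.fit.item_ids]
            if unknown:
                raise DomainError(f"eligible items not in fit: {unknown}")
            self.eligible = tuple(self.eligible)

    @property
    def eligible_items(self) -> tuple[str, ...]:
        if self.eligible is not None:
            return self.eligible
        return tuple(i for i, bj in zip(self.fit.item_ids, self.fit.b) if bj > 0)

    @property
    def eligible_mask(self) -> np.ndarray:
        elig = set(self.eligible_items)
        return np.array([i in elig for i in self.fit.item_ids])


@dataclass
class ImprovementSolution:
    """Solved per-item improvement vector with feasibility status."""

    item_ids: tuple[str, ...]
    delta: np.ndarray
    achieved: float
    objective: float
    selected: tuple[str, ...]
    status: str  # feasible | infeasible

    def delta_of(self, item_id: str) -> float:
        return float(self.delta[self.item_ids.index(item_id)])


def _score_of_eta(problem: ImprovementProblem, eta: float) -> float:
    if problem.metric == "top_box":
        return float(1.0 - expit(problem.fit.kappa[-1] - eta))
    probs = category_probs(problem.fit.kappa, float(eta))
    return float(probs @ np.asarray(problem.fit.categories, float))


def _caps_vector(problem: ImprovementProblem) -> np.ndarray:
    head = 100.0 * (problem.scale_max - problem.baseline) / problem.baseline
    return np.minimum(problem.cap, head)


def baseline_score(problem: ImprovementProblem) -> float:
    """Predicted satisfaction metric at the unimproved stratum mean vector."""
    return _score_of_eta(problem, float(problem.fit.b @ problem.baseline))


def effective_cap(problem: ImprovementProblem, item_id: str) -> float:
    """Per-item cap: the configured percent cap or the scale-ceiling headroom."""
    j = problem.fit.item_ids.index(item_id)
    return float(_caps_vector(problem)[j])


def predicted_improvement(problem: ImprovementProblem, delta: Sequence[float]) -> float:
    """Percent gain in the metric when item means scale by (1 + delta/100)."""
    delta = np.asarray(delta, float)
    if delta.shape != problem.baseline.shape:
        raise DomainError("delta length does not match the problem items")
    caps = _caps_vector(problem)
    if np.any(delta < -1e-9) or np.any(delta > caps + 1e-9):
        raise DomainError("delta outside [0, effective cap]")
    s0 = baseline_score(problem)
    eta = float(problem.fit.b @ (problem.baseline * (1.0 + delta / 100.0)))
    return 100.0 * (_score_of_eta(problem, eta) - s0) / s0


def feasibility_bound(problem: ImprovementProblem) -> float:
    """Maximum achievable percent gain: every eligible item at its effective cap."""
    caps = np.where(problem.eligible_mask, _caps_vector(problem), 0.0)
    # pushing an item with b_j <= 0 to its cap would lower the score
    caps = np.where(problem.fit.b > 0, caps, 0.0)
    return predicted_improvement(problem, caps)


def solve_improvement(problem: ImprovementProblem) -> ImprovementSolution:
    """Minimum-total-effort improvement vector meeting the target gain.

    Exact greedy solution of the continuous knapsack the problem reduces to
    (see module docstring).  Ties in efficiency w_j = b_j x̄_j are broken by
    larger b_j, then by item order.  Infeasible targets return the all-caps
    vector as a diagnostic, with ``achieved`` equal to the feasibility bound.
    """
    items = problem.fit.item_ids
    J = len(items)
    b = problem.fit.b
    caps_all = _caps_vector(problem)
    caps = np.where(problem.eligible_mask & (b > 0), caps_all, 0.0)
    w = b * problem.baseline / 100.0  # d(eta)/d(delta_j)

    zero = np.zeros(J)
    if problem.target <= 0:
        return ImprovementSolution(items, zero, 0.0, 0.0, (), "feasible")

    s0 = baseline_score(problem)
    s_req = s0 * (1.0 + problem.target / 100.0)
    eta0 = float(b @ problem.baseline)
    eta_max = eta0 + float((w * caps)[w > 0].sum())
    bound = 100.0 * (_score_of_eta(problem, eta_max) - s0) / s0
    if bound < problem.target - 1e-9:
        delta = caps.copy()
        sel = tuple(i for i, d in zip(items, delta) if d > SELECTION_TOL)
        return ImprovementSolution(items, delta, bound, float(delta.sum()), sel, "infeasible")

    if _score_of_eta(problem, eta0) >= s_req:
        eta_req = eta0
    else:
        eta_req = brentq(
            lambda e: _score_of_eta(problem, e) - s_req, eta0, eta_max, xtol=1e-12
        )
    need = eta_req - eta0

    order = sorted(
        (j for j in range(J) if caps[j] > 0 and w[j] > 0),
        key=lambda j: (-w[j], -b[j], j),
    )
    delta = np.zeros(J)
    for j in order:
        if need <= 0:
            break
        take = min(caps[j], need / w[j])
        delta[j] = take
        need -= w[j] * take
    achieved = predicted_improvement(problem, delta)
    # guard against root-finding round-off on the marginal item
    if achieved < problem.target:
        for j in order:
            if delta[j] < caps[j]:
                delta[j] = min(caps[j], delta[j] + 1e-9)
                break
        achieved = predicted_improvement(problem, delta)
    sel = tuple(i for i, d in zip(items, delta) if d > SELECTION_TOL)
    return ImprovementSolution(items, delta, achieved, float(delta.sum()), sel, "feasible")


def brute_force_oracle(problem: ImprovementProblem, grid_step: float = 0.1) -> ImprovementSolution:
    """Exhaustive grid search over the eligible deltas (test oracle, <= 4 items)."""
    items = problem.fit.item_ids
    elig = [j for j, i in enumerate(items) if i in problem.eligible_items]
    if len(elig) > 4:
        raise DomainError(
            f"{len(elig)} eligible items: the exhaustive oracle only handles <= 4; "
            "restrict problem.eligible or use solve_improvement"
        )
    caps = _caps_vector(problem)
    if problem.target <= 0:
        return ImprovementSolution(items, np.zeros(len(items)), 0.0, 0.0, (), "feasible")

    grids = []
    for j in elig:
        g = np.arange(0.0, caps[j] + grid_step * 0.5, grid_step)
        if len(g) == 0 or g[-1] < caps[j] - 1e-12:
            g = np.append(g, caps[j])
        grids.append(g)
    mesh = np.meshgrid(*grids, indexing="ij")
    flat = np.stack([m.ravel() for m in mesh], axis=1)  # (G, n_elig)

    b = problem.fit.b
    w = b * problem.baseline / 100.0
    s0 = baseline_score(problem)
    eta0 = float(b @ problem.baseline)
    etas = eta0 + flat @ w[elig]
    if problem.metric == "top_box":
        scores = 1.0 - expit(problem.fit.kappa[-1] - etas)
    else:
        probs = category_probs(problem.fit.kappa, etas)
        scores = probs @ np.asarray(problem.fit.categories, float)
    gains = 100.0 * (scores - s0) / s0
    feasible = gains >= problem.target - 1e-9
    if not feasible.any():
        delta = np.zeros(len(items))
        delta[elig] = caps[elig]
        bound = float(gains.max())
        sel = tuple(i for i, d in zip(items, delta) if d > SELECTION_TOL)
        return ImprovementSolution(items, delta, bound, float(delta.sum()), sel, "infeasible")
    objectives = flat.sum(axis=1)
    objectives = np.where(feasible, objectives, np.inf)
    best = int(np.argmin(objectives))
    delta = np.zeros(len(items))
    delta[elig] = flat[best]
    sel = tuple(i for i, d in zip(items, delta) if d > SELECTION_TOL)
    return ImprovementSolution(
        items, delta, float(gains[best]), float(flat[best].sum()), sel, "feasible"
    )


# -- priority tables -------------------------------------------------------


@dataclass
class PriorityTable:
    """Items x targets matrix of required per-item improvements for one stratum."""

    item_ids: tuple[str, ...]
    targets: tuple[float, ...]
    delta: np.ndarray  # (items, targets); NaN = not selected / infeasible column
    counts: np.ndarray  # selected items per target
    feasible: np.ndarray  # bool per target
    stratum: str | None = None

    def __post_init__(self) -> None:
        nonempty = np.sum(~np.isnan(self.delta), axis=0)
        if not np.array_equal(nonempty, self.counts):
            raise DomainError("counts row must equal the number of nonempty cells per column")
        if np.any(nonempty[~self.feasible]):
            raise DomainError("infeasible target columns must carry no cells")

    def to_frame(self, rounded: bool = True) -> pd.DataFrame:
        """Display table: one row per item, one column per target, counts row last."""
        cols = {}
        for t_idx, t in enumerate(self.targets):
            col = []
            for i_idx in range(len(self.item_ids)):
                v = self.delta[i_idx, t_idx]
                if np.isnan(v):
                    col.append("")
                else:
                    col.append(f"{round(v, 1):g}" if rounded else repr(v))
            col.append("Unfeasible" if not self.feasible[t_idx] else str(int(self.counts[t_idx])))
            cols[f"{t:g}%"] = col
        index = list(self.item_ids) + ["required_items_n"]
        return pd.DataFrame(cols, index=pd.Index(index, name="item"))

    def counts_frame(self) -> pd.DataFrame:
        """One-row table of selected-item counts per target (infeasible flagged)."""
        row = {
            f"{t:g}%": ("Unfeasible" if not f else int(c))
            for t, c, f in zip(self.targets, self.counts, self.feasible)
        }
        return pd.DataFrame([row], index=pd.Index([self.stratum or "all"], name="stratum"))

    def to_csv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path)

    def to_markdown(self) -> str:
        frame = self.to_frame()
        header = "| item | " + " | ".join(frame.columns) + " |"
        sep = "|" + "---|" * (len(frame.columns) + 1)
        lines = [header, sep]
        for idx, row in frame.iterrows():
            lines.append("| " + " | ".join([str(idx)] + [str(v) for v in row]) + " |")
        return "\n".join(lines) + "\n"

    def to_dict(self) -> dict:
        return {
            "item_ids": list(self.item_ids),
            "targets": list(self.targets),
            "delta": [[None if np.isnan(v) else v for v in row] for row in self.delta],
            "counts": self.counts.tolist(),
            "feasible": self.feasible.tolist(),
            "stratum": self.stratum,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PriorityTable":
        delta = np.array(
            [[np.nan if v is None else v for v in row] for row in d["delta"]], float
        )
        if delta.size == 0:
            delta = delta.reshape(len(d["item_ids"]), len(d["targets"]))
        return cls(
            item_ids=tuple(d["item_ids"]),
            targets=tuple(d["targets"]),
            delta=delta,
            counts=np.asarray(d["counts"], int),
            feasible=np.asarray(d["feasible"], bool),
            stratum=d.get("stratum"),
        )

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2) + "\n")


def build_priority_table(
    fit: OrdinalFit,
    baseline: Sequence[float],
    targets: Sequence[float],
    cap: float = 15.0,
    metric: str = "expected_score",
    eligible: Sequence[str] | None = None,
    stratum: str | None = None,
) -> PriorityTable:
    """Solve once per target and assemble the items-by-targets priority table."""
    targets = list(targets)
    if any(t < 0 for t in targets) or sorted(targets) != targets:
        raise DomainError("targets must be nonnegative and sorted ascending")
    items = fit.item_ids
    delta = np.full((len(items), len(targets)), np.nan)
    counts = np.zeros(len(targets), int)
    feas = np.zeros(len(targets), bool)
    for t_idx, t in enumerate(targets):
        problem = ImprovementProblem(
            fit=fit,
            baseline=np.asarray(baseline, float),
            target=float(t),
            cap=cap,
            metric=metric,
            eligible=None if eligible is None else tuple(eligible),
        )
        sol = solve_improvement(problem)
        feas[t_idx] = sol.status == "feasible"
        if feas[t_idx]:
            for i_idx, item in enumerate(items):
                if sol.delta[i_idx] > SELECTION_TOL:
                    delta[i_idx, t_idx] = sol.delta[i_idx]
            counts[t_idx] = len(sol.selected)
    return PriorityTable(
        item_ids=items,
        targets=tuple(float(t) for t in targets),
        delta=delta,
        counts=counts,
        feasible=feas,
        stratum=stratum,
    )
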