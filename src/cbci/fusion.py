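"""Confidence-weighted group decision fusion and exhaustive group evaluation.

Each observer's yes/no decision on a trial is scaled by a positive weight
derived from a confidence proxy x (response time, the neural feature nf, or
a mixture) through a negative-exponential weighting function

    w(x) = exp(-a * (x - c)),   a > 0,

which is strictly decreasing and always positive, so that a confident
minority can outweigh an uncertain majority without any weight ever flipping
a vote.  The group decides "yes" when the summed weights of yes-voters
exceed those of no-voters.  Defaults a=1, c_RT=4.0 s, c_nf=2.5 put the two
weight scales in the same range (the shifts differ by 1.5 because typical
RTs sit around +0.7 s while nf sits around -0.75); the RTnf mixture is
alpha*w_RT + (1-alpha)*w_nf with alpha=0.75, weighting the more reliable
behavioural measure more heavily.

Plain majority is evaluated with expected-value tie handling: an even split
earns credit 0.5 rather than an actual coin flip.  A group's response time
on a trial is the maximum member RT (everyone must have answered);
fastest-responder variants fuse only the v quickest members per trial, and
their group RT is the v-th smallest member RT.

``evaluate_all_groups`` scores every one of the C(m, n) groups of size n
over all trials.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from math import comb

import numpy as np
import pandas as pd

METHODS = ("majority", "RT", "nf", "RTnf")


@dataclass(frozen=True)
class WeightParams:
    """Constants of the weighting function and the RTnf mixture."""

    a: float = 1.0
    c_rt: float = 4.0
    c_nf: float = 2.5
    alpha: float = 0.75

    def __post_init__(self) -> None:
        if self.a <= 0:
            raise ValueError("scale a must be positive")
        if not 0.0 <= self.alpha <= 1.0:
            raise ValueError("alpha must lie in [0, 1]")


def weight(x, a: float = 1.0, c: float = 0.0):
    """Negative-exponential weighting function w(x) = exp(-a (x - c))."""
    return np.exp(-a * (np.asarray(x, dtype=float) - c))


def rt_weight(rt, params: WeightParams = WeightParams()):
    return weight(rt, params.a, params.c_rt)


def nf_weight(nf, params: WeightParams = WeightParams()):
    return weight(nf, params.a, params.c_nf)


def combine_rtnf(w_rt, w_nf, alpha: float = 0.75):
    """Linear mixture alpha*w_RT + (1-alpha)*w_nf."""
    if not 0.0 <= alpha <= 1.0:
        raise ValueError("alpha must lie in [0, 1]")
    return alpha * np.asarray(w_rt, dtype=float) + (1.0 - alpha) * np.asarray(w_nf, dtype=float)


@dataclass
class MemberVote:
    """One observer's decision on one trial, with its decision weights."""

    participant_id: str
    decision: str  # "yes" (identical) | "no" (different)
    rt: float
    nf: float = 0.0
    weights: dict = field(default_factory=dict)  # method -> positive weight

    def __post_init__(self) -> None:
        if self.decision not in ("yes", "no"):
            raise ValueError("decision must be 'yes' or 'no'")
        if self.rt <= 0:
            raise ValueError("rt must be positive")

    @classmethod
    def build(cls, participant_id, decision, rt, nf, params: WeightParams = WeightParams()):
        w_rt = float(rt_weight(rt, params))
        w_nf = float(nf_weight(nf, params))
        return cls(
            participant_id=participant_id,
            decision=decision,
            rt=rt,
            nf=nf,
            weights={"RT": w_rt, "nf": w_nf, "RTnf": float(combine_rtnf(w_rt, w_nf, params.alpha))},
        )


@dataclass(frozen=True)
class GroupTrialOutcome:
    decision: str  # "yes" | "no" | "tie"
    credit: float  # 1, 0.5 or 0
    group_rt: float


def _outcome(yes_score: float, no_score: float, truth: str, group_rt: float) -> GroupTrialOutcome:
    if yes_score > no_score:
        decision = "yes"
    elif yes_score < no_score:
        decision = "no"
    else:
        return GroupTrialOutcome("tie", 0.5, group_rt)
    truth_decision = "yes" if truth == "identical" else "no"
    return GroupTrialOutcome(decision, 1.0 if decision == truth_decision else 0.0, group_rt)


def fuse_majority(votes: list[MemberVote], truth: str) -> GroupTrialOutcome:
    """Unweighted vote count; an even split earns expected credit 0.5."""
    if not votes:
        raise ValueError("cannot fuse an empty group")
    yes = sum(v.decision == "yes" for v in votes)
    group_rt = max(v.rt for v in votes)
    return _outcome(float(yes), float(len(votes) - yes), truth, group_rt)


def fuse_weighted(votes: list[MemberVote], method: str, truth: str) -> GroupTrialOutcome:
    """Confidence-weighted fusion: compare summed weights of yes vs no voters."""
    if not votes:
        raise ValueError("cannot fuse an empty group")
    if method not in ("RT", "nf", "RTnf"):
        raise ValueError("method must be 'RT', 'nf' or 'RTnf'")
    yes = sum(v.weights[method] for v in votes if v.decision == "yes")
    no = sum(v.weights[method] for v in votes if v.decision == "no")
    group_rt = max(v.rt for v in votes)
    return _outcome(yes, no, truth, group_rt)


@dataclass
class VoteMatrices:
    """Per-(participant, trial) matrices shared by the group evaluators."""

    participants: list[str]
    decisions: np.ndarray  # (m, T), +1 yes / -1 no
    truth: np.ndarray  # (T,), +1 identical / -1 different
    rt: np.ndarray  # (m, T) seconds
    nf: np.ndarray  # (m, T)
    weights: dict  # method -> (m, T); "majority" -> ones
    dom: np.ndarray  # (T,)

    @property
    def m(self) -> int:
        return len(self.participants)

    @property
    def n_trials(self) -> int:
        return self.decisions.shape[1]

    @classmethod
    def from_table(cls, votes: pd.DataFrame, params: WeightParams = WeightParams()):
        """Build from a tidy table with columns participant, trial, decision
        ('yes'/'no'), truth ('identical'/'different'), rt, nf, dom."""
        participants = sorted(votes["participant"].unique())
        trials = np.sort(votes["trial"].unique())
        wide = votes.set_index(["participant", "trial"]).sort_index()

        def mat(col):
            return np.stack(
                [wide.loc[p][col].reindex(trials).to_numpy(dtype=float) for p in participants]
            )

        dec = np.stack(
            [
                np.where(wide.loc[p]["decision"].reindex(trials).to_numpy() == "yes", 1.0, -1.0)
                for p in participants
            ]
        )
        first = wide.reset_index().drop_duplicates("trial").set_index("trial").loc[trials]
        truth = np.where(first["truth"].to_numpy() == "identical", 1.0, -1.0)
        dom = first["dom"].to_numpy(dtype=int)
        rt, nf = mat("rt"), mat("nf")
        w_rt = rt_weight(rt, params)
        w_nf = nf_weight(nf, params)
        weights = {
            "majority": np.ones_like(rt),
            "RT": w_rt,
            "nf": w_nf,
            "RTnf": combine_rtnf(w_rt, w_nf, params.alpha),
        }
        return cls(list(participants), dec, truth, rt, nf, weights, dom)

    def individual_error_pct(self) -> np.ndarray:
        """Per-participant error rate (%) of the raw decisions."""
        return 100.0 * (self.decisions != self.truth[None, :]).mean(axis=1)


@dataclass(frozen=True)
class GroupSizeSummary:
    method: str
    size: int
    mean_error_pct: float
    mean_group_rt: float
    n_groups: int
    n_voters: int | None = None


def _credit(scores: np.ndarray, truth: np.ndarray) -> np.ndarray:
    """Expected correctness credit per (group, trial): 1 right, 0.5 tie, 0 wrong."""
    return np.where(scores * truth[None, :] > 0, 1.0, np.where(scores == 0, 0.5, 0.0))


def _group_index(m: int, n: int) -> np.ndarray:
    if not 1 <= n <= m:
        raise ValueError(f"group size {n} outside 1..{m}")
    return np.array(list(itertools.combinations(range(m), n)), dtype=int)


def group_errors(vm: VoteMatrices, n: int, method: str):
    """Per-group error (%) and mean group RT for every group of size n."""
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    idx = _group_index(vm.m, n)
    signed = vm.decisions * vm.weights[method]
    scores = signed[idx].sum(axis=1)  # (g, T)
    credit = _credit(scores, vm.truth)
    err = 100.0 * (1.0 - credit.mean(axis=1))
    grp_rt = vm.rt[idx].max(axis=1).mean(axis=1)
    return idx, err, grp_rt


def evaluate_all_groups(vm: VoteMatrices, n: int, method: str) -> GroupSizeSummary:
    """Average error credit and group RT over all C(m, n) groups of size n."""
    idx, err, grp_rt = group_errors(vm, n, method)
    assert len(idx) == comb(vm.m, n)
    return GroupSizeSummary(method, n, float(err.mean()), float(grp_rt.mean()), len(idx))


def fastest_group_errors(vm: VoteMatrices, n: int, v: int, method: str):
    """Per-group error (%) and group RT when only the v fastest members vote.

    RT ties are broken by ascending participant index (stable sort over
    members listed in index order).  The group RT on a trial is the v-th
    smallest member RT.
    """
    if not 1 <= v <= n:
        raise ValueError(f"n_voters {v} outside 1..{n}")
    if method not in METHODS:
        raise ValueError(f"method must be one of {METHODS}")
    idx = _group_index(vm.m, n)
    signed = vm.decisions * vm.weights[method]
    errs = np.empty(len(idx))
    rts = np.empty(len(idx))
    for g, members in enumerate(idx):
        r = vm.rt[members]  # (n, T)
        order = np.argsort(r, axis=0, kind="stable")[:v]
        sel = np.take_along_axis(signed[members], order, axis=0)
        scores = sel.sum(axis=0)
        credit = _credit(scores[None, :], vm.truth)[0]
        errs[g] = 100.0 * (1.0 - credit.mean())
        rts[g] = np.take_along_axis(r, order[v - 1 : v], axis=0).mean()
    return idx, errs, rts


def fastest_subgroup_evaluate(vm: VoteMatrices, n: int, v: int, method: str) -> GroupSizeSummary:
    idx, errs, rts = fastest_group_errors(vm, n, v, method)
    return GroupSizeSummary(method, n, float(errs.mean()), float(rts.mean()), len(idx), n_voters=v)


def best_member_gap(vm: VoteMatrices, n: int, method: str = "RTnf") -> float:
    """Median over groups of (best member error % - group error %).

    Positive values mean fused group decisions beat each group's best
    individual performer, i.e. fusion is integrating confidence rather than
    merely tracking top performers.
    """
    indiv = vm.individual_error_pct()
    idx, err, _ = group_errors(vm, n, method)
    best = indiv[idx].min(axis=1)
    return float(np.median(best - err))


def method_size_table(vm: VoteMatrices, sizes=None, methods=METHODS) -> pd.DataFrame:
    """Mean group error (%) per size x method (the headline comparison table)."""
    sizes = range(1, vm.m + 1) if sizes is None else sizes
    rows = []
    for n in sizes:
        row = {"group_size": n}
        for method in methods:
            s = evaluate_all_groups(vm, n, method)
            row[method] = s.mean_error_pct
            row[f"{method}_rt"] = s.mean_group_rt
        rows.append(row)
    return pd.DataFrame(rows)


def fastest_responder_table(vm: VoteMatrices, methods=("majority", "RTnf"), sizes=None) -> pd.DataFrame:
    """Error/RT trade-off for every (group size, number of fastest voters)."""
    sizes = range(1, vm.m + 1) if sizes is None else sizes
    rows = []
    for n in sizes:
        for v in range(1, n + 1):
            for method in methods:
                s = fastest_subgroup_evaluate(vm, n, v, method)
                rows.append(
                    {
                        "group_size": n,
                        "n_voters": v,
                        "method": method,
                        "mean_error_pct": s.mean_error_pct,
                        "mean_group_rt": s.mean_group_rt,
                    }
                )
    return pd.DataFrame(rows)


def best_member_gap_table(vm: VoteMatrices, method: str = "RTnf", sizes=None) -> pd.DataFrame:
    sizes = range(1, vm.m + 1) if sizes is None else sizes
    return pd.DataFrame(
        {
            "group_size": list(sizes),
            "median_gap_pct": [best_member_gap(vm, n, method) for n in sizes],
        }
    )
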