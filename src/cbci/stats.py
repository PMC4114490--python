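"""Nonparametric evaluation statistics and ERP contrasts.

Weight distributions are heavily non-Gaussian, so group/method comparisons
use rank-based tests: the Kruskal-Wallis one-way analysis of variance for
independent samples and an *exact* Wilcoxon signed-rank test for paired
samples.  The Wilcoxon here enumerates the conditional null over all 2^n
sign assignments (via a shift-convolution over the tied-averaged ranks, with
zero differences dropped), matching the convention of exact implementations
that remain valid in the presence of ties -- scipy's exact mode refuses
ties, which the per-group error counts produce in abundance.

ERP contrasts are grand averages (means of per-participant means, never a
pooled epoch mean) of correct vs incorrect trials, with a per-(channel,
time-sample) p-value series from both a pooled Kruskal-Wallis test over all
epochs and a paired exact Wilcoxon over the per-participant means.  No
multiplicity correction is applied by default; a Bonferroni option exists.
"""

from __future__ import annotations

import itertools
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class TestResult:
    statistic: float
    p_value: float
    n_per_group: tuple
    tails: str  # "one" | "two"


# ---------------------------------------------------------------------------
# Kruskal-Wallis


def _kw_statistic(groups: list[np.ndarray]) -> float:
    """Tie-corrected H statistic computed from first principles."""
    pooled = np.concatenate(groups)
    n = len(pooled)
    ranks = sps.rankdata(pooled)
    offset = 0
    h = 0.0
    for g in groups:
        r = ranks[offset : offset + len(g)]
        offset += len(g)
        h += len(g) * (r.mean() - (n + 1) / 2.0) ** 2
    h *= 12.0 / (n * (n + 1))
    _, counts = np.unique(pooled, return_counts=True)
    tie = 1.0 - np.sum(counts**3 - counts) / float(n**3 - n)
    return h / tie if tie > 0 else 0.0


def kruskal_wallis(*groups, method: str = "chi2") -> TestResult:
    """Rank-based one-way ANOVA over two or more independent samples.

    ``method="chi2"`` (default) returns the usual chi-square p-value;
    ``method="exact"`` enumerates every distinct assignment of the pooled
    observations to the group sizes (feasible only for tiny samples) and
    returns the permutation p-value P(H >= H_obs).
    """
    if len(groups) < 2:
        raise ValueError("need at least two samples")
    groups = [np.asarray(g, dtype=float) for g in groups]
    if any(len(g) == 0 for g in groups):
        raise ValueError("each sample must be nonempty")
    sizes = tuple(len(g) for g in groups)
    pooled = np.concatenate(groups)
    if np.ptp(pooled) == 0:  # degenerate: every observation identical
        return TestResult(0.0, 1.0, sizes, "two")
    if method == "chi2":
        h, p = sps.kruskal(*groups)
        return TestResult(float(h), float(p), sizes, "two")
    if method != "exact":
        raise ValueError("method must be 'chi2' or 'exact'")
    h_obs = _kw_statistic(groups)
    labels = np.repeat(np.arange(len(groups)), sizes)
    count = hits = 0
    for perm in set(itertools.permutations(labels)):
        perm = np.asarray(perm)
        h = _kw_statistic([pooled[perm == i] for i in range(len(groups))])
        count += 1
        hits += h >= h_obs - 1e-12
    return TestResult(float(h_obs), hits / count, sizes, "two")


# ---------------------------------------------------------------------------
# Exact Wilcoxon signed-rank


def _signed_rank_distribution(scaled_ranks: np.ndarray) -> np.ndarray:
    """Counts of each value of 2*W+ over all 2^n sign assignments."""
    total = int(scaled_ranks.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in scaled_ranks:
        new = dist.copy()
        new[r:] += dist[: total + 1 - r]
        dist = new
    return dist


def wilcoxon_signed_rank(
    paired_diffs, tails: str = "two", alternative: str = "greater"
) -> TestResult:
    """Exact Wilcoxon signed-rank test on paired differences.

    Convention: zero differences are dropped, tied absolute values get
    averaged ranks, and the null distribution of W+ (the rank sum of the
    positive differences) is enumerated exactly over all sign assignments.
    ``tails="one"`` tests ``alternative`` ("greater": positive shift, i.e.
    large W+; "less": negative shift); ``tails="two"`` doubles the smaller
    tail, capped at 1.
    """
    d = np.asarray(paired_diffs, dtype=float)
    d = d[d != 0]
    if len(d) == 0:
        raise ValueError("all paired differences are zero; the test is undefined")
    ranks = sps.rankdata(np.abs(d))
    scaled = np.rint(2 * ranks).astype(int)  # halves become exact integers
    w_plus = float(ranks[d > 0].sum())
    w_scaled = int(round(2 * w_plus))
    dist = _signed_rank_distribution(scaled)
    denom = 2.0 ** len(d)
    p_ge = dist[w_scaled:].sum() / denom
    p_le = dist[: w_scaled + 1].sum() / denom
    if tails == "one":
        if alternative == "greater":
            p = p_ge
        elif alternative == "less":
            p = p_le
        else:
            raise ValueError("alternative must be 'greater' or 'less'")
    elif tails == "two":
        p = min(1.0, 2.0 * min(p_ge, p_le))
    else:
        raise ValueError("tails must be 'one' or 'two'")
    return TestResult(w_plus, float(p), (len(d),), tails)


# ---------------------------------------------------------------------------
# ERP contrasts


@dataclass
class ERPContrast:
    """Grand averages and pointwise p-value series for one channel."""

    channel: str
    locking: str
    time_ms: np.ndarray  # (24,)
    grand_avg_correct: np.ndarray
    grand_avg_incorrect: np.ndarray
    p_series_pooled: np.ndarray
    p_series_paired: np.ndarray


def grand_average(epochs: np.ndarray, participants, mask) -> np.ndarray:
    """Mean across participants of per-participant mean epochs.

    ``mask`` selects the epochs of one condition.  Participants with no
    epoch in the condition are excluded (and logged), so each participant
    contributes equally regardless of epoch count.
    """
    epochs = np.asarray(epochs, dtype=float)
    participants = np.asarray(participants)
    mask = np.asarray(mask, dtype=bool)
    means = []
    for p in pd.unique(participants):
        sel = (participants == p) & mask
        if not sel.any():
            logger.warning("participant %s has no epochs in condition; excluded", p)
            continue
        means.append(epochs[sel].mean(axis=0))
    if not means:
        raise ValueError("no participant contributes to this condition")
    return np.mean(means, axis=0)


def pointwise_erp_tests(
    epochs: np.ndarray, correct, participants, bonferroni: bool = False
) -> tuple[np.ndarray, np.ndarray]:
    """Per-(channel, time) p-values for the correct vs incorrect contrast.

    Returns ``(p_pooled, p_paired)``, each (n_channels, n_times): a pooled
    Kruskal-Wallis over all epochs and a two-tailed exact Wilcoxon over the
    per-participant condition means.  Degenerate cells record p = 1.
    """
    epochs = np.asarray(epochs, dtype=float)
    correct = np.asarray(correct, dtype=bool)
    participants = np.asarray(participants)
    _, n_ch, n_t = epochs.shape
    uniq = [p for p in pd.unique(participants)]
    means_c, means_i = [], []
    for p in uniq:
        for cond, store in ((correct, means_c), (~correct, means_i)):
            sel = (participants == p) & cond
            store.append(epochs[sel].mean(axis=0) if sel.any() else None)
    paired_ok = [i for i in range(len(uniq)) if means_c[i] is not None and means_i[i] is not None]
    if len(paired_ok) < len(uniq):
        logger.warning("%d participant(s) lack one condition; excluded from the paired test",
                       len(uniq) - len(paired_ok))
    p_pooled = np.ones((n_ch, n_t))
    p_paired = np.ones((n_ch, n_t))
    a = epochs[correct]
    b = epochs[~correct]
    for c in range(n_ch):
        for t in range(n_t):
            if np.ptp(epochs[:, c, t]) > 0:
                p_pooled[c, t] = kruskal_wallis(a[:, c, t], b[:, c, t]).p_value
            diffs = np.array([means_c[i][c, t] - means_i[i][c, t] for i in paired_ok])
            if np.any(diffs != 0):
                p_paired[c, t] = wilcoxon_signed_rank(diffs, tails="two").p_value
    if bonferroni:
        cells = n_ch * n_t
        p_pooled = np.minimum(1.0, p_pooled * cells)
        p_paired = np.minimum(1.0, p_paired * cells)
    return p_pooled, p_paired


def erp_contrast_table(
    epochs: np.ndarray,
    correct,
    participants,
    channel_names,
    locking: str = "response",
    bonferroni: bool = False,
) -> pd.DataFrame:
    """Long-format contrast: channel, time_ms, condition means, p-values."""
    epochs = np.asarray(epochs, dtype=float)
    correct = np.asarray(correct, dtype=bool)
    ga_c = grand_average(epochs, participants, correct)
    ga_i = grand_average(epochs, participants, ~correct)
    p_pooled, p_paired = pointwise_erp_tests(epochs, correct, participants, bonferroni)
    n_t = epochs.shape[2]
    if locking == "response":
        time_ms = -1000.0 + 62.5 * np.arange(n_t)
    else:
        time_ms = 62.5 * np.arange(n_t)
    rows = []
    for c, name in enumerate(channel_names):
        for t in range(n_t):
            rows.append(
                {
                    "channel": name,
                    "locking": locking,
                    "time_ms": time_ms[t],
                    "mean_correct": ga_c[c, t],
                    "mean_incorrect": ga_i[c, t],
                    "p_pooled": p_pooled[c, t],
                    "p_paired": p_paired[c, t],
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Weight summaries


def weight_summaries(votes: pd.DataFrame) -> dict:
    """Median decision weights by correctness and by degree of match.

    ``votes`` is the tidy per-(participant, trial) table with boolean
    ``correct``, integer ``dom`` and weight columns ``w_RT``, ``w_nf``,
    ``w_RTnf``.  Medians pool all participants' trials.  Empty cells are
    reported as NaN.
    """
    weight_cols = {"RT": "w_RT", "nf": "w_nf", "RTnf": "w_RTnf"}
    by_corr = pd.DataFrame(
        {
            name: votes.groupby(votes["correct"].map({True: "correct", False: "incorrect"}))[
                col
            ].median()
            for name, col in weight_cols.items()
        }
    ).reindex(["correct", "incorrect"])
    by_dom = pd.DataFrame(
        {name: votes.groupby("dom")[col].median() for name, col in weight_cols.items()}
    ).reindex(range(7))
    by_dom.index.name = "dom"
    return {"by_correctness": by_corr, "by_dom": by_dom}


def weight_density(values, grid=None):
    """Gaussian kernel density (Silverman bandwidth) of a weight sample."""
    values = np.asarray(values, dtype=float)
    kde = sps.gaussian_kde(values, bw_method="silverman")
    if grid is None:
        bw = kde.factor * values.std(ddof=1)
        grid = np.linspace(values.min() - 4 * bw, values.max() + 4 * bw, 512)
    return grid, kde(grid)
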