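"""End-to-end analysis: epochs -> nf -> weights -> group decision tables.

Glue shared by the CLI, the tests and the reproduction script.  Times are
seconds internally; report tables use the units of the headline results
(error percentages, seconds for group RTs).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .confidence import crossvalidated_nf
from .fusion import (
    VoteMatrices,
    WeightParams,
    best_member_gap_table,
    combine_rtnf,
    fastest_responder_table,
    method_size_table,
    nf_weight,
    rt_weight,
)
from .simulate import Population
from .stats import erp_contrast_table, weight_summaries


@dataclass(frozen=True)
class AnalysisConfig:
    k_folds: int = 16
    n_components: int = 24
    lars_max_steps: int = 24
    weights: WeightParams = field(default_factory=WeightParams)
    fastest_methods: tuple = ("majority", "RTnf")
    erp_channels: tuple | None = None  # None = all 64


def compute_confidence_table(population: Population, config: AnalysisConfig = AnalysisConfig()) -> pd.DataFrame:
    """Tidy per-(participant, trial) table with out-of-fold nf and weights."""
    frames = []
    for session in population.sessions:
        if session.epochs is None:
            raise ValueError(f"session {session.participant_id} has no epochs")
        nf, fold = crossvalidated_nf(
            session.epochs,
            session.labels,
            k=config.k_folds,
            n_components=config.n_components,
            max_steps=config.lars_max_steps,
        )
        tbl = session.behaviour.copy()
        tbl.insert(0, "participant", session.participant_id)
        tbl["nf"] = nf
        tbl["fold"] = fold
        frames.append(tbl)
    votes = pd.concat(frames, ignore_index=True)
    p = config.weights
    votes["w_RT"] = rt_weight(votes["rt"].to_numpy(), p)
    votes["w_nf"] = nf_weight(votes["nf"].to_numpy(), p)
    votes["w_RTnf"] = combine_rtnf(votes["w_RT"], votes["w_nf"], p.alpha)
    return votes


@dataclass
class AnalysisResults:
    votes: pd.DataFrame
    vote_matrices: VoteMatrices
    method_size: pd.DataFrame  # mean error % per group size x method
    fastest: pd.DataFrame  # error/RT per (size, n_voters, method)
    best_member_gap: pd.DataFrame
    weight_medians: dict  # by_correctness / by_dom
    erp_contrast: pd.DataFrame | None = None


def analyse_population(
    population: Population,
    config: AnalysisConfig = AnalysisConfig(),
    votes: pd.DataFrame | None = None,
    with_erp: bool = True,
) -> AnalysisResults:
    """Run the full offline analysis on a (simulated or ingested) population."""
    if votes is None:
        votes = compute_confidence_table(population, config)
    vm = VoteMatrices.from_table(votes, config.weights)
    erp = None
    if with_erp:
        from .montage import BIOSEMI64

        epochs = np.concatenate([s.epochs for s in population.sessions])
        correct = np.concatenate([s.behaviour["correct"].to_numpy() for s in population.sessions])
        participants = np.concatenate(
            [np.repeat(s.participant_id, len(s.behaviour)) for s in population.sessions]
        )
        names = list(BIOSEMI64)
        if config.erp_channels is not None:
            keep = [names.index(c) for c in config.erp_channels]
            epochs = epochs[:, keep, :]
            names = [names[i] for i in keep]
        erp = erp_contrast_table(epochs, correct, participants, names, locking="response")
    return AnalysisResults(
        votes=votes,
        vote_matrices=vm,
        method_size=method_size_table(vm),
        fastest=fastest_responder_table(vm, methods=config.fastest_methods),
        best_member_gap=best_member_gap_table(vm),
        weight_medians=weight_summaries(votes),
        erp_contrast=erp,
    )
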