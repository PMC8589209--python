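"""Synthetic respondent cohorts for the bundled adjusting-delay study.

Emulates the study design end to end: participants with heterogeneous
hyperbolic discount rates (log10 k ~ Normal), 1:1 random assignment to
ascending or descending bundle-size order, the three within-subject
bundle-size conditions {1, 3, 9}, and the appended quality-control
trials (a color catch item plus one no-delay choice trial per
condition).

The response model is the generator's own assumption — the study
design does not prescribe one.  Choices are softmax on the additive
hyperbolic value difference with a lapse mixture: with probability
``lapse_rate`` the agent picks uniformly at random; otherwise

    P(LLR) = logistic(beta * (V_LLR - V_SSR) / scale)

where ``beta`` is the inverse temperature and ``scale`` expresses the
value difference per $100 of the smaller-sooner total (so beta is
comparable across option magnitudes).  ``beta = inf`` is the
deterministic value maximizer (ties go to the larger-later option).

Inattentive agents (a Bernoulli fraction of the cohort) answer the
choice quality-control trials uniformly at random, so each fails at
least one of the three with probability 7/8.  The default inattentive
fraction, 0.136, makes the expected share of participants failing
quality control about 30 of 252 — the exclusion rate the task's
deployed versions typically see.  The color item is carried in the
schema but never failed, matching its observed zero failure rate.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .task import DelayGrid, TaskRecord, default_delay_grid, qc_choice_trial, run_adjusting_task
from .valuation import (
    DEFAULT_LLR_TOTAL,
    DEFAULT_SSR_TOTAL,
    BundleOption,
    DiscountParams,
    Role,
    bundle_value,
)

__all__ = [
    "AgentParams",
    "CohortConfig",
    "CohortDataset",
    "sample_agent",
    "agent_choose",
    "make_chooser",
    "simulate_cohort",
    "TRIAL_COLUMNS",
]

ORDER_ASCENDING = "ascending"
ORDER_DESCENDING = "descending"

#: Schema of the long-format trial table (one row per trial, QC rows included).
TRIAL_COLUMNS = [
    "participant_id",
    "order_group",
    "bundle_size",
    "trial",
    "presented_delay_days",
    "choice",
    "is_final",
    "final_index",
    "indifference_days",
    "is_qc",
    "qc_pass",
]


@dataclass(frozen=True)
class AgentParams:
    """Latent parameters of one simulated respondent."""

    k: float  # hyperbolic discount rate, 1/day
    inverse_temperature: float = math.inf  # softmax sharpness; inf = deterministic
    lapse_rate: float = 0.0  # probability of a uniformly random choice
    qc_inattentive: bool = False  # answers choice-QC trials at random

    def __post_init__(self) -> None:
        if not self.k > 0:
            raise ValueError(f"agent k must be > 0, got {self.k}")
        if self.inverse_temperature < 0:
            raise ValueError("inverse_temperature must be >= 0")
        if not 0.0 <= self.lapse_rate <= 1.0:
            raise ValueError("lapse_rate must be in [0, 1]")


@dataclass(frozen=True)
class CohortConfig:
    """Generator configuration; a cohort is reproducible from this alone."""

    n_participants: int = 252
    mu_log10k: float = -2.2
    sigma_log10k: float = 0.9
    inverse_temperature: float = 4.0
    lapse_rate: float = 0.02
    inattentive_fraction: float = 0.136
    order_effect_multiplier: float = 1.0  # multiplies k in the descending group
    bundle_sizes: tuple[int, ...] = (1, 3, 9)
    total_llr: int = DEFAULT_LLR_TOTAL
    total_ssr: int = DEFAULT_SSR_TOTAL
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_participants < 2 or self.n_participants % 2:
            raise ValueError(
                f"n_participants must be even and >= 2 (1:1 order assignment), "
                f"got {self.n_participants}"
            )
        if self.sigma_log10k < 0:
            raise ValueError("sigma_log10k must be >= 0")
        if not 0.0 <= self.inattentive_fraction <= 1.0:
            raise ValueError("inattentive_fraction must be in [0, 1]")
        if self.order_effect_multiplier <= 0:
            raise ValueError("order_effect_multiplier must be > 0")


@dataclass
class CohortDataset:
    """A simulated cohort: long trial table plus per-participant truth."""

    trials: pd.DataFrame  # TRIAL_COLUMNS schema
    participants: pd.DataFrame  # id, order_group, true_k, inattentive, qc columns
    config: CohortConfig
    grid: DelayGrid


def sample_agent(config: CohortConfig, rng: np.random.Generator) -> AgentParams:
    """Draw one agent: k = 10**x with x ~ Normal(mu, sigma); inattention ~ Bernoulli."""
    x = rng.normal(config.mu_log10k, config.sigma_log10k)
    inattentive = bool(rng.random() < config.inattentive_fraction)
    return AgentParams(
        k=10.0**x,
        inverse_temperature=config.inverse_temperature,
        lapse_rate=config.lapse_rate,
        qc_inattentive=inattentive,
    )


def _value_gap(agent: AgentParams, llr: BundleOption, ssr: BundleOption) -> float:
    params = DiscountParams(k=agent.k)
    scale = ssr.total.dollars / 100.0  # per $100 of the smaller-sooner total
    return (bundle_value(llr, params) - bundle_value(ssr, params)) / scale


def agent_choose(
    agent: AgentParams,
    llr: BundleOption,
    ssr: BundleOption,
    rng: np.random.Generator | None = None,
) -> Role:
    """One choice under the softmax-plus-lapse response model.

    Deterministic agents (``inverse_temperature = inf``, zero lapse)
    need no RNG and pick the larger additive value, tie going to the
    larger-later option.
    """
    gap = _value_gap(agent, llr, ssr)
    deterministic = math.isinf(agent.inverse_temperature) and agent.lapse_rate == 0.0
    if deterministic:
        return Role.LLR if gap >= 0 else Role.SSR
    if rng is None:
        raise ValueError("stochastic agents require an rng")
    if rng.random() < agent.lapse_rate:
        return Role.LLR if rng.random() < 0.5 else Role.SSR
    if math.isinf(agent.inverse_temperature):
        p_llr = 1.0 if gap >= 0 else 0.0
    else:
        with np.errstate(over="ignore"):
            p_llr = 1.0 / (1.0 + math.exp(-min(max(agent.inverse_temperature * gap, -700), 700)))
    return Role.LLR if rng.random() < p_llr else Role.SSR


def make_chooser(agent: AgentParams, rng: np.random.Generator | None = None):
    """Bind an agent (and its RNG stream) into a task-engine chooser."""
    return lambda llr, ssr: agent_choose(agent, llr, ssr, rng)


def _participant_rng(seed: int, participant_id: int) -> np.random.Generator:
    # one independent stream per participant: cohort-size changes never
    # reshuffle earlier participants
    return np.random.default_rng(np.random.SeedSequence(seed, spawn_key=(participant_id,)))


def simulate_cohort(config: CohortConfig, grid: DelayGrid | None = None) -> CohortDataset:
    """Simulate a full cohort through the task battery.

    Participants are assigned 1:1 to ascending/descending bundle-size
    order by a seeded permutation, complete the five-trial task at each
    configured bundle size in their assigned order, and answer one
    quality-control choice trial per condition plus the color item.
    Identical config (including seed) yields an identical dataset.
    """
    if grid is None:
        grid = default_delay_grid()
    n = config.n_participants
    assign_rng = np.random.default_rng(np.random.SeedSequence(config.seed, spawn_key=(0xA551,)))
    order = np.array([ORDER_ASCENDING] * (n // 2) + [ORDER_DESCENDING] * (n // 2))
    assign_rng.shuffle(order)

    trial_rows: list[dict] = []
    participant_rows: list[dict] = []
    for pid in range(n):
        rng = _participant_rng(config.seed, pid)
        agent = sample_agent(config, rng)
        group = order[pid]
        effective_k = agent.k
        if group == ORDER_DESCENDING:
            effective_k = agent.k * config.order_effect_multiplier
        task_agent = replace(agent, k=effective_k)

        sizes = list(config.bundle_sizes)
        if group == ORDER_DESCENDING:
            sizes = sizes[::-1]

        qc_passes: dict[int, bool] = {}
        for bs in sizes:
            chooser = make_chooser(task_agent, rng)
            record = run_adjusting_task(
                chooser, grid=grid, bundle_size=bs,
                total_llr=config.total_llr, total_ssr=config.total_ssr,
            )
            if agent.qc_inattentive:
                qc = bool(rng.random() < 0.5)  # random answer on the QC trial
            else:
                # attentive agents can't miss the dominant option: answer
                # the (trivial) QC trial by pure value maximization
                strict = replace(task_agent, inverse_temperature=math.inf, lapse_rate=0.0)
                qc = qc_choice_trial(
                    bs, make_chooser(strict), config.total_llr, config.total_ssr
                )
            qc_passes[bs] = qc
            for t, (d1, choice) in enumerate(record.trials, start=1):
                final = t == 5
                trial_rows.append(dict(
                    participant_id=pid, order_group=group, bundle_size=bs,
                    trial=t, presented_delay_days=d1, choice=choice.value,
                    is_final=final,
                    final_index=record.final_index if final else pd.NA,
                    indifference_days=record.indifference_days if final else np.nan,
                    is_qc=False, qc_pass=pd.NA,
                ))
            trial_rows.append(dict(
                participant_id=pid, order_group=group, bundle_size=bs,
                trial=6, presented_delay_days=0.0,
                choice=Role.LLR.value if qc else Role.SSR.value,
                is_final=False, final_index=pd.NA, indifference_days=np.nan,
                is_qc=True, qc_pass=qc,
            ))

        row = dict(
            participant_id=pid, order_group=group, true_k=agent.k,
            effective_k=effective_k, inattentive=agent.qc_inattentive,
            qc_color_pass=True,
        )
        for bs in config.bundle_sizes:
            row[f"qc_pass_bs{bs}"] = qc_passes[bs]
        row["qc_pass_all"] = all(qc_passes.values())
        participant_rows.append(row)

    trials = pd.DataFrame(trial_rows, columns=TRIAL_COLUMNS)
    participants = pd.DataFrame(participant_rows)
    return CohortDataset(trials=trials, participants=participants, config=config, grid=grid)
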