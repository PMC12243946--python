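"""Shared fixtures: small simulated datasets and directly constructed
pattern stores (so decoding/statistics tests need not pay for a full
simulate + GLM pass)."""

import numpy as np
import pytest

from vwmdecode import glm
from vwmdecode.design import build_run_schedule, enumerate_conditions, round_onsets_to_tr
from vwmdecode.glm import BetaPatternSet, PeriodPatternSet, build_split_plan
from vwmdecode.simulate import HemodynamicModel, make_ground_truth, simulate_run

CONDITIONS = tuple(enumerate_conditions())


def make_period_patterns(
    condition_means: dict,
    noise_sd: float = 0.1,
    n_vertices: int = 60,
    n_splits: int = 4,
    per_split: int = 7,
    period: str = "delay",
    seed: int = 0,
) -> PeriodPatternSet:
    """Build a period-pattern store directly: every (split, combination)
    pattern for condition c is ``condition_means[c] + noise``.  Conditions
    without an entry get pure noise."""
    rng = np.random.default_rng(seed)
    patterns = {}
    for s in range(n_splits):
        for c in range(per_split):
            block = np.zeros((len(CONDITIONS), n_vertices))
            for ci, cond in enumerate(CONDITIONS):
                mean = condition_means.get(cond, 0.0)
                block[ci] = mean + rng.standard_normal(n_vertices) * noise_sd
            patterns[(s, c)] = block
    return PeriodPatternSet(patterns=patterns, conditions=CONDITIONS, period=period)


def null_beta_patterns(n_vertices=60, n_splits=4, per_split=7, seed=0) -> BetaPatternSet:
    """Pure-noise beta store (all conditions, all 30 lags): the zero-signal
    world in which decoding must sit at chance."""
    rng = np.random.default_rng(seed)
    plan = build_split_plan([13, 14])
    betas = {
        (si, ci): rng.standard_normal((len(CONDITIONS), glm.N_LAGS, n_vertices))
        for si, ci, _ in plan.iter_combinations()
    }
    return BetaPatternSet(betas=betas, conditions=CONDITIONS, plan=plan)


def simulate_small_participant(
    theta=0.0,
    noise_sd=0.0,
    n_vertices=24,
    runs_per_session=(13, 14),
    hemo_kind="fir_identity",
    seed=0,
    **gains,
):
    """Simulate all runs of one participant at reduced size; returns
    (series, schedules, truth, split_plan)."""
    rng = np.random.default_rng(seed)
    truth = make_ground_truth(
        n_vertices=n_vertices, theta=theta, noise_sd=noise_sd, seed=rng, **gains
    )
    hemo = HemodynamicModel(kind=hemo_kind)
    series, schedules = [], []
    for s_idx, n in enumerate(runs_per_session, start=1):
        for r in range(1, n + 1):
            sched = round_onsets_to_tr(build_run_schedule(seed=rng))
            schedules.append(sched)
            series.append(
                simulate_run(
                    sched, truth, hemo, seed=rng,
                    session_id=f"ses-{s_idx}", run_id=f"run-{r:02d}",
                )
            )
    return series, schedules, truth, build_split_plan(list(runs_per_session))


def expected_lag_profile(truth, condition):
    """Independent forward-model oracle: the noiseless per-lag amplitude
    pattern a trial of ``condition`` contributes under the identity kernel.

    Built from the trial's stage timing directly (not from the simulator's
    event loop): target image on lag 1; memory boxcar lags 1..15; one
    distractor image every 0.5 s from 2.5 s, each at its nearest TR lag.
    """
    from vwmdecode.simulate import _lag_of

    exp = np.zeros((glm.N_LAGS, truth.n_vertices))
    exp[1] += truth.gain_encoding * truth.perceptual[condition.target]
    for lag in range(1, 16):
        exp[lag] += truth.gain_delay * truth.memory[condition.target]
    if condition.has_distractor:
        for k in range(20):
            lag = _lag_of(25 + 5 * k)
            exp[lag] += truth.gain_distractor * truth.perceptual[condition.distractor]
    return exp


@pytest.fixture(scope="session")
def noiseless_fit():
    """One noiseless identity-kernel participant, fitted: the linear-model
    identity setting where betas must equal the simulated truth."""
    series, schedules, truth, plan = simulate_small_participant(
        theta=np.pi / 4, noise_sd=0.0, n_vertices=16, seed=101
    )
    patterns = glm.estimate_patterns(series, schedules, plan)
    return series, schedules, truth, plan, patterns
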