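"""FIR beta-series estimation with the odd/even run-combination split plan.

Because each condition appears only once per run and intertrial intervals are
short relative to the hemodynamic lag, single-run FIR estimates are unusable.
Runs are therefore split into odd and even halves within each of the two scan
sessions (4 splits), and a joint GLM is fitted to each leave-one-run-out
combination within a half: a 7-run half yields its seven 6-run combinations,
a 6-run half its six 5-run combinations plus the full 6-run set — seven
estimates per split, 28 beta patterns per (condition, lag) in total.  Splits
share no runs, so patterns from different splits are independent; the seven
patterns within a split are not.

The FIR model carries 480 stimulus regressors (16 conditions x 30 lags of
0.8 s, covering 24 s from trial onset) plus per-run polynomial nuisance
regressors.  Fitting is ordinary least squares via per-run cross-products,
so the 28 combinations reuse each run's work.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.sparse

from .design import TrialCondition, enumerate_conditions
from .simulate import VertexTimeSeries

N_LAGS = 30  # 30 TRs x 0.8 s = 24 s from trial onset
N_NUISANCE_PER_RUN = 3  # Legendre 0..2: intercept, linear, quadratic

#: closed period windows in deciseconds after trial onset (lag l covers l*8 ds)
PERIOD_WINDOWS_DS = {"encoding": (40, 64), "delay": (96, 120)}

RunKey = tuple[int, int]  # (session index, run index), 1-based


def period_lags(period: str) -> list[int]:
    """TR lags whose time l*0.8 s falls in the period's closed window."""
    lo, hi = PERIOD_WINDOWS_DS[period]
    return [l for l in range(N_LAGS) if lo <= l * 8 <= hi]


# ---------------------------------------------------------------------------
# detrending


def detrend(ts: VertexTimeSeries) -> VertexTimeSeries:
    """Remove the per-vertex best-fit linear + quadratic trend (and mean)."""
    if ts.n_trs < 4:
        raise ValueError("detrending requires at least 4 TRs")
    basis = _poly_basis(ts.n_trs)  # (T, 3), orthonormal
    resid = ts.data - (ts.data @ basis) @ basis.T
    return VertexTimeSeries(
        data=resid,
        tr_seconds=ts.tr_seconds,
        run_id=ts.run_id,
        session_id=ts.session_id,
        participant_id=ts.participant_id,
    )


def _poly_basis(n_trs: int) -> np.ndarray:
    """Orthonormal Legendre-like polynomial basis of order 0..2, (T, 3)."""
    t = np.linspace(-1.0, 1.0, n_trs)
    raw = np.column_stack([np.ones(n_trs), t, t**2])
    q, _ = np.linalg.qr(raw)
    return q


# ---------------------------------------------------------------------------
# split plan


@dataclass(frozen=True)
class Split:
    session: int
    parity: str  # "odd" | "even"
    runs: tuple[RunKey, ...]
    combinations: tuple[tuple[RunKey, ...], ...]


@dataclass(frozen=True)
class SplitPlan:
    splits: tuple[Split, ...]

    @property
    def n_combinations(self) -> int:
        return sum(len(s.combinations) for s in self.splits)

    def iter_combinations(self):
        for si, split in enumerate(self.splits):
            for ci, combo in enumerate(split.combinations):
                yield si, ci, combo


def _half_combinations(runs: tuple[RunKey, ...]) -> tuple[tuple[RunKey, ...], ...]:
    k = len(runs)
    combos = list(itertools.combinations(runs, k - 1))
    if k <= 6:
        combos.append(tuple(runs))
    return tuple(combos)


def build_split_plan(runs_per_session: list[int] | tuple[int, int]) -> SplitPlan:
    """Odd/even halves per session, with leave-one-run-out combinations.

    Run indices are 1-based; the odd half takes the extra run when a
    session's count is odd.  Sessions of 13 or 14 runs reproduce the
    canonical 28-combination plan; other counts are accepted with a warning.
    """
    if len(runs_per_session) != 2:
        raise ValueError("expected run counts for exactly two sessions")
    splits: list[Split] = []
    for session, n in enumerate(runs_per_session, start=1):
        if n not in (13, 14):
            warnings.warn(
                f"session {session} has {n} runs (canonical designs use 13 or 14); "
                "the combination rule generalizes but pattern counts will differ",
                stacklevel=2,
            )
        odd = tuple((session, r) for r in range(1, n + 1, 2))
        even = tuple((session, r) for r in range(2, n + 1, 2))
        for parity, runs in (("odd", odd), ("even", even)):
            if len(runs) < 2:
                raise ValueError(
                    f"session {session} {parity} half has {len(runs)} run(s); "
                    "at least 2 are required"
                )
            splits.append(
                Split(session, parity, runs, _half_combinations(runs))
            )
    return SplitPlan(splits=tuple(splits))


# ---------------------------------------------------------------------------
# FIR design and OLS


@dataclass(frozen=True)
class FIRDesign:
    """Sparse indicator design for one run: (condition, lag) -> column."""

    matrix: scipy.sparse.csr_matrix  # (n_trs, n_conditions * N_LAGS)
    conditions: tuple[TrialCondition, ...]

    def column(self, condition_index: int, lag: int) -> int:
        return condition_index * N_LAGS + lag


def build_fir_design(schedule, conditions: list[TrialCondition] | None = None) -> FIRDesign:
    """One FIR indicator column per (condition, lag); a trial contributes a 1
    at rows onset_tr + lag for lags 0..29 (truncated at run end)."""
    conditions = conditions or enumerate_conditions()
    cond_index = {c: i for i, c in enumerate(conditions)}
    n_trs = schedule.n_trs
    tr = schedule.tr_seconds
    rows, cols = [], []
    for onset, cond in schedule.trial_onsets():
        t0 = int(round(onset / tr))
        if abs(onset / tr - t0) > 1e-6:
            raise ValueError("schedule must be rounded to the TR grid before GLM")
        ci = cond_index[cond]
        for lag in range(N_LAGS):
            row = t0 + lag
            if row < n_trs:
                rows.append(row)
                cols.append(ci * N_LAGS + lag)
    mat = scipy.sparse.csr_matrix(
        (np.ones(len(rows)), (rows, cols)),
        shape=(n_trs, len(conditions) * N_LAGS),
    )
    return FIRDesign(matrix=mat, conditions=tuple(conditions))


class _RunCross:
    """Per-run design/data cross-products, reused across combinations."""

    def __init__(self, ts: VertexTimeSeries, schedule, conditions):
        design = build_fir_design(schedule, conditions)
        S = design.matrix
        N = _poly_basis(ts.n_trs)
        Y = ts.data.T  # (T, V)
        self.StS = (S.T @ S).toarray()
        self.StN = S.T @ N
        self.NtN = N.T @ N
        self.StY = S.T @ Y
        self.NtY = N.T @ Y
        self.n_vertices = ts.n_vertices


def _solve_combination(crosses: list[_RunCross], n_stim: int) -> np.ndarray:
    """OLS for one run combination from per-run cross-products.

    Stimulus regressors are shared across runs; each run carries its own
    polynomial nuisance block.  Returns (n_stim, V) stimulus betas.
    """
    nr = len(crosses)
    dim = n_stim + N_NUISANCE_PER_RUN * nr
    G = np.zeros((dim, dim))
    rhs = np.zeros((dim, crosses[0].n_vertices))
    for j, c in enumerate(crosses):
        G[:n_stim, :n_stim] += c.StS
        j0 = n_stim + j * N_NUISANCE_PER_RUN
        j1 = j0 + N_NUISANCE_PER_RUN
        G[:n_stim, j0:j1] = c.StN
        G[j0:j1, :n_stim] = c.StN.T
        G[j0:j1, j0:j1] = c.NtN
        rhs[:n_stim] += c.StY
        rhs[j0:j1] = c.NtY
    try:
        cho = scipy.linalg.cho_factor(G)
    except np.linalg.LinAlgError:
        _raise_rank_deficient(G, n_stim)
    sol = scipy.linalg.cho_solve(cho, rhs)
    return sol[:n_stim]


def _raise_rank_deficient(G: np.ndarray, n_stim: int):
    eigval, eigvec = np.linalg.eigh(G)
    null = eigvec[:, eigval < 1e-8 * eigval.max()]
    bad = sorted(set(np.where(np.abs(null) > 1e-3)[0].tolist()))
    stim_bad = [i for i in bad if i < n_stim]
    cond_lag = [(i // N_LAGS, i % N_LAGS) for i in stim_bad]
    raise ValueError(
        "rank-deficient FIR design: collinear (condition, lag) columns "
        f"{cond_lag[:20]}{'...' if len(cond_lag) > 20 else ''}; "
        "combine more runs (single runs cannot support the FIR model)"
    )


def fit_fir_glm(
    runs: list[VertexTimeSeries],
    schedules: list,
    conditions: list[TrialCondition] | None = None,
) -> np.ndarray:
    """Joint OLS over the given runs; returns betas (n_conditions, 30, V)."""
    if len(runs) != len(schedules):
        raise ValueError("runs and schedules must align")
    if len(runs) < 2:
        raise ValueError(
            "single-run FIR fits are unreliable by design (conditions occur once "
            "per run with short ITIs); provide a multi-run combination"
        )
    conditions = conditions or enumerate_conditions()
    crosses = [_RunCross(ts, sched, conditions) for ts, sched in zip(runs, schedules)]
    n_stim = len(conditions) * N_LAGS
    betas = _solve_combination(crosses, n_stim)  # (n_stim, V)
    return betas.reshape(len(conditions), N_LAGS, -1)


# ---------------------------------------------------------------------------
# pattern containers


@dataclass
class BetaPatternSet:
    """FIR betas per (split, combination): arrays (n_conditions, 30, V_roi)."""

    betas: dict[tuple[int, int], np.ndarray]
    conditions: tuple[TrialCondition, ...]
    plan: SplitPlan
    participant_id: str = "sub-01"
    roi: str = "roi"

    @property
    def n_patterns(self) -> int:
        """Patterns available per (condition, lag)."""
        return len(self.betas)

    def split_keys(self, split: int) -> list[tuple[int, int]]:
        return sorted(k for k in self.betas if k[0] == split)


@dataclass
class PeriodPatternSet:
    """Period-averaged patterns: (split, combination) -> (n_conditions, V)."""

    patterns: dict[tuple[int, int], np.ndarray]
    conditions: tuple[TrialCondition, ...]
    period: str
    participant_id: str = "sub-01"
    roi: str = "roi"

    def split_keys(self, split: int) -> list[tuple[int, int]]:
        return sorted(k for k in self.patterns if k[0] == split)

    @property
    def n_splits(self) -> int:
        return len({k[0] for k in self.patterns})


def estimate_patterns(
    runs: list[VertexTimeSeries],
    schedules: list,
    plan: SplitPlan,
    roi: np.ndarray | list[int] | None = None,
    conditions: list[TrialCondition] | None = None,
    detrend_first: bool = True,
) -> BetaPatternSet:
    """Run the full estimation stage: detrend, fit every combination of the
    split plan, restrict to the ROI's vertices.

    ``runs``/``schedules`` are matched lists covering both sessions; runs are
    located by their (session, run) identifiers.
    """
    conditions = conditions or enumerate_conditions()
    by_key: dict[RunKey, tuple[VertexTimeSeries, object]] = {}
    for ts, sched in zip(runs, schedules):
        key = (int(ts.session_id.split("-")[1]), int(ts.run_id.split("-")[1]))
        by_key[key] = (ts, sched)
    crosses: dict[RunKey, _RunCross] = {}
    n_stim = len(conditions) * N_LAGS
    betas: dict[tuple[int, int], np.ndarray] = {}
    roi_idx = None if roi is None else np.asarray(roi, dtype=int)
    for si, ci, combo in plan.iter_combinations():
        for key in combo:
            if key not in by_key:
                raise ValueError(f"split plan references missing run {key}")
            if key not in crosses:
                ts, sched = by_key[key]
                if detrend_first:
                    ts = detrend(ts)
                crosses[key] = _RunCross(ts, sched, conditions)
        sol = _solve_combination([crosses[k] for k in combo], n_stim)
        betas[(si, ci)] = sol.reshape(len(conditions), N_LAGS, -1)
    first = runs[0]
    return assemble_patterns(
        betas, plan, conditions=conditions, roi=roi_idx,
        participant_id=first.participant_id,
    )


def assemble_patterns(
    betas_by_combination: dict[tuple[int, int], np.ndarray],
    plan: SplitPlan,
    conditions: list[TrialCondition] | None = None,
    roi: np.ndarray | list[int] | None = None,
    participant_id: str = "sub-01",
    roi_name: str = "roi",
) -> BetaPatternSet:
    """Collect per-combination betas into a :class:`BetaPatternSet`,
    optionally restricting to an ROI vertex list."""
    conditions = tuple(conditions or enumerate_conditions())
    expected = {(si, ci) for si, ci, _ in plan.iter_combinations()}
    missing = expected - set(betas_by_combination)
    if missing:
        raise ValueError(f"missing betas for combinations: {sorted(missing)}")
    out = {}
    for key in sorted(expected):
        b = np.asarray(betas_by_combination[key])
        if roi is not None:
            idx = np.asarray(roi, dtype=int)
            if idx.size == 0:
                raise ValueError("empty ROI")
            if idx.min() < 0 or idx.max() >= b.shape[2]:
                raise ValueError("ROI references out-of-range vertex indices")
            b = b[:, :, idx]
        out[key] = b
    return BetaPatternSet(
        betas=out,
        conditions=conditions,
        plan=plan,
        participant_id=participant_id,
        roi=roi_name,
    )


def average_period(patterns: BetaPatternSet, period: str) -> PeriodPatternSet:
    """Mean over the period's four TR lags, per (split, combination,
    condition): encoding covers 4.0-6.4 s, delay 9.6-12.0 s (closed)."""
    lags = period_lags(period)
    out = {
        key: b[:, lags, :].mean(axis=1) for key, b in patterns.betas.items()
    }
    return PeriodPatternSet(
        patterns=out,
        conditions=patterns.conditions,
        period=period,
        participant_id=patterns.participant_id,
        roi=patterns.roi,
    )


def roi_mean_timecourse(patterns: BetaPatternSet) -> pd.DataFrame:
    """Mean beta over vertices and all patterns, per (condition, lag) — the
    diagnostic amplitude-vs-time curve."""
    stack = np.stack(list(patterns.betas.values()))  # (P, C, L, V)
    mean = stack.mean(axis=(0, 3))  # (C, L)
    rows = []
    for ci, cond in enumerate(patterns.conditions):
        for lag in range(mean.shape[1]):
            rows.append(
                {
                    "condition": cond.label(),
                    "lag": lag,
                    "time_s": lag * 0.8,
                    "amplitude": mean[ci, lag],
                }
            )
    return pd.DataFrame(rows)
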