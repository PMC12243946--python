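"""Synthetic vertex time series with a controllable representational geometry.

The generator realizes the hypothesis space the analysis is built to probe:
each object category has a *perceptual* population pattern (driving responses
whenever the object is on screen — target presentation or distractor images)
and a *memory* pattern (sustained through the retention delay while the
object is held in working memory).  The two codes are related by a rotation
angle ``theta``:

    memory[o] = cos(theta) * perceptual[o] + sin(theta) * q_o,

with ``q_o`` a unit vector orthogonal to ``perceptual[o]``.  ``theta = 0``
makes perception and memory share one code (the sensory account);
``theta = pi/2`` makes them orthogonal (a fully transformed code).  Because
the truth is known, every downstream stage — FIR GLM, cross-decoding, the
cross-decoding ratio — has a known answer.

Stage gains emulate the empirical regime: distractor-evoked visual responses
are far stronger than the sustained delay-period memory signal.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .design import (
    TR_SECONDS,
    EventKind,
    ObjectID,
    RunSchedule,
    SessionPlan,
    build_run_schedule,
    round_onsets_to_tr,
    write_events_tsv,
)

__all__ = [
    "GroundTruthGeometry",
    "HemodynamicModel",
    "VertexTimeSeries",
    "make_ground_truth",
    "simulate_run",
    "simulate_participant",
]


@dataclass(frozen=True)
class GroundTruthGeometry:
    """Per-object perceptual and memory patterns plus stage gains.

    Attributes
    ----------
    perceptual, memory
        dict ObjectID -> unit vector over vertices.
    theta
        Rotation angle (radians, in [0, pi/2]) between the two codes.
    gain_encoding
        Amplitude of the target's perceptual pattern while the target image
        is on screen.
    gain_delay
        Amplitude of the target's memory pattern, sustained from target
        offset to probe onset.
    gain_distractor
        Amplitude of the distractor's perceptual pattern contributed by each
        distractor image.
    noise_sd
        SD of i.i.d. Gaussian noise per vertex per TR.
    """

    n_vertices: int
    theta: float
    perceptual: dict[ObjectID, np.ndarray]
    memory: dict[ObjectID, np.ndarray]
    gain_encoding: float = 1.0
    gain_delay: float = 0.35
    gain_distractor: float = 0.8
    noise_sd: float = 0.45


def make_ground_truth(
    n_vertices: int = 200,
    theta: float = 0.0,
    gain_encoding: float = 1.0,
    gain_delay: float = 0.35,
    gain_distractor: float = 0.8,
    noise_sd: float = 0.45,
    seed: int | np.random.Generator = 0,
) -> GroundTruthGeometry:
    """Draw random unit perceptual patterns and rotate them into memory
    patterns at angle ``theta``."""
    if n_vertices < 8:
        raise ValueError("n_vertices must be >= 8 to admit orthogonal directions")
    if not 0.0 <= theta <= np.pi / 2 + 1e-12:
        raise ValueError("theta must lie in [0, pi/2]")
    for name, g in [
        ("gain_encoding", gain_encoding),
        ("gain_delay", gain_delay),
        ("gain_distractor", gain_distractor),
        ("noise_sd", noise_sd),
    ]:
        if g < 0:
            raise ValueError(f"{name} must be >= 0")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    perceptual: dict[ObjectID, np.ndarray] = {}
    memory: dict[ObjectID, np.ndarray] = {}
    for obj in ObjectID:
        p = rng.standard_normal(n_vertices)
        p /= np.linalg.norm(p)
        q = rng.standard_normal(n_vertices)
        q -= (q @ p) * p  # orthogonalize
        q /= np.linalg.norm(q)
        perceptual[obj] = p
        memory[obj] = np.cos(theta) * p + np.sin(theta) * q
    return GroundTruthGeometry(
        n_vertices=n_vertices,
        theta=theta,
        perceptual=perceptual,
        memory=memory,
        gain_encoding=gain_encoding,
        gain_delay=gain_delay,
        gain_distractor=gain_distractor,
        noise_sd=noise_sd,
    )


@dataclass(frozen=True)
class HemodynamicModel:
    """Forward hemodynamic kernel sampled on the TR grid.

    ``fir_identity`` is a unit impulse (so GLM recovery can be tested
    exactly).  ``compact_gamma`` (the default) is a single gamma response
    peaking at 4 s with compact support (back to baseline by 8 s): brief
    events evoke no signal inside the delay analysis window that starts
    8.6 s after stimulus offset, matching that window's design intent.
    ``double_gamma`` is the community-standard two-gamma response (5 s peak,
    15 s undershoot, peak:undershoot ratio 6, truncated at 24 s); its long
    positive tail leaks stimulus-evoked signal into the delay window, which
    real analyses tolerate because it is small relative to measurement noise.
    """

    kind: str = "compact_gamma"
    peak_s: float = 4.0
    scale_s: float = 0.25  # gamma scale for compact_gamma
    undershoot_s: float = 15.0
    ratio: float = 6.0
    length_s: float = 8.0

    def kernel(self, tr_seconds: float = TR_SECONDS) -> np.ndarray:
        if self.kind == "fir_identity":
            return np.array([1.0])
        if self.length_s > 24.0 + 1e-9:
            raise ValueError("kernel length must be <= 24 s")
        from scipy.stats import gamma as gamma_dist

        if self.kind == "compact_gamma":
            t = np.arange(0, self.length_s, tr_seconds)
            shape = self.peak_s / self.scale_s + 1  # peak at (shape-1)*scale
            h = gamma_dist.pdf(t, shape, scale=self.scale_s)
        elif self.kind == "double_gamma":
            length = self.length_s if self.length_s > 8.0 else 24.0
            t = np.arange(0, length, tr_seconds)
            peak = gamma_dist.pdf(t, 5.0 + 1, scale=1.0)
            under = gamma_dist.pdf(t, self.undershoot_s + 1, scale=1.0)
            h = peak - under / self.ratio
        else:
            raise ValueError(f"unknown hemodynamic model kind: {self.kind!r}")
        if h.sum() <= 0:
            raise ValueError("kernel must integrate to a positive value")
        return h / h.max()


@dataclass
class VertexTimeSeries:
    """vertices x TRs data matrix for one run."""

    data: np.ndarray  # (n_vertices, n_trs)
    tr_seconds: float = TR_SECONDS
    run_id: str = "run-01"
    session_id: str = "ses-1"
    participant_id: str = "sub-01"

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.data.ndim != 2:
            raise ValueError("data must be 2-D (vertices x TRs)")
        if not np.all(np.isfinite(self.data)):
            raise ValueError("time series contains non-finite values")

    @property
    def n_vertices(self) -> int:
        return self.data.shape[0]

    @property
    def n_trs(self) -> int:
        return self.data.shape[1]


def _lag_of(rel_deciseconds: int) -> int:
    """Nearest-TR lag of a within-trial offset given in deciseconds (0.1 s),
    half-TR ties rounding up; exact integer arithmetic (TR = 8 ds)."""
    return (2 * rel_deciseconds + 8) // 16


def neural_signal(schedule: RunSchedule, truth: GroundTruthGeometry) -> np.ndarray:
    """Noise-free neural signal (n_trs x n_vertices) on the TR grid.

    Target presentation contributes the perceptual pattern at the encoding
    gain; the retention interval (target offset to probe onset) contributes
    a sustained memory-pattern boxcar; each distractor image adds the
    distractor's perceptual pattern at its onset TR.  Within-trial offsets
    map to TR lags by exact decisecond arithmetic, so every trial of a
    condition occupies the same lags relative to its onset.
    """
    tr = schedule.tr_seconds
    n_trs = schedule.n_trs
    sig = np.zeros((n_trs, truth.n_vertices))
    anchor = None  # (onset seconds, TR index) of current trial
    for ev in schedule.events:
        if ev.condition is None:
            continue
        if ev.kind is EventKind.FIXATION:
            ti = int(round(ev.onset / tr))
            anchor = (ev.onset, ti)
            # memory boxcar: target offset (1.0 s) up to probe onset (12.5 s)
            l0, l1 = _lag_of(10), _lag_of(125)
            sig[ti + l0 : min(ti + l1, n_trs)] += (
                truth.gain_delay * truth.memory[ev.condition.target]
            )
            continue
        if anchor is None:
            raise ValueError("trial event encountered before its fixation anchor")
        rel_ds = int(round((ev.onset - anchor[0]) * 10))
        ti = anchor[1]
        if ev.kind is EventKind.TARGET:
            l0 = _lag_of(rel_ds)
            l1 = max(_lag_of(rel_ds + int(round(ev.duration * 10))), l0 + 1)
            sig[ti + l0 : min(ti + l1, n_trs)] += (
                truth.gain_encoding * truth.perceptual[ev.condition.target]
            )
        elif ev.kind is EventKind.DISTRACTOR_IMAGE:
            i = ti + _lag_of(rel_ds)
            if i < n_trs:
                sig[i] += truth.gain_distractor * truth.perceptual[ev.condition.distractor]
    return sig


def simulate_run(
    schedule: RunSchedule,
    truth: GroundTruthGeometry,
    hemo: HemodynamicModel | None = None,
    seed: int | np.random.Generator = 0,
    drift: float = 0.0,
    ar1: float = 0.0,
    **ids,
) -> VertexTimeSeries:
    """Simulate one run: neural signal * hemodynamic kernel + noise.

    Parameters
    ----------
    drift
        Peak-to-peak amplitude of an added linear drift (0 disables).
    ar1
        AR(1) coefficient for temporally correlated noise (0 = white).
    """
    onsets = [on for on, _ in schedule.trial_onsets()]
    tr = schedule.tr_seconds
    for on in onsets:
        if abs(on / tr - round(on / tr)) > 1e-9:
            raise ValueError("schedule must be rounded to the TR grid before simulation")
    hemo = hemo or HemodynamicModel()
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    sig = neural_signal(schedule, truth)  # (T, V)
    h = hemo.kernel(tr)
    if len(h) > 1:
        from scipy.signal import fftconvolve

        sig = fftconvolve(sig, h[:, None], axes=0)[: sig.shape[0]]
    elif h[0] != 1.0:
        sig = sig * h[0]
    n_trs = sig.shape[0]
    noise = rng.standard_normal((n_trs, truth.n_vertices)) * truth.noise_sd
    if truth.noise_sd > 0 and ar1 != 0.0:
        from scipy.signal import lfilter

        noise = lfilter([1.0], [1.0, -ar1], noise, axis=0)
    data = sig + noise
    if drift != 0.0:
        data += drift * np.linspace(-0.5, 0.5, n_trs)[:, None]
    return VertexTimeSeries(data=data.T, tr_seconds=tr, **ids)


def simulate_participant(
    plan: SessionPlan,
    truth: GroundTruthGeometry,
    hemo: HemodynamicModel | None = None,
    seed: int | np.random.Generator = 0,
    participant_id: str = "sub-01",
    strict: bool = True,
) -> tuple[list[VertexTimeSeries], list[RunSchedule]]:
    """Simulate all runs of a two-session participant.

    Run schedules are drawn independently per run (fresh condition order,
    blank placement and distractor sequences) and rounded to the TR grid.
    With fewer than 10 runs in a session the odd/even split-combination plan
    degenerates; ``strict=True`` raises, otherwise a warning is emitted.
    """
    import warnings

    if min(plan.runs_per_session) < 10:
        msg = (
            f"session plan {plan.runs_per_session} has a session with fewer than "
            "10 runs; the odd/even split-combination plan is ill-posed"
        )
        if strict:
            raise ValueError(msg)
        warnings.warn(msg, stacklevel=2)
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    series: list[VertexTimeSeries] = []
    schedules: list[RunSchedule] = []
    for s_idx, n_runs in enumerate(plan.runs_per_session, start=1):
        for r_idx in range(1, n_runs + 1):
            sched = round_onsets_to_tr(build_run_schedule(seed=rng))
            ts = simulate_run(
                sched,
                truth,
                hemo,
                seed=rng,
                run_id=f"run-{r_idx:02d}",
                session_id=f"ses-{s_idx}",
                participant_id=participant_id,
            )
            series.append(ts)
            schedules.append(sched)
    return series, schedules


def write_run(ts: VertexTimeSeries, schedule: RunSchedule, out_dir) -> None:
    """Write one run as .npy + JSON sidecar + events TSV."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    stem = f"{ts.participant_id}_{ts.session_id}_{ts.run_id}"
    np.save(out_dir / f"{stem}_bold.npy", ts.data)
    sidecar = {
        "participant": ts.participant_id,
        "session": ts.session_id,
        "run": ts.run_id,
        "tr_seconds": ts.tr_seconds,
        "n_vertices": ts.n_vertices,
        "n_trs": ts.n_trs,
    }
    (out_dir / f"{stem}_bold.json").write_text(json.dumps(sidecar, indent=1))
    write_events_tsv(schedule, out_dir / f"{stem}_events.tsv")


def read_run(out_dir, participant_id: str, session_id: str, run_id: str):
    """Read back one run written by :func:`write_run`."""
    from .design import read_events_tsv

    out_dir = Path(out_dir)
    stem = f"{participant_id}_{session_id}_{run_id}"
    data = np.load(out_dir / f"{stem}_bold.npy")
    sidecar = json.loads((out_dir / f"{stem}_bold.json").read_text())
    if sidecar["n_vertices"] != data.shape[0] or sidecar["n_trs"] != data.shape[1]:
        raise ValueError(f"sidecar/array shape mismatch for {stem}")
    ts = VertexTimeSeries(
        data=data,
        tr_seconds=float(sidecar["tr_seconds"]),
        run_id=run_id,
        session_id=session_id,
        participant_id=participant_id,
    )
    schedule = read_events_tsv(out_dir / f"{stem}_events.tsv")
    return ts, schedule
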