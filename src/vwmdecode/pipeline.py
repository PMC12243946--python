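"""End-to-end driver: simulate -> estimate -> decode -> stats.

A :class:`PipelineConfig` fixes every parameter and seed explicitly; a run
emits tidy TSV tables (decoding accuracies, cross-decoding ratios, the full
statistical battery, ROI-mean beta time courses) plus a manifest of input
parameters and output checksums, so identical configs reproduce identical
results byte for byte.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import decode as dec
from . import glm, simulate, stats
from .design import SessionPlan, build_run_schedule, round_onsets_to_tr
from .simulate import HemodynamicModel


@dataclass
class ROIConfig:
    """One synthetic ROI: its sector, size and representational geometry."""

    name: str
    n_vertices: int = 200
    theta: float = 0.0  # radians between perceptual and memory codes
    gain_encoding: float = 1.0
    gain_delay: float = 0.35
    gain_distractor: float = 0.8
    noise_sd: float = 0.45

    @property
    def sector(self) -> str | None:
        return dec.sector_of(self.name)


@dataclass
class PipelineConfig:
    n_participants: int = 3
    runs_per_session: tuple[int, int] = (13, 14)
    rois: list[ROIConfig] = field(
        default_factory=lambda: [
            ROIConfig("V1", theta=float(np.pi / 2)),
            ROIConfig("LOT", theta=float(np.pi / 3)),
            ROIConfig("IPS2", theta=float(np.pi / 6)),
        ]
    )
    schemes: list[tuple[str, str]] = field(
        default_factory=lambda: [
            ("within_target_delay", "with_distractors"),
            ("cross_distractor_to_target_delay", "with_distractors"),
            ("within_target_encoding", "with_distractors"),
            ("cross_distractor_to_target_encoding", "with_distractors"),
            ("within_delay", "without_distractors"),
            ("cross_to_no_distractor_targets", "without_distractors"),
        ]
    )
    comparisons: list[tuple[str, str, str]] = field(
        default_factory=lambda: [
            ("within_target_delay", "cross_distractor_to_target_delay", "with_distractors"),
            (
                "within_target_encoding",
                "cross_distractor_to_target_encoding",
                "with_distractors",
            ),
            ("within_delay", "cross_to_no_distractor_targets", "without_distractors"),
        ]
    )
    hemodynamic: str = "compact_gamma"
    seed: int | None = 0
    alpha: float = 0.05

    def validate(self) -> None:
        if self.seed is None:
            raise ValueError("config must set an explicit seed")
        if self.n_participants < 1:
            raise ValueError("n_participants must be >= 1")
        if len(self.runs_per_session) != 2:
            raise ValueError("runs_per_session must list two sessions")
        for name, tset in self.schemes:
            dec.get_scheme(name, trial_set=tset)  # raises on unknown

    # -- serialization -----------------------------------------------------
    def to_dict(self) -> dict:
        d = asdict(self)
        d["runs_per_session"] = list(self.runs_per_session)
        d["schemes"] = [list(s) for s in self.schemes]
        d["comparisons"] = [list(c) for c in self.comparisons]
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        d["rois"] = [ROIConfig(**r) for r in d.get("rois", [])] or None
        if d["rois"] is None:
            d.pop("rois")
        if "runs_per_session" in d:
            d["runs_per_session"] = tuple(d["runs_per_session"])
        if "schemes" in d:
            d["schemes"] = [tuple(s) for s in d["schemes"]]
        if "comparisons" in d:
            d["comparisons"] = [tuple(c) for c in d["comparisons"]]
        return cls(**d)

    def to_yaml(self, path) -> None:
        Path(path).write_text(yaml.safe_dump(self.to_dict(), sort_keys=True))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        return cls.from_dict(yaml.safe_load(Path(path).read_text()))

    def param_hash(self) -> str:
        canon = json.dumps(self.to_dict(), sort_keys=True)
        return hashlib.sha256(canon.encode()).hexdigest()[:16]


# ---------------------------------------------------------------------------
# single-participant unit used by the pipeline and the acceptance checks


def decode_participant(
    config: PipelineConfig,
    participant_index: int,
    rng: np.random.Generator,
) -> pd.DataFrame:
    """Simulate, estimate and decode one participant; tidy rows per
    (ROI, scheme).  Run schedules are shared across the participant's ROIs,
    as they would be for real concurrent recordings."""
    pid = f"sub-{participant_index + 1:02d}"
    plan = SessionPlan(tuple(config.runs_per_session))
    split_plan = glm.build_split_plan(config.runs_per_session)
    hemo = HemodynamicModel(kind=config.hemodynamic)
    schedules = []
    ids = []
    for s_idx, n_runs in enumerate(plan.runs_per_session, start=1):
        for r_idx in range(1, n_runs + 1):
            schedules.append(round_onsets_to_tr(build_run_schedule(seed=rng)))
            ids.append((f"ses-{s_idx}", f"run-{r_idx:02d}"))
    rows = []
    for roi_cfg in config.rois:
        truth = simulate.make_ground_truth(
            n_vertices=roi_cfg.n_vertices,
            theta=roi_cfg.theta,
            gain_encoding=roi_cfg.gain_encoding,
            gain_delay=roi_cfg.gain_delay,
            gain_distractor=roi_cfg.gain_distractor,
            noise_sd=roi_cfg.noise_sd,
            seed=rng,
        )
        series = [
            simulate.simulate_run(
                sched, truth, hemo, seed=rng,
                session_id=sid, run_id=rid, participant_id=pid,
            )
            for sched, (sid, rid) in zip(schedules, ids)
        ]
        patterns = glm.estimate_patterns(series, schedules, split_plan)
        patterns.roi = roi_cfg.name
        for name, tset in config.schemes:
            res = dec.run_scheme(patterns, name, trial_set=tset)
            rows.append(
                {
                    "participant": pid,
                    "unit": roi_cfg.name,
                    "level": "roi",
                    "sector": roi_cfg.sector or "n/a",
                    "scheme": name,
                    "trial_set": res.trial_set,
                    "n_instances": res.n_pair_instances,
                    "accuracy": res.accuracy,
                }
            )
    return pd.DataFrame(rows)


def add_sector_rows(decoding: pd.DataFrame) -> pd.DataFrame:
    """Append sector-level rows: unweighted mean over member ROIs, per
    participant x scheme x trial_set."""
    roi_rows = decoding[decoding["level"] == "roi"]
    grouped = (
        roi_rows[roi_rows["sector"] != "n/a"]
        .groupby(["participant", "sector", "scheme", "trial_set"], as_index=False)
        .agg(accuracy=("accuracy", "mean"), n_instances=("n_instances", "first"))
    )
    grouped["unit"] = grouped["sector"]
    grouped["level"] = "sector"
    return pd.concat([decoding, grouped[decoding.columns]], ignore_index=True)


def ratio_table(decoding: pd.DataFrame, comparisons, eps: float = 0.01) -> pd.DataFrame:
    """Cross-decoding ratios per participant and unit, plus a group-level
    ratio formed from participant-mean accuracies (both levels are reported
    because figures could be built either way)."""
    rows = []
    for within_s, cross_s, tset in comparisons:
        for unit, level in decoding[["unit", "level"]].drop_duplicates().itertuples(index=False):
            sel = decoding[(decoding["unit"] == unit) & (decoding["trial_set"] == tset)]
            w = sel[sel["scheme"] == within_s].set_index("participant")["accuracy"]
            c = sel[sel["scheme"] == cross_s].set_index("participant")["accuracy"]
            common = w.index.intersection(c.index)
            if common.empty:
                continue
            for p in common:
                r = dec.cross_ratio(w[p], c[p], eps=eps)
                rows.append(
                    {
                        "participant": p, "unit": unit, "level": level,
                        "comparison": f"{within_s}|{cross_s}", "trial_set": tset,
                        "within": r.within, "cross": r.cross,
                        "ratio": r.ratio, "valid": r.valid,
                    }
                )
            g = dec.cross_ratio(float(w.loc[common].mean()), float(c.loc[common].mean()), eps=eps)
            rows.append(
                {
                    "participant": "group", "unit": unit, "level": level,
                    "comparison": f"{within_s}|{cross_s}", "trial_set": tset,
                    "within": g.within, "cross": g.cross,
                    "ratio": g.ratio, "valid": g.valid,
                }
            )
    return pd.DataFrame(rows)


@dataclass
class RunManifest:
    param_hash: str
    seed: int
    outputs: dict[str, str]  # relative path -> sha256

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: PipelineConfig, out_dir) -> RunManifest:
    """Execute all stages and write the output tree.

    Outputs: ``decoding.tsv`` (per participant/unit/scheme accuracies, ROI
    and sector level), ``ratios.tsv``, ``stats_*.tsv`` (the battery),
    ``timecourses.tsv`` diagnostics, ``config.yaml`` and ``manifest.json``.
    """
    config.validate()
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    root = np.random.SeedSequence(config.seed)
    tables: dict[str, pd.DataFrame] = {}
    per_part = []
    for p_idx, child in enumerate(root.spawn(config.n_participants)):
        rng = np.random.default_rng(child)
        per_part.append(decode_participant(config, p_idx, rng))
    decoding = add_sector_rows(pd.concat(per_part, ignore_index=True))
    tables["decoding.tsv"] = decoding
    tables["ratios.tsv"] = ratio_table(decoding, config.comparisons)
    report = stats.run_battery(decoding, comparisons=config.comparisons, alpha=config.alpha)
    tables["stats_vs_chance.tsv"] = report.vs_chance
    tables["stats_drop.tsv"] = report.drop
    tables["stats_sector_pairwise.tsv"] = report.sector_pairwise
    tables["stats_anova.tsv"] = report.anova
    config.to_yaml(out / "config.yaml")
    outputs = {"config.yaml": _sha256(out / "config.yaml")}
    for name, df in tables.items():
        path = out / name
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
        outputs[name] = _sha256(path)
    manifest = RunManifest(param_hash=config.param_hash(), seed=config.seed, outputs=outputs)
    manifest.to_json(out / "manifest.json")
    return manifest


# ---------------------------------------------------------------------------
# ROI label files: newline-delimited vertex indices with a tag header


def write_roi_file(path, name: str, vertices, sector: str | None = None) -> None:
    lines = [f"# roi: {name}", f"# sector: {sector or dec.sector_of(name) or 'n/a'}"]
    lines += [str(int(v)) for v in vertices]
    Path(path).write_text("\n".join(lines) + "\n")


def read_roi_file(path, n_vertices: int | None = None) -> tuple[str, str, np.ndarray]:
    """Returns (name, sector, vertex indices); bounds-checked when
    ``n_vertices`` is given."""
    name, sector = "roi", "n/a"
    idx = []
    for line in Path(path).read_text().splitlines():
        line = line.strip()
        if not line:
            continue
        if line.startswith("#"):
            key, _, val = line.lstrip("# ").partition(":")
            if key.strip() == "roi":
                name = val.strip()
            elif key.strip() == "sector":
                sector = val.strip()
            continue
        idx.append(int(line))
    vertices = np.array(idx, dtype=int)
    if n_vertices is not None and vertices.size and (
        vertices.min() < 0 or vertices.max() >= n_vertices
    ):
        raise ValueError(
            f"ROI {name!r} references vertex indices outside [0, {n_vertices})"
        )
    return name, sector, vertices
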