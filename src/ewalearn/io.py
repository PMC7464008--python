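"""File formats, run configuration and the end-to-end pipeline.

All tabular formats are comma-separated UTF-8 with a header row and
1-based trial indices:

* trials CSV: participant_id, trial, chosen, feedback, phase
* profiles CSV: participant_id, group, ces_d, dams_d, panas_pa, panas_na,
  awareness, attention, age, gender
* heartbeat CSV: participant_id, duration, actual_beats, reported_beats
* probe CSV: participant_id, probe_type, rt, emotion_block, soa

Every run writes a JSON manifest carrying the seed and a hash of the full
configuration, so reruns are reproducible and attributable.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .cohort import CohortSpec, simulate_cohort
from .ewa import SessionData, TrialRecord
from .hbayes import PosteriorResult, SamplerConfig, fit_hierarchical
from .psychometrics import (
    HeartbeatTrial,
    ParticipantProfile,
    ProbeTrial,
    arcsine_transform,
    heartbeat_score,
    interoceptive_attention,
)
from .stats import correlation_table, two_sample_t
from .task import TaskConfig

__all__ = [
    "RunConfig",
    "read_sessions",
    "write_sessions",
    "read_profiles",
    "write_profiles",
    "write_heartbeat_trials",
    "read_heartbeat_trials",
    "write_probe_trials",
    "read_probe_trials",
    "run_pipeline",
]

log = logging.getLogger("ewalearn")


@dataclass
class RunConfig:
    """Full pipeline configuration: cohort, sampler and analysis settings."""

    cohort: CohortSpec = field(default_factory=CohortSpec)
    sampler: SamplerConfig = field(default_factory=SamplerConfig)
    window: str = "reversal"
    grubbs_level: float = 0.05
    seed: int = 0

    def __post_init__(self) -> None:
        # One master seed fans out to the cohort and sampler stages.
        ss = np.random.SeedSequence(self.seed).spawn(2)
        self.cohort = dataclasses.replace(
            self.cohort, seed=int(ss[0].generate_state(1)[0] % 2**31)
        )
        self.sampler = dataclasses.replace(
            self.sampler, seed=int(ss[1].generate_state(1)[0] % 2**31)
        )

    def to_dict(self) -> dict:
        def enc(obj):
            if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
                return {k: enc(v) for k, v in dataclasses.asdict(obj).items()}
            if isinstance(obj, (tuple, list)):
                return [enc(v) for v in obj]
            return obj

        return {
            "cohort": enc(self.cohort),
            "sampler": enc(self.sampler),
            "window": self.window,
            "grubbs_level": self.grubbs_level,
            "seed": self.seed,
        }

    def hash(self) -> str:
        payload = json.dumps(self.to_dict(), sort_keys=True).encode()
        return hashlib.sha256(payload).hexdigest()[:16]

    @classmethod
    def from_yaml(cls, path: str | Path, seed: int | None = None) -> "RunConfig":
        import yaml

        raw = yaml.safe_load(Path(path).read_text()) or {}
        cohort_raw = dict(raw.get("cohort", {}))
        task_raw = cohort_raw.pop("task", {})
        if "correlation_targets" in cohort_raw:
            cohort_raw["correlation_targets"] = tuple(
                tuple(t) for t in cohort_raw["correlation_targets"]
            )
        cohort = CohortSpec(task=TaskConfig(**task_raw), **cohort_raw)
        sampler = SamplerConfig(**raw.get("sampler", {}))
        return cls(
            cohort=cohort,
            sampler=sampler,
            window=raw.get("window", "reversal"),
            grubbs_level=raw.get("grubbs_level", 0.05),
            seed=seed if seed is not None else raw.get("seed", 0),
        )


# ---------------------------------------------------------------------------
# Readers / writers
# ---------------------------------------------------------------------------

def write_sessions(sessions: list[SessionData], path: str | Path) -> None:
    rows = [
        {
            "participant_id": s.participant_id,
            "trial": t.trial,
            "chosen": t.chosen,
            "feedback": t.feedback,
            "phase": t.phase,
        }
        for s in sessions
        for t in s.trials
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_sessions(path: str | Path, task: TaskConfig | None = None) -> list[SessionData]:
    """Read and validate a trials CSV.

    Rejects malformed rows (feedback outside {0,1}, non-contiguous trial
    indices within a participant) with the offending CSV line number.
    An empty file yields an empty collection with a warning.
    """
    task = task or TaskConfig()
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError:
        warnings.warn(f"{path}: empty trials file", stacklevel=2)
        return []
    if df.empty:
        warnings.warn(f"{path}: empty trials file", stacklevel=2)
        return []
    required = {"participant_id", "trial", "chosen", "feedback", "phase"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing columns {sorted(missing)}")
    df["_line"] = np.arange(2, len(df) + 2)  # header is line 1
    bad = df.loc[~df["feedback"].isin([0, 1])]
    if not bad.empty:
        raise ValueError(
            f"{path}: line {int(bad['_line'].iloc[0])}: "
            f"feedback {bad['feedback'].iloc[0]!r} not in {{0, 1}}"
        )
    sessions = []
    for pid, g in df.groupby("participant_id", sort=False):
        trials_idx = g["trial"].to_numpy()
        jumps = np.flatnonzero(np.diff(trials_idx) != 1)
        if trials_idx[0] != 1 or jumps.size:
            line = int(g["_line"].iloc[0 if trials_idx[0] != 1 else jumps[0] + 1])
            raise ValueError(
                f"{path}: line {line}: non-contiguous trial index for participant {pid!r}"
            )
        records = [
            TrialRecord(int(r.trial), int(r.chosen), int(r.feedback), str(r.phase))
            for r in g.itertuples()
        ]
        sessions.append(SessionData(str(pid), records, task))
    return sessions


def write_profiles(profiles: list[ParticipantProfile], path: str | Path) -> None:
    pd.DataFrame([dataclasses.asdict(p) for p in profiles]).to_csv(path, index=False)


def read_profiles(path: str | Path) -> list[ParticipantProfile]:
    df = pd.read_csv(path)
    return [
        ParticipantProfile(
            participant_id=str(r.participant_id),
            group=str(r.group),
            ces_d=int(r.ces_d),
            dams_d=int(r.dams_d),
            panas_pa=int(r.panas_pa),
            panas_na=int(r.panas_na),
            awareness=float(r.awareness),
            attention=float(r.attention),
            age=float(getattr(r, "age", float("nan"))),
            gender=str(getattr(r, "gender", "unknown")),
        )
        for r in df.itertuples()
    ]


def write_heartbeat_trials(
    trials: dict[str, list[HeartbeatTrial]], path: str | Path
) -> None:
    rows = [
        {"participant_id": pid, **dataclasses.asdict(t)}
        for pid, ts in trials.items()
        for t in ts
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_heartbeat_trials(path: str | Path) -> dict[str, list[HeartbeatTrial]]:
    df = pd.read_csv(path)
    out: dict[str, list[HeartbeatTrial]] = {}
    for r in df.itertuples():
        out.setdefault(str(r.participant_id), []).append(
            HeartbeatTrial(float(r.duration), int(r.actual_beats), int(r.reported_beats))
        )
    return out


def write_probe_trials(trials: dict[str, list[ProbeTrial]], path: str | Path) -> None:
    rows = [
        {"participant_id": pid, **dataclasses.asdict(t)}
        for pid, ts in trials.items()
        for t in ts
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_probe_trials(path: str | Path) -> dict[str, list[ProbeTrial]]:
    df = pd.read_csv(path)
    out: dict[str, list[ProbeTrial]] = {}
    for r in df.itertuples():
        out.setdefault(str(r.participant_id), []).append(
            ProbeTrial(str(r.probe_type), float(r.rt), str(r.emotion_block), float(r.soa))
        )
    return out


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------

_PROFILE_MEASURES = ("ces_d", "dams_d", "panas_pa", "panas_na", "awareness", "attention")


def group_comparison_table(profiles: list[ParticipantProfile]) -> pd.DataFrame:
    """Baseline group comparison: per-measure group means (SD) and t tests."""
    rows = []
    groups = sorted({p.group for p in profiles})
    if len(groups) != 2:
        raise ValueError(f"expected two groups; got {groups}")
    for m in _PROFILE_MEASURES:
        a = [getattr(p, m) for p in profiles if p.group == groups[0]]
        b = [getattr(p, m) for p in profiles if p.group == groups[1]]
        t, df, p = two_sample_t(a, b)
        rows.append(
            {
                "measure": m,
                f"mean_{groups[0]}": np.mean(a),
                f"sd_{groups[0]}": np.std(a, ddof=1),
                f"mean_{groups[1]}": np.mean(b),
                f"sd_{groups[1]}": np.std(b, ddof=1),
                "t": t,
                "df": df,
                "p": p,
            }
        )
    return pd.DataFrame(rows)


def run_pipeline(config: RunConfig, outdir: str | Path) -> dict:
    """Simulate -> fit -> score -> analyze, writing the full report bundle.

    Returns a dict with the in-memory results and the list of files
    written. Any stage failure is re-raised naming the stage.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    bundle: dict = {"files": []}

    def stage(name):
        log.info("stage %s starting", name)
        return time.perf_counter()

    def write(df: pd.DataFrame, name: str):
        path = outdir / name
        df.to_csv(path, index=False)
        bundle["files"].append(str(path))

    try:
        t0 = stage("simulate")
        sessions, profiles, truth = simulate_cohort(config.cohort)
        log.info("stage simulate done in %.1fs", time.perf_counter() - t0)
    except Exception as e:
        raise RuntimeError("pipeline stage 'simulate' failed") from e

    try:
        t0 = stage("fit")
        result: PosteriorResult = fit_hierarchical(
            sessions, config.sampler, window=config.window
        )
        log.info("stage fit done in %.1fs", time.perf_counter() - t0)
    except Exception as e:
        raise RuntimeError("pipeline stage 'fit' failed") from e

    try:
        t0 = stage("analyze")
        group_table = group_comparison_table(profiles)
        corr = correlation_table(profiles, result.map_estimates)
        corr_rows = [
            {
                "measure": m,
                "parameter": p,
                "r": cell.r,
                "p": cell.p,
                "n": cell.n,
                "flag": cell.flag,
            }
            for m, row in corr.iterrows()
            for p, cell in row.items()
        ]
        log.info("stage analyze done in %.1fs", time.perf_counter() - t0)
    except Exception as e:
        raise RuntimeError("pipeline stage 'analyze' failed") from e

    write_sessions(sessions, outdir / "trials.csv")
    bundle["files"].append(str(outdir / "trials.csv"))
    write_profiles(profiles, outdir / "profiles.csv")
    bundle["files"].append(str(outdir / "profiles.csv"))
    write(truth, "true_params.csv")
    write(result.map_table, "posterior_summary.csv")
    write(group_table, "group_comparison.csv")
    write(pd.DataFrame(corr_rows), "correlation_table.csv")

    diagnostics = {
        "config_hash": config.hash(),
        "seed": config.seed,
        "version": __version__,
        "rhat": result.rhat,
        "converged": result.converged,
        "accept_rate": result.accept_rate,
        "waic": result.waic,
        "sampler": {
            "chains": result.config.chains,
            "draws": result.config.draws,
            "warmup": result.config.warmup,
            "seed": result.config.seed,
        },
    }
    (outdir / "diagnostics.json").write_text(json.dumps(diagnostics, indent=2))
    bundle["files"].append(str(outdir / "diagnostics.json"))

    manifest = {
        "config": config.to_dict(),
        "config_hash": config.hash(),
        "seed": config.seed,
        "version": __version__,
        "files": [Path(f).name for f in bundle["files"]],
    }
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2))
    bundle["files"].append(str(outdir / "manifest.json"))

    bundle.update(
        sessions=sessions,
        profiles=profiles,
        truth=truth,
        posterior=result,
        group_table=group_table,
        correlation_table=corr,
        converged=result.converged,
    )
    return bundle
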