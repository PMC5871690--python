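"""Config-driven end-to-end session processing.

``run_pipeline`` takes a YAML config naming the annotation files of one or
more dyadic sessions and executes the full chain — validate, rasterize,
derive states, per-participant summaries, joint/synchrony analysis, event
export — and, when at least two dyads were recorded under both conditions,
the per-state condition comparison. All artifacts plus a machine-readable run
log (package version, seed, config hash) land in the configured output
directory.
"""

from __future__ import annotations

import hashlib
import json
import logging
from pathlib import Path

import yaml

from . import __version__
from .dyad import compare_conditions, joint_distribution, joint_states, synchrony
from .events import export_events, write_events
from .states import derive_states, segment_states, session_summary
from .timeline import (
    AnnotationDialect,
    TimelineError,
    align_dyad,
    rasterize,
    read_annotations,
)

logger = logging.getLogger(__name__)


class PipelineError(Exception):
    """A pipeline stage failed; the message names the stage and input."""


def load_config(path) -> dict:
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    if not isinstance(cfg, dict) or "sessions" not in cfg:
        raise PipelineError("config must be a mapping with a 'sessions' list")
    return cfg


def _config_hash(cfg: dict) -> str:
    return hashlib.sha256(
        json.dumps(cfg, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _stage(name: str, detail: str, fn, *args, **kwargs):
    try:
        return fn(*args, **kwargs)
    except (TimelineError, OSError, ValueError) as exc:
        raise PipelineError(f"stage {name!r} failed on {detail}: {exc}") from exc


def process_session(session_cfg: dict, fps: float, out_dir: Path,
                    dialect: AnnotationDialect, fill=None,
                    min_duration_frames: int = 1) -> dict:
    """Run one session end to end; returns its summary bundle."""
    session_id = str(session_cfg.get("session_id", "session"))
    condition = str(session_cfg.get("condition", "condition"))
    path = session_cfg.get("annotations")
    if path is None or not Path(path).exists():
        raise PipelineError(f"stage 'validate' failed: annotation file not found: {path}")

    annotations = _stage("validate", path, read_annotations, path, dialect)
    duration = session_cfg.get("duration_s") or max(
        (a.offset_s for anns in annotations.values() for a in anns), default=0.0
    )
    timelines = {}
    for participant in ("infant", "adult"):
        if participant not in annotations:
            raise PipelineError(
                f"stage 'validate' failed on {path}: no annotations for {participant!r}"
            )
        timelines[participant] = _stage(
            "rasterize", f"{path} ({participant})", rasterize,
            annotations[participant], fps, duration,
            participant=participant, session_id=session_id,
            condition=condition, fill=fill,
        )
    dyad = _stage("align", session_id, align_dyad,
                  timelines["infant"], timelines["adult"])

    sdir = out_dir / session_id
    sdir.mkdir(parents=True, exist_ok=True)
    bundle = {"session_id": session_id, "condition": condition,
              "dyad": str(session_cfg.get("dyad", session_id)),
              "participants": {}}
    for participant in ("infant", "adult"):
        tl = getattr(dyad, participant)
        tl.write_tsv(sdir / f"{participant}_timeline.tsv")
        seq = derive_states(tl)
        seq.to_frame_table().to_csv(sdir / f"{participant}_states.tsv",
                                    sep="\t", index=False)
        summary = session_summary(tl)
        with open(sdir / f"{participant}_summary.json", "w") as fh:
            json.dump(summary, fh, indent=2)
        segments = segment_states(seq, min_duration_frames)
        events = export_events(segments, fps, participant=participant,
                               session_id=session_id, condition=condition)
        write_events(events, sdir / f"{participant}_events.tsv")
        bundle["participants"][participant] = summary

    jseq = _stage("joint", session_id, joint_states, dyad)
    jd = joint_distribution(jseq)
    jd.to_frame().to_csv(sdir / "joint_distribution.csv")
    sync = synchrony(jseq)
    with open(sdir / "synchrony.json", "w") as fh:
        json.dump(sync.as_dict(), fh, indent=2)
    bundle["synchrony"] = sync.as_dict()
    return bundle


def run_pipeline(config_path, seed: int | None = None) -> dict:
    """Execute the pipeline described by a YAML config; returns the report.

    Config keys: ``fps`` (default 30), ``out_dir``, ``alpha``,
    ``min_duration_frames``, ``delimiter``, ``columns`` (column remapping),
    ``fill`` (per-dimension gap fill), and ``sessions`` — a list of
    ``{session_id, dyad, condition, annotations}`` entries. The condition
    comparison runs when at least 2 dyads have both conditions.
    """
    cfg = load_config(config_path)
    fps = float(cfg.get("fps", 30.0))
    out_dir = Path(cfg.get("out_dir", "dyadplay_out"))
    alpha = float(cfg.get("alpha", 0.05))
    min_dur = int(cfg.get("min_duration_frames", 1))
    dialect = AnnotationDialect(
        delimiter=str(cfg.get("delimiter", ",")),
        columns=dict(cfg.get("columns", {})),
    )
    fill_cfg = cfg.get("fill") or None
    fill = None
    if fill_cfg:
        fill = {dim: (int(v[0]), None if v[1] is None else int(v[1]))
                for dim, v in fill_cfg.items()}
    out_dir.mkdir(parents=True, exist_ok=True)

    bundles = [
        process_session(s, fps, out_dir, dialect, fill=fill,
                        min_duration_frames=min_dur)
        for s in cfg["sessions"]
    ]

    report = {
        "version": __version__,
        "seed": seed,
        "config_hash": _config_hash(cfg),
        "fps": fps,
        "n_sessions": len(bundles),
        "sessions": bundles,
    }

    # condition comparison over dyads seen under exactly two conditions
    conditions = sorted({b["condition"] for b in bundles})
    comparisons = {}
    if len(conditions) == 2:
        for participant in ("infant", "adult"):
            nested: dict = {}
            for b in bundles:
                freqs = b["participants"][participant]["state_frequencies"]
                nested.setdefault(b["dyad"], {})[b["condition"]] = freqs
            complete = {d: v for d, v in nested.items() if len(v) == 2}
            if len(complete) >= 2:
                result = compare_conditions(
                    complete, alpha=alpha, group=participant,
                    conditions=(conditions[0], conditions[1]),
                )
                result.to_frame().to_csv(
                    out_dir / f"comparison_{participant}.tsv", sep="\t", index=False
                )
                comparisons[participant] = json.loads(
                    result.to_frame().to_json(orient="records")
                )
    if comparisons:
        report["comparisons"] = comparisons
    else:
        report["comparisons_skipped"] = (
            "need >= 2 dyads observed under 2 conditions; "
            f"found conditions {conditions}"
        )
        logger.info(report["comparisons_skipped"])

    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(report, fh, indent=2)
    return report
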