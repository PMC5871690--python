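"""Reading, validating, rasterizing and aligning behavioral annotations.

Coders mark intervals (onset/offset in seconds) per participant and per
dimension; this module turns those interval tables into gap-free fixed-rate
*coded timelines* — one (main code, sub-code) triple per video frame — which
every downstream analysis consumes.

Time base: 0-based frames with half-open coverage. Frame ``i`` covers
``[i/fps, (i+1)/fps)``; a time landing exactly on a frame boundary belongs to
the later frame. Coding intervals are half-open ``[onset_s, offset_s)`` as
well, so rasterization is unambiguous and onset arithmetic stays exact for
event-locked (e.g. EEG) use downstream.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from . import scheme
from .scheme import DIMENSIONS, NO_SUBCODE, validate_subcode

logger = logging.getLogger(__name__)

#: Participant roles in a dyad.
PARTICIPANTS = ("infant", "adult")

#: Default frame rate (frames per second) of the coded video.
DEFAULT_FPS = 30.0

#: Default annotation-table column names; remappable via AnnotationDialect.
DEFAULT_COLUMNS = ("participant", "dimension", "main_code", "sub_code", "onset_s", "offset_s")

_COVERAGE_TOL = 1e-9


class TimelineError(Exception):
    """Base class for annotation/timeline errors."""


class FormatError(TimelineError):
    """The input file does not match the expected table format."""


class ValidationError(TimelineError):
    """A row or frame violates the coding scheme."""


@dataclass(frozen=True)
class AnnotationDialect:
    """How to parse an annotation table: delimiter and column mapping.

    ``columns`` maps the canonical names (participant, dimension, main_code,
    sub_code, onset_s, offset_s) to the names actually present in the file.
    """

    delimiter: str = ","
    columns: dict[str, str] = field(default_factory=dict)

    def column(self, canonical: str) -> str:
        return self.columns.get(canonical, canonical)


@dataclass(frozen=True)
class DimensionAnnotation:
    """One coder-marked interval on one dimension.

    The interval is half-open: the code applies on ``[onset_s, offset_s)``.
    Sub-code legality is enforced at construction.
    """

    dimension: str
    main_code: int
    sub_code: int | None
    onset_s: float
    offset_s: float

    def __post_init__(self):
        validate_subcode(self.dimension, self.main_code, self.sub_code)
        if not self.onset_s >= 0:
            raise ValidationError(f"onset_s must be >= 0, got {self.onset_s}")
        if not self.offset_s > self.onset_s:
            raise ValidationError(
                f"offset_s ({self.offset_s}) must exceed onset_s ({self.onset_s})"
            )


@dataclass
class CodedTimeline:
    """Gap-free per-frame codes for one participant at a fixed frame rate.

    ``main`` is an ``(n_frames, 3)`` int8 array and ``sub`` an ``(n_frames, 3)``
    int16 array, columns ordered (SE, SM, C); absent sub-codes hold
    :data:`~dyadplay.scheme.NO_SUBCODE`.
    """

    participant: str
    session_id: str
    condition: str
    fps: float
    main: np.ndarray
    sub: np.ndarray

    def __post_init__(self):
        self.main = np.asarray(self.main, dtype=np.int8)
        self.sub = np.asarray(self.sub, dtype=np.int16)
        if self.participant not in PARTICIPANTS:
            raise ValidationError(
                f"participant must be one of {PARTICIPANTS}, got {self.participant!r}"
            )
        if self.fps <= 0:
            raise ValidationError(f"fps must be positive, got {self.fps}")
        if self.main.shape != self.sub.shape or self.main.ndim != 2 or self.main.shape[1] != 3:
            raise ValidationError("main and sub must both be (n_frames, 3) arrays")

    @property
    def n_frames(self) -> int:
        return self.main.shape[0]

    @property
    def duration_s(self) -> float:
        return self.n_frames / self.fps

    def frame_onsets(self) -> np.ndarray:
        """Onset time in seconds of every frame (frame i starts at i/fps)."""
        return np.arange(self.n_frames) / self.fps

    def validate(self) -> None:
        """Check every frame's codes against the coding scheme."""
        for j, dim in enumerate(DIMENSIONS):
            for m in (0, 1):
                legal = scheme.LEGAL_SUBCODES[(dim, m)]
                sel = self.main[:, j] == m
                subs = self.sub[sel, j]
                if legal:
                    bad = ~np.isin(subs, legal)
                else:
                    bad = subs != NO_SUBCODE
                if bad.any():
                    frame = int(np.flatnonzero(sel)[bad][0])
                    raise ValidationError(
                        f"frame {frame}: sub-code {int(subs[bad][0])} illegal for "
                        f"{dim} main code {m}"
                    )
        if not np.isin(self.main, (0, 1)).all():
            raise ValidationError("main codes must be binary")

    def to_frame_table(self) -> pd.DataFrame:
        """One row per frame: frame, t_onset_s, SE, SE_sub, SM, SM_sub, C, C_sub."""
        data = {"frame": np.arange(self.n_frames), "t_onset_s": self.frame_onsets()}
        for j, dim in enumerate(DIMENSIONS):
            data[dim] = self.main[:, j]
            sub = pd.Series(self.sub[:, j], dtype="Int64")
            data[f"{dim}_sub"] = sub.mask(sub == NO_SUBCODE)
        return pd.DataFrame(data)

    def write_tsv(self, path) -> None:
        self.to_frame_table().to_csv(path, sep="\t", index=False)


@dataclass
class DyadTimeline:
    """The two aligned partner timelines of one session."""

    infant: CodedTimeline
    adult: CodedTimeline

    def __post_init__(self):
        if self.infant.fps != self.adult.fps:
            raise ValidationError(
                f"fps mismatch: infant {self.infant.fps} vs adult {self.adult.fps}"
            )
        if self.infant.n_frames != self.adult.n_frames:
            raise ValidationError(
                f"frame-count mismatch: infant {self.infant.n_frames} vs "
                f"adult {self.adult.n_frames}; align with align_dyad first"
            )
        if self.infant.session_id != self.adult.session_id:
            raise ValidationError("partner timelines belong to different sessions")
        if self.infant.condition != self.adult.condition:
            raise ValidationError("partner timelines belong to different conditions")

    @property
    def fps(self) -> float:
        return self.infant.fps

    @property
    def n_frames(self) -> int:
        return self.infant.n_frames


def read_annotations(path, dialect: AnnotationDialect | None = None
                     ) -> dict[str, list[DimensionAnnotation]]:
    """Parse an annotation table into per-participant annotation lists.

    Expects one row per coded interval with columns participant, dimension,
    main_code, sub_code (may be empty), onset_s, offset_s (names remappable
    through ``dialect``). Returns ``{participant: [DimensionAnnotation, ...]}``
    sorted by onset within (participant, dimension); sub-code legality is
    enforced row by row.
    """
    dialect = dialect or AnnotationDialect()
    df = pd.read_csv(path, sep=dialect.delimiter)
    colmap = {canonical: dialect.column(canonical) for canonical in DEFAULT_COLUMNS}
    missing = [name for name in colmap.values() if name not in df.columns]
    if missing:
        raise FormatError(f"missing required column(s): {', '.join(missing)}")
    df = df.rename(columns={v: k for k, v in colmap.items()})

    out: dict[str, list[DimensionAnnotation]] = {}
    for idx, row in df.iterrows():
        participant = str(row["participant"])
        if participant not in PARTICIPANTS:
            raise ValidationError(
                f"row {idx}: participant must be one of {PARTICIPANTS}, "
                f"got {participant!r}"
            )
        sub = row["sub_code"]
        sub = None if pd.isna(sub) else int(sub)
        try:
            ann = DimensionAnnotation(
                dimension=str(row["dimension"]),
                main_code=int(row["main_code"]),
                sub_code=sub,
                onset_s=float(row["onset_s"]),
                offset_s=float(row["offset_s"]),
            )
        except (ValidationError, ValueError) as exc:
            raise ValidationError(f"row {idx}: {exc}") from None
        out.setdefault(participant, []).append(ann)
    for participant in out:
        out[participant].sort(key=lambda a: (a.dimension, a.onset_s))
    return out


def _intervals_by_dimension(annotations) -> dict[str, list[DimensionAnnotation]]:
    by_dim: dict[str, list[DimensionAnnotation]] = {d: [] for d in DIMENSIONS}
    for ann in annotations:
        by_dim[ann.dimension].append(ann)
    for d in by_dim:
        by_dim[d].sort(key=lambda a: a.onset_s)
    return by_dim


def rasterize(annotations: list[DimensionAnnotation], fps: float, duration_s: float,
              *, participant: str = "infant", session_id: str = "session",
              condition: str = "condition",
              fill: dict[str, tuple[int, int | None]] | None = None) -> CodedTimeline:
    """Convert interval annotations to a gap-free per-frame coded timeline.

    Frame ``i`` takes the code of the interval containing its onset ``i/fps``;
    frame count is ``round(duration_s * fps)``. Within each dimension the
    intervals must be non-overlapping and (unless ``fill`` provides a default
    code for that dimension) must cover ``[0, duration_s)`` with no gaps —
    uncovered frames are a hard error because a coding gap usually means coder
    error, not genuinely missing behavior.

    ``fill`` maps a dimension to the ``(main_code, sub_code)`` used for frames
    no interval covers (for sparse coding styles).
    """
    fill = fill or {}
    n_frames = int(round(duration_s * fps))
    if n_frames <= 0:
        raise ValidationError(f"duration {duration_s}s at {fps} fps yields no frames")
    t = np.arange(n_frames) / fps

    main = np.zeros((n_frames, 3), dtype=np.int8)
    sub = np.full((n_frames, 3), NO_SUBCODE, dtype=np.int16)
    by_dim = _intervals_by_dimension(annotations)

    for j, dim in enumerate(DIMENSIONS):
        ivals = by_dim[dim]
        if not ivals and dim not in fill:
            raise ValidationError(f"dimension {dim}: no annotations and no fill policy")
        onsets = np.array([a.onset_s for a in ivals])
        offsets = np.array([a.offset_s for a in ivals])
        for k in range(len(ivals) - 1):
            if onsets[k + 1] < offsets[k] - _COVERAGE_TOL:
                raise ValidationError(
                    f"dimension {dim}: overlapping intervals "
                    f"[{onsets[k]}, {offsets[k]}) and [{onsets[k + 1]}, {offsets[k + 1]})"
                )
        if dim not in fill:
            gaps = []
            if len(ivals) and onsets[0] > _COVERAGE_TOL:
                gaps.append((0.0, float(onsets[0])))
            for k in range(len(ivals) - 1):
                if onsets[k + 1] > offsets[k] + _COVERAGE_TOL:
                    gaps.append((float(offsets[k]), float(onsets[k + 1])))
            if len(ivals) and offsets[-1] < duration_s - _COVERAGE_TOL:
                gaps.append((float(offsets[-1]), float(duration_s)))
            if gaps:
                raise ValidationError(
                    f"dimension {dim}: uncovered gap(s) with no fill policy: "
                    + ", ".join(f"[{a:g}, {b:g})" for a, b in gaps)
                )
        if len(ivals):
            # Frame i belongs to the last interval with onset <= t_i, provided
            # t_i falls before that interval's offset (half-open on both sides).
            idx = np.searchsorted(onsets, t + _COVERAGE_TOL, side="right") - 1
            inside = idx >= 0
            inside[inside] = t[inside] < offsets[idx[inside]]
        else:
            idx = np.full(n_frames, -1)
            inside = np.zeros(n_frames, dtype=bool)
        if inside.any():
            mains = np.array([a.main_code for a in ivals], dtype=np.int8)
            subs = np.array(
                [NO_SUBCODE if a.sub_code is None else a.sub_code for a in ivals],
                dtype=np.int16,
            )
            main[inside, j] = mains[idx[inside]]
            sub[inside, j] = subs[idx[inside]]
        if (~inside).any():
            fmain, fsub = fill[dim]
            validate_subcode(dim, fmain, fsub)
            main[~inside, j] = fmain
            sub[~inside, j] = NO_SUBCODE if fsub is None else fsub

    tl = CodedTimeline(participant=participant, session_id=session_id,
                       condition=condition, fps=fps, main=main, sub=sub)
    tl.validate()
    return tl


def derasterize(timeline: CodedTimeline) -> list[DimensionAnnotation]:
    """Merge equal adjacent frames back into interval annotations.

    Inverse of :func:`rasterize` for frame-aligned, gap-free annotation sets
    whose adjacent intervals carry distinct codes.
    """
    out: list[DimensionAnnotation] = []
    for j, dim in enumerate(DIMENSIONS):
        codes = timeline.main[:, j].astype(np.int64) * 1000 + timeline.sub[:, j]
        change = np.flatnonzero(np.diff(codes)) + 1
        starts = np.concatenate(([0], change))
        ends = np.concatenate((change, [timeline.n_frames]))
        for s, e in zip(starts, ends):
            sc = int(timeline.sub[s, j])
            out.append(DimensionAnnotation(
                dimension=dim,
                main_code=int(timeline.main[s, j]),
                sub_code=None if sc == NO_SUBCODE else sc,
                onset_s=s / timeline.fps,
                offset_s=e / timeline.fps,
            ))
    return out


def align_dyad(infant: CodedTimeline, adult: CodedTimeline) -> DyadTimeline:
    """Pair the two partners' timelines on a shared session clock.

    Both cameras record concurrently, so alignment only truncates the longer
    timeline to the shorter frame count — never resamples. A frame-rate
    mismatch is an error.
    """
    if infant.fps != adult.fps:
        raise ValidationError(
            f"fps mismatch: infant {infant.fps} vs adult {adult.fps}; "
            "resampling is not performed"
        )
    n = min(infant.n_frames, adult.n_frames)
    if infant.n_frames != adult.n_frames:
        logger.info(
            "truncating dyad %s to %d frames (infant %d, adult %d)",
            infant.session_id, n, infant.n_frames, adult.n_frames,
        )
        infant = replace(infant, main=infant.main[:n], sub=infant.sub[:n])
        adult = replace(adult, main=adult.main[:n], sub=adult.sub[:n])
    return DyadTimeline(infant=infant, adult=adult)


def annotations_to_table(annotations: dict[str, list[DimensionAnnotation]]) -> pd.DataFrame:
    """Render per-participant annotations as the canonical CSV table."""
    rows = []
    for participant, anns in annotations.items():
        for a in anns:
            rows.append({
                "participant": participant,
                "dimension": a.dimension,
                "main_code": a.main_code,
                "sub_code": a.sub_code,
                "onset_s": a.onset_s,
                "offset_s": a.offset_s,
            })
    df = pd.DataFrame(rows, columns=list(DEFAULT_COLUMNS))
    return df.astype({"sub_code": "Int64"}) if len(df) else df


def write_annotations(annotations: dict[str, list[DimensionAnnotation]], path,
                      dialect: AnnotationDialect | None = None) -> None:
    """Write annotations in the same dialect :func:`read_annotations` reads."""
    dialect = dialect or AnnotationDialect()
    df = annotations_to_table(annotations)
    df = df.rename(columns={c: dialect.column(c) for c in DEFAULT_COLUMNS})
    df.to_csv(path, sep=dialect.delimiter, index=False)
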