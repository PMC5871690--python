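"""Event-table export for neural time-locking.

State segments become rows of a BIDS-events-style TSV (onset, duration,
trial_type) so EEG/MEG tooling can epoch neural recordings around behavioral
states. At 30 fps frame onsets do not fall on exact millisecond boundaries
(frames are 33.3_ ms), so alongside the 3-decimal rounded seconds every row
carries exact ``frame_start``/``frame_end`` indices — re-importing through the
frame columns reconstructs the segment list exactly, preserving the frame-level
temporal precision that phase-sensitive analyses need.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .scheme import N_STATES
from .states import StateSegment
from .timeline import ValidationError

EVENT_COLUMNS = ("onset", "duration", "trial_type", "frame_start", "frame_end")


def state_label(state: int) -> str:
    return f"state_{state}"


def export_events(segments: list[StateSegment], fps: float,
                  filter_states: set[int] | None = None,
                  participant: str | None = None, session_id: str | None = None,
                  condition: str | None = None) -> pd.DataFrame:
    """Turn state segments into an event table.

    One row per (optionally state-filtered) segment, ordered by onset, with
    ``onset = start_frame / fps`` and ``duration = n_frames / fps`` in
    seconds. Optional metadata columns are appended when provided.
    """
    if filter_states is not None:
        bad = {s for s in filter_states if not 1 <= int(s) <= N_STATES}
        if bad:
            raise ValidationError(f"unknown state(s) in filter: {sorted(bad)}")
        segments = [seg for seg in segments if seg.state in filter_states]
    rows = {
        "onset": [seg.start_frame / fps for seg in segments],
        "duration": [seg.n_frames / fps for seg in segments],
        "trial_type": [state_label(seg.state) for seg in segments],
        "frame_start": [seg.start_frame for seg in segments],
        "frame_end": [seg.end_frame for seg in segments],
    }
    df = pd.DataFrame(rows, columns=list(EVENT_COLUMNS))
    for name, value in (("participant", participant), ("session_id", session_id),
                        ("condition", condition)):
        if value is not None:
            df[name] = value
    return df.sort_values("onset", kind="stable").reset_index(drop=True)


def write_events(df: pd.DataFrame, path) -> None:
    """Write an event table as TSV with onset/duration at 3 decimal places."""
    out = df.copy()
    for col in ("onset", "duration"):
        out[col] = out[col].map(lambda v: f"{v:.3f}")
    out.to_csv(path, sep="\t", index=False)


def read_events(path, fps: float) -> tuple[list[StateSegment], pd.DataFrame]:
    """Read an event TSV back into segments (via the exact frame columns)."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in EVENT_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"event table missing column(s): {', '.join(missing)}")
    segments = [
        StateSegment(
            state=int(str(row.trial_type).rsplit("_", 1)[-1]),
            start_frame=int(row.frame_start),
            end_frame=int(row.frame_end),
        )
        for row in df.itertuples()
    ]
    # sanity: rounded onsets agree with frame arithmetic to file precision
    onsets = np.array([s.start_frame / fps for s in segments])
    if len(onsets) and np.abs(onsets - df["onset"].to_numpy(float)).max() > 5e-4 + 1e-9:
        raise ValidationError("event onsets disagree with frame_start/fps")
    return segments, df
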