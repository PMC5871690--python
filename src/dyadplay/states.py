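"""Social states: per-frame derivation, segments, dimensional scores,
frequency distributions, and modal states.

A participant's *social state* at a frame is a deterministic function of the
three main codes at that frame — one of 8 states, with state 1 (``[1 1 1]``)
the play-congruent state. No smoothing or latent-state inference is applied.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import scheme
from .scheme import DIM_INDEX, DIMENSIONS, N_STATES
from .timeline import CodedTimeline, ValidationError


@dataclass
class SocialStateSequence:
    """Per-frame social-state indices (1..8) at a fixed frame rate."""

    fps: float
    states: np.ndarray
    participant: str = ""
    session_id: str = ""
    condition: str = ""

    def __post_init__(self):
        self.states = np.asarray(self.states, dtype=np.int64)
        if self.states.ndim != 1:
            raise ValidationError("states must be a 1-d array")
        if len(self.states) and not np.isin(self.states, np.arange(1, 9)).all():
            raise ValidationError("state indices must lie in 1..8")

    @property
    def n_frames(self) -> int:
        return len(self.states)

    def to_frame_table(self) -> pd.DataFrame:
        """frame, t_onset_s, state_index, SE, SM, C — one row per frame."""
        main = scheme.code_array_from_states(self.states)
        return pd.DataFrame({
            "frame": np.arange(self.n_frames),
            "t_onset_s": np.arange(self.n_frames) / self.fps,
            "state_index": self.states,
            "SE": main[:, 0],
            "SM": main[:, 1],
            "C": main[:, 2],
        })


@dataclass(frozen=True)
class StateSegment:
    """Maximal run of one state over half-open frame bounds
    ``[start_frame, end_frame)``."""

    state: int
    start_frame: int
    end_frame: int

    def __post_init__(self):
        if self.end_frame <= self.start_frame:
            raise ValidationError("end_frame must exceed start_frame")

    @property
    def n_frames(self) -> int:
        return self.end_frame - self.start_frame


@dataclass(frozen=True)
class DimensionalSummary:
    """Session-mean main code per dimension, each in [0, 1].

    A mean of e.g. 0.7 on SM means the participant had active possession of
    the object 70% of the session.
    """

    mean_SE: float
    mean_SM: float
    mean_C: float

    def as_dict(self) -> dict[str, float]:
        return {"SE": self.mean_SE, "SM": self.mean_SM, "C": self.mean_C}


@dataclass
class StateFrequency:
    """Proportion of frames spent in each of the 8 states (sums to 1)."""

    freq: np.ndarray

    def __post_init__(self):
        self.freq = np.asarray(self.freq, dtype=float)
        if self.freq.shape != (N_STATES,):
            raise ValidationError(f"freq must have shape ({N_STATES},)")
        if (self.freq < 0).any() or abs(self.freq.sum() - 1.0) > 1e-12:
            raise ValidationError("freq entries must be non-negative and sum to 1")

    def __getitem__(self, state: int) -> float:
        """Frequency of a state by its 1-based index."""
        if not 1 <= state <= N_STATES:
            raise IndexError(f"state index must be 1..{N_STATES}")
        return float(self.freq[state - 1])


def derive_states(timeline: CodedTimeline) -> SocialStateSequence:
    """Map each frame's (SE, SM, C) main codes to its social-state index.

    Sub-codes are ignored: the taxonomy lives entirely on the main codes.
    """
    return SocialStateSequence(
        fps=timeline.fps,
        states=scheme.states_from_code_array(timeline.main),
        participant=timeline.participant,
        session_id=timeline.session_id,
        condition=timeline.condition,
    )


def _run_length_encode(states: np.ndarray) -> list[StateSegment]:
    change = np.flatnonzero(np.diff(states)) + 1
    starts = np.concatenate(([0], change))
    ends = np.concatenate((change, [len(states)]))
    return [StateSegment(int(states[s]), int(s), int(e)) for s, e in zip(starts, ends)]


def segment_states(seq: SocialStateSequence, min_duration_frames: int = 1
                   ) -> list[StateSegment]:
    """Partition the sequence into maximal same-state segments.

    With ``min_duration_frames=1`` this is the exact run-length encoding.
    With a larger minimum, runs shorter than the minimum are absorbed into the
    longer adjacent run (ties go to the preceding run) and adjacent equal
    segments re-merged, repeating until every segment meets the minimum or a
    single segment remains. Shortest runs are absorbed first (ties: earliest).
    """
    if seq.n_frames == 0:
        raise ValidationError("cannot segment an empty sequence")
    if min_duration_frames < 1:
        raise ValidationError("min_duration_frames must be >= 1")

    runs = [[s.state, s.start_frame, s.end_frame] for s in _run_length_encode(seq.states)]
    while len(runs) > 1:
        lengths = [e - s for _, s, e in runs]
        short = [i for i, L in enumerate(lengths) if L < min_duration_frames]
        if not short:
            break
        i = min(short, key=lambda k: lengths[k])
        if i == 0:
            absorber = 1
        elif i == len(runs) - 1:
            absorber = i - 1
        else:
            # absorb into the longer neighbor; tie -> preceding run
            absorber = i - 1 if lengths[i - 1] >= lengths[i + 1] else i + 1
        runs[absorber][1] = min(runs[absorber][1], runs[i][1])
        runs[absorber][2] = max(runs[absorber][2], runs[i][2])
        del runs[i]
        # re-merge adjacent equal-state runs
        merged = [runs[0]]
        for r in runs[1:]:
            if r[0] == merged[-1][0]:
                merged[-1][2] = r[2]
            else:
                merged.append(r)
        runs = merged
    return [StateSegment(st, s, e) for st, s, e in runs]


def dimensional_means(timeline: CodedTimeline) -> DimensionalSummary:
    """Average each dimension's main code over all frames of the session."""
    if timeline.n_frames == 0:
        raise ValidationError("cannot summarize an empty timeline")
    m = timeline.main.mean(axis=0)
    return DimensionalSummary(
        mean_SE=float(m[DIM_INDEX["SE"]]),
        mean_SM=float(m[DIM_INDEX["SM"]]),
        mean_C=float(m[DIM_INDEX["C"]]),
    )


def state_frequencies(seq: SocialStateSequence) -> StateFrequency:
    """Proportion of frames spent in each state."""
    if seq.n_frames == 0:
        raise ValidationError("cannot compute frequencies of an empty sequence")
    counts = np.bincount(seq.states, minlength=N_STATES + 1)[1:]
    return StateFrequency(freq=counts / seq.n_frames)


def modal_state(freq: StateFrequency) -> tuple[int, bool]:
    """Most frequently occupied state.

    Returns ``(state_index, tied)``; on a tie the lowest state index is
    reported and ``tied`` is True, so ambiguous modes are surfaced rather
    than silently resolved.
    """
    best = float(freq.freq.max())
    winners = np.flatnonzero(freq.freq == best) + 1
    return int(winners[0]), len(winners) > 1


def subcode_counts(timeline: CodedTimeline) -> pd.DataFrame:
    """Convenience tally of sub-code usage per (dimension, main code).

    Sub-codes are stored and validated but never enter state derivation;
    this is descriptive output only.
    """
    rows = []
    for j, dim in enumerate(DIMENSIONS):
        for m in (0, 1):
            legal = scheme.LEGAL_SUBCODES[(dim, m)]
            sel = timeline.main[:, j] == m
            for sc in legal:
                rows.append({
                    "dimension": dim, "main_code": m, "sub_code": sc,
                    "n_frames": int((timeline.sub[sel, j] == sc).sum()),
                })
    return pd.DataFrame(rows)


def session_summary(timeline: CodedTimeline) -> dict:
    """Machine-readable per-session summary: dimensional means, state
    frequencies, modal state and tie flag, plus session metadata."""
    seq = derive_states(timeline)
    freq = state_frequencies(seq)
    mode, tied = modal_state(freq)
    means = dimensional_means(timeline)
    return {
        "participant": timeline.participant,
        "session_id": timeline.session_id,
        "condition": timeline.condition,
        "fps": timeline.fps,
        "n_frames": timeline.n_frames,
        "duration_s": timeline.duration_s,
        "dimensional_means": means.as_dict(),
        "state_frequencies": freq.freq.tolist(),
        "modal_state": mode,
        "modal_state_codes": list(scheme.codes_from_state(mode)),
        "modal_state_tied": tied,
    }
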