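"""Inter-rater reliability between two coders' frame-level timelines.

Agreement is computed frame-wise on the main codes (the coding unit is the
frame), over the frame range both coders covered. Percent agreement is the
primary figure; Cohen's kappa is provided as a chance-corrected supplement
and flagged undefined when either coder is constant.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .scheme import DIM_INDEX, DIMENSIONS
from .timeline import CodedTimeline, ValidationError


@dataclass(frozen=True)
class AgreementReport:
    """Per-dimension agreement between two coders on one participant's video."""

    percent: dict[str, float]        # 0–100 per dimension, main codes
    kappa: dict[str, float | None]   # None where undefined (a coder is constant)
    n_frames: int
    sub_percent: dict[str, float] | None = None  # optional sub-code agreement

    def as_dict(self) -> dict:
        out = {
            "n_frames": self.n_frames,
            "percent_agreement": dict(self.percent),
            "kappa": dict(self.kappa),
        }
        if self.sub_percent is not None:
            out["subcode_percent_agreement"] = dict(self.sub_percent)
        return out


def _overlap(a: CodedTimeline, b: CodedTimeline) -> int:
    if a.fps != b.fps:
        raise ValidationError(f"fps mismatch: {a.fps} vs {b.fps}")
    n = min(a.n_frames, b.n_frames)
    if n == 0:
        raise ValidationError("coders share no overlapping frames")
    return n


def percent_agreement(a: CodedTimeline, b: CodedTimeline, dimension: str) -> float:
    """Percentage of overlapping frames on which the two coders assigned the
    same main code on ``dimension`` (0–100)."""
    j = DIM_INDEX[dimension]
    n = _overlap(a, b)
    return 100.0 * float((a.main[:n, j] == b.main[:n, j]).mean())


def kappa(a: CodedTimeline, b: CodedTimeline, dimension: str) -> float | None:
    """Cohen's kappa on the binary main codes of ``dimension``.

    Computed from the 2x2 confusion table: kappa = (p_o - p_e) / (1 - p_e)
    with observed agreement p_o and chance agreement p_e from the coders'
    marginal code rates. Returns ``None`` (undefined) when either coder uses
    a single code throughout, since chance agreement is then 1.
    """
    j = DIM_INDEX[dimension]
    n = _overlap(a, b)
    x, y = a.main[:n, j], b.main[:n, j]
    if len(np.unique(x)) < 2 or len(np.unique(y)) < 2:
        return None
    p_o = float((x == y).mean())
    px1, py1 = float(x.mean()), float(y.mean())
    p_e = px1 * py1 + (1 - px1) * (1 - py1)
    return (p_o - p_e) / (1 - p_e)


def subcode_agreement(a: CodedTimeline, b: CodedTimeline, dimension: str) -> float:
    """Percent agreement on the full (main, sub) pair — stricter than the
    main-code figure; off by default in reports."""
    j = DIM_INDEX[dimension]
    n = _overlap(a, b)
    same = (a.main[:n, j] == b.main[:n, j]) & (a.sub[:n, j] == b.sub[:n, j])
    return 100.0 * float(same.mean())


def agreement_report(a: CodedTimeline, b: CodedTimeline,
                     include_subcodes: bool = False) -> AgreementReport:
    """Full per-dimension agreement report over the coders' shared frames."""
    n = _overlap(a, b)
    return AgreementReport(
        percent={d: percent_agreement(a, b, d) for d in DIMENSIONS},
        kappa={d: kappa(a, b, d) for d in DIMENSIONS},
        n_frames=n,
        sub_percent=(
            {d: subcode_agreement(a, b, d) for d in DIMENSIONS}
            if include_subcodes else None
        ),
    )
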