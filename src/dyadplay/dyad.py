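"""Dyadic analysis: joint states, synchrony, and condition comparison.

The *joint state* of a dyad at a frame is the ordered pair (infant state,
adult state) — 64 possibilities. *Synchronous play* is the proportion of
frames with both partners concurrently in the play-congruent state
``[1 1 1]``, i.e. joint state (1, 1).

Condition comparison follows the study design this framework serves: per
social state, a paired t-test on each dyad's state *frequency* (proportion of
session time, so sessions of unequal length stay comparable) between two
conditions, Benjamini–Hochberg FDR correction across the 8 states within one
participant group, and the paired-design effect size d_z = t / sqrt(n). The
comparison is exposed as a model/results pair: build a
:class:`StateFrequencyComparison` from per-dyad frequencies, call ``fit()``,
and read the estimates off the returned :class:`ComparisonResult` (or print
``.summary()``).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .scheme import DIM_INDEX, N_STATES, PLAY_STATE, STATE_CODES
from .states import StateFrequency, derive_states
from .timeline import DyadTimeline, ValidationError


@dataclass
class JointStateSequence:
    """Per-frame (infant state, adult state) pairs for one aligned dyad."""

    fps: float
    infant_states: np.ndarray
    adult_states: np.ndarray
    session_id: str = ""
    condition: str = ""
    # main-code arrays are kept so dimension-wise concordance can be computed
    infant_main: np.ndarray | None = None
    adult_main: np.ndarray | None = None

    def __post_init__(self):
        self.infant_states = np.asarray(self.infant_states, dtype=np.int64)
        self.adult_states = np.asarray(self.adult_states, dtype=np.int64)
        if self.infant_states.shape != self.adult_states.shape:
            raise ValidationError("partner state sequences have different lengths")

    @property
    def n_frames(self) -> int:
        return len(self.infant_states)

    def pairs(self) -> np.ndarray:
        return np.column_stack([self.infant_states, self.adult_states])


@dataclass
class JointDistribution:
    """8x8 joint probability matrix; rows = infant state, columns = adult."""

    p: np.ndarray

    def __post_init__(self):
        self.p = np.asarray(self.p, dtype=float)
        if self.p.shape != (N_STATES, N_STATES):
            raise ValidationError("joint distribution must be 8x8")
        if (self.p < 0).any() or abs(self.p.sum() - 1.0) > 1e-12:
            raise ValidationError("joint probabilities must be non-negative and sum to 1")

    @property
    def infant_marginal(self) -> StateFrequency:
        return StateFrequency(self.p.sum(axis=1))

    @property
    def adult_marginal(self) -> StateFrequency:
        return StateFrequency(self.p.sum(axis=0))

    def to_frame(self) -> pd.DataFrame:
        labels_i = [f"infant_{s}" for s in range(1, N_STATES + 1)]
        labels_a = [f"adult_{s}" for s in range(1, N_STATES + 1)]
        return pd.DataFrame(self.p, index=labels_i, columns=labels_a)


@dataclass(frozen=True)
class SynchronyReport:
    """Frame-wise synchrony measures for one dyad.

    ``p_joint_play`` — proportion of frames with both partners in state 1
    (synchronous play); ``p_same_state`` — proportion with identical state
    indices; ``dimension_concordance`` — per-dimension proportion of frames
    with equal main codes.
    """

    p_joint_play: float
    p_same_state: float
    dimension_concordance: dict[str, float]

    def as_dict(self) -> dict:
        return {
            "p_joint_play": self.p_joint_play,
            "p_same_state": self.p_same_state,
            "dimension_concordance": dict(self.dimension_concordance),
        }


def joint_states(dyad: DyadTimeline) -> JointStateSequence:
    """Pair the two partners' derived state sequences frame by frame."""
    if dyad.n_frames == 0:
        raise ValidationError("cannot derive joint states of an empty dyad")
    inf = derive_states(dyad.infant)
    adu = derive_states(dyad.adult)
    return JointStateSequence(
        fps=dyad.fps,
        infant_states=inf.states,
        adult_states=adu.states,
        session_id=dyad.infant.session_id,
        condition=dyad.infant.condition,
        infant_main=dyad.infant.main,
        adult_main=dyad.adult.main,
    )


def joint_distribution(jseq: JointStateSequence) -> JointDistribution:
    """Empirical joint probability of (infant state, adult state).

    By construction the row sums equal the infant's state frequencies and the
    column sums the adult's.
    """
    if jseq.n_frames == 0:
        raise ValidationError("cannot compute a joint distribution of an empty sequence")
    counts = np.zeros((N_STATES, N_STATES))
    np.add.at(counts, (jseq.infant_states - 1, jseq.adult_states - 1), 1.0)
    return JointDistribution(counts / jseq.n_frames)


def synchrony(jseq: JointStateSequence) -> SynchronyReport:
    """Synchrony measures of one dyad's joint state sequence."""
    if jseq.n_frames == 0:
        raise ValidationError("cannot compute synchrony of an empty sequence")
    jd = joint_distribution(jseq)
    p_joint_play = float(jd.p[PLAY_STATE - 1, PLAY_STATE - 1])
    p_same = float(np.trace(jd.p))
    concordance = {}
    if jseq.infant_main is not None and jseq.adult_main is not None:
        for dim, j in DIM_INDEX.items():
            concordance[dim] = float(
                (jseq.infant_main[:, j] == jseq.adult_main[:, j]).mean()
            )
    return SynchronyReport(
        p_joint_play=p_joint_play,
        p_same_state=p_same,
        dimension_concordance=concordance,
    )


def bh_fdr(p_values, alpha: float = 0.05) -> tuple[np.ndarray, np.ndarray]:
    """Benjamini–Hochberg step-up FDR correction.

    Implemented from the step-up definition: with the m raw p-values sorted
    ascending, the adjusted value at rank k is
    ``min_{j >= k} min(1, m * p_(j) / j)``; hypotheses with adjusted p <= alpha
    are rejected. Returns ``(adjusted_p, rejected)`` in the input order.
    """
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1 or len(p) == 0:
        raise ValidationError("p_values must be a non-empty 1-d sequence")
    if (p < 0).any() or (p > 1).any():
        raise ValidationError("p-values must lie in [0, 1]")
    m = len(p)
    order = np.argsort(p, kind="stable")
    scaled = p[order] * m / np.arange(1, m + 1)
    adjusted_sorted = np.minimum(1.0, np.minimum.accumulate(scaled[::-1])[::-1])
    adjusted = np.empty(m)
    adjusted[order] = adjusted_sorted
    return adjusted, adjusted <= alpha


def cohens_dz(t_statistic, n: int):
    """Paired-design Cohen's d (d_z = t / sqrt(n)) from a paired t statistic
    computed over n difference scores."""
    if n < 1:
        raise ValidationError("n must be >= 1")
    return np.asarray(t_statistic, dtype=float) / np.sqrt(n)


class StateFrequencyComparison:
    """Paired comparison of per-state frequencies between two conditions.

    The model holds one participant group's per-dyad state-frequency vectors
    under each condition (an ``(n_dyads, 8)`` array per condition, rows
    paired by dyad). ``fit()`` runs, for every social state, a two-sided
    paired t-test on condition-2 minus condition-1 frequencies, corrects the
    8 p-values by Benjamini–Hochberg FDR, and attaches the paired-design
    effect size d_z = t/sqrt(n).

    Parameters
    ----------
    freq_condition1, freq_condition2 : array-like, shape (n_dyads, 8)
        State-frequency vectors (proportions) per dyad, rows aligned.
    group : str
        Participant group label (e.g. ``"infant"`` or ``"adult"``).
    alpha : float
        FDR level.
    """

    def __init__(self, freq_condition1, freq_condition2, group: str = "",
                 alpha: float = 0.05):
        f1 = np.atleast_2d(np.asarray(freq_condition1, dtype=float))
        f2 = np.atleast_2d(np.asarray(freq_condition2, dtype=float))
        if f1.shape != f2.shape or f1.shape[1] != N_STATES:
            raise ValidationError(
                f"both conditions need matching (n_dyads, {N_STATES}) frequency arrays"
            )
        if f1.shape[0] < 2:
            raise ValidationError("need at least 2 dyads for a paired comparison")
        if not (0 < alpha < 1):
            raise ValidationError("alpha must lie in (0, 1)")
        self.freq_condition1 = f1
        self.freq_condition2 = f2
        self.group = group
        self.alpha = alpha
        self.n_dyads = f1.shape[0]

    @classmethod
    def from_frequencies(cls, freqs_by_dyad_condition: dict, *, group: str = "",
                         alpha: float = 0.05,
                         conditions: tuple[str, str] | None = None):
        """Build from ``{dyad_id: {condition: StateFrequency | 8-vector}}``.

        Every dyad must have both conditions; ``conditions`` fixes which label
        is condition 1 vs 2 (default: sorted order of the labels found).
        """
        if conditions is None:
            labels = sorted({c for d in freqs_by_dyad_condition.values() for c in d})
            if len(labels) != 2:
                raise ValidationError(
                    f"expected exactly 2 conditions, found {labels}"
                )
            conditions = (labels[0], labels[1])
        rows1, rows2 = [], []
        for dyad_id in sorted(freqs_by_dyad_condition):
            per_cond = freqs_by_dyad_condition[dyad_id]
            for c in conditions:
                if c not in per_cond:
                    raise ValidationError(
                        f"dyad {dyad_id!r} is missing condition {c!r}"
                    )
            def vec(v):
                return v.freq if isinstance(v, StateFrequency) else np.asarray(v, float)
            rows1.append(vec(per_cond[conditions[0]]))
            rows2.append(vec(per_cond[conditions[1]]))
        model = cls(np.array(rows1), np.array(rows2), group=group, alpha=alpha)
        model.condition_labels = conditions
        return model

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, *, dyad_col: str = "dyad",
                       condition_col: str = "condition", state_col: str = "state",
                       freq_col: str = "frequency", group: str = "",
                       alpha: float = 0.05,
                       conditions: tuple[str, str] | None = None):
        """Build from a long table with one row per (dyad, condition, state)."""
        nested: dict = {}
        for (dyad, cond), sub in df.groupby([dyad_col, condition_col]):
            vec = np.zeros(N_STATES)
            vec[sub[state_col].to_numpy(dtype=int) - 1] = sub[freq_col].to_numpy(float)
            nested.setdefault(dyad, {})[cond] = vec
        return cls.from_frequencies(nested, group=group, alpha=alpha,
                                    conditions=conditions)

    def fit(self) -> "ComparisonResult":
        """Run the per-state paired t-tests with BH-FDR correction."""
        diff = self.freq_condition2 - self.freq_condition1
        n = self.n_dyads
        res = stats.ttest_rel(self.freq_condition2, self.freq_condition1, axis=0)
        t = np.asarray(res.statistic, dtype=float)
        p_raw = np.asarray(res.pvalue, dtype=float)
        # a state absent from every session in both conditions has zero
        # variance and zero mean difference: report t = 0, p = 1
        degenerate = ~np.isfinite(t)
        t[degenerate & np.isclose(diff.mean(axis=0), 0.0)] = 0.0
        p_raw[degenerate & np.isclose(diff.mean(axis=0), 0.0)] = 1.0
        p_fdr, rejected = bh_fdr(p_raw, alpha=self.alpha)
        return ComparisonResult(
            group=self.group,
            n=n,
            df=n - 1,
            alpha=self.alpha,
            mean_difference=diff.mean(axis=0),
            t_statistics=t,
            p_raw=p_raw,
            p_bh_fdr=p_fdr,
            effect_sizes=cohens_dz(t, n),
            rejected=rejected,
        )


@dataclass
class ComparisonResult:
    """Per-state paired-test results for one participant group.

    All per-state arrays are ordered by state index 1..8. Effect sizes use
    the paired-design convention d_z = t/sqrt(n), so sign(d) = sign(t).
    """

    group: str
    n: int
    df: int
    alpha: float
    mean_difference: np.ndarray
    t_statistics: np.ndarray
    p_raw: np.ndarray
    p_bh_fdr: np.ndarray
    effect_sizes: np.ndarray
    rejected: np.ndarray
    condition_labels: tuple[str, str] = ("condition1", "condition2")

    def to_frame(self) -> pd.DataFrame:
        codes = [" ".join(map(str, STATE_CODES[s])) for s in range(1, N_STATES + 1)]
        return pd.DataFrame({
            "state": np.arange(1, N_STATES + 1),
            "codes": codes,
            "mean_diff": self.mean_difference,
            "t": self.t_statistics,
            "df": self.df,
            "p_raw": self.p_raw,
            "p_fdr": self.p_bh_fdr,
            "d": self.effect_sizes,
            "significant": self.rejected,
            "n": self.n,
        })

    def summary(self) -> str:
        """Human-readable results table."""
        header = (
            f"Paired comparison of social-state frequencies"
            + (f" — {self.group}" if self.group else "")
            + f"\n{self.condition_labels[1]} minus {self.condition_labels[0]}, "
            f"n = {self.n} dyads, df = {self.df}, "
            f"BH-FDR alpha = {self.alpha:g}, d_z = t/sqrt(n)\n"
        )
        table = self.to_frame().drop(columns="n")
        with pd.option_context("display.float_format", lambda v: f"{v: .4f}"):
            body = table.to_string(index=False)
        return header + body


def compare_conditions(freqs_by_dyad_condition: dict, alpha: float = 0.05,
                       group: str = "",
                       conditions: tuple[str, str] | None = None) -> ComparisonResult:
    """Functional surface over :class:`StateFrequencyComparison`.

    Takes ``{dyad_id: {condition: StateFrequency}}`` for one participant
    group and returns the fitted :class:`ComparisonResult`.
    """
    model = StateFrequencyComparison.from_frequencies(
        freqs_by_dyad_condition, group=group, alpha=alpha, conditions=conditions
    )
    result = model.fit()
    if hasattr(model, "condition_labels"):
        result.condition_labels = model.condition_labels
    return result
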