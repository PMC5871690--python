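import numpy as np
import pytest

from dyadplay import scheme
from dyadplay.timeline import CodedTimeline


def make_timeline(main, sub=None, *, participant="infant", fps=30.0,
                  session_id="s1", condition="c1") -> CodedTimeline:
    """Build a CodedTimeline from an (n, 3) main-code array, filling legal
    sub-codes where required."""
    main = np.asarray(main, dtype=np.int8)
    if sub is None:
        sub = np.full(main.shape, scheme.NO_SUBCODE, dtype=np.int16)
        for j, dim in enumerate(scheme.DIMENSIONS):
            for m in (0, 1):
                legal = scheme.LEGAL_SUBCODES[(dim, m)]
                if legal:
                    sub[main[:, j] == m, j] = legal[0]
    return CodedTimeline(participant=participant, session_id=session_id,
                         condition=condition, fps=fps, main=main, sub=sub)


def random_timeline(rng: np.random.Generator, n_frames: int, **kwargs) -> CodedTimeline:
    """Random legal timeline: binary main codes, sub-codes uniform over the
    legal set for each (dimension, main code)."""
    main = rng.integers(0, 2, size=(n_frames, 3)).astype(np.int8)
    tl = make_timeline(main, **kwargs)
    for j, dim in enumerate(scheme.DIMENSIONS):
        for m in (0, 1):
            legal = scheme.LEGAL_SUBCODES[(dim, m)]
            if legal:
                sel = main[:, j] == m
                tl.sub[sel, j] = rng.choice(legal, size=int(sel.sum()))
    return tl


@pytest.fixture
def rng():
    return np.random.default_rng(20260920)
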