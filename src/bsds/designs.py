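"""Block designs: condition intervals in seconds mapped to frame masks.

A :class:`BlockDesign` describes a task paradigm as a list of
non-overlapping ``(onset_s, duration_s, condition)`` intervals plus a
sampling interval (TR).  Frames not covered by any interval are assigned a
designated rest label.  Frame mapping is 0-based with half-open intervals
``[floor(onset/tr), floor((onset+duration)/tr))`` so that every frame maps
to exactly one condition.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = ["BlockDesign", "make_block_design", "DESIGN_PRESETS"]

REST_LABEL = "rest"


class DesignError(ValueError):
    """Invalid block-design specification."""


@dataclass(frozen=True)
class BlockDesign:
    """Task paradigm as labeled time intervals on a fixed sampling grid.

    Parameters
    ----------
    intervals
        ``(onset_s, duration_s, condition)`` tuples, in seconds.
    tr
        Sampling interval in seconds (must be positive).
    n_frames
        Number of frames in the series the design applies to.  Defaults to
        the smallest grid covering the last interval.
    rest_label
        Condition assigned to frames outside every interval.
    """

    intervals: tuple[tuple[float, float, str], ...]
    tr: float
    n_frames: int
    rest_label: str = REST_LABEL
    conditions: tuple[str, ...] = field(init=False)

    def __post_init__(self) -> None:
        if self.tr <= 0:
            raise DesignError(f"tr must be positive, got {self.tr}")
        if self.n_frames < 1:
            raise DesignError("n_frames must be >= 1")
        ivs = sorted(self.intervals, key=lambda iv: iv[0])
        for onset, dur, _ in ivs:
            if onset < 0:
                raise DesignError(f"negative onset {onset}")
            if dur <= 0:
                raise DesignError(f"non-positive duration {dur}")
        for (o1, d1, c1), (o2, _, c2) in zip(ivs, ivs[1:]):
            if o1 + d1 > o2 + 1e-9:
                raise DesignError(
                    f"overlapping intervals: ({o1}, {d1}, {c1!r}) and onset {o2} ({c2!r})"
                )
        object.__setattr__(self, "intervals", tuple(ivs))
        seen: dict[str, None] = {}
        for _, _, c in ivs:
            seen.setdefault(c, None)
        conds = list(seen)
        if self.rest_label not in conds and self._has_gaps():
            conds.append(self.rest_label)
        object.__setattr__(self, "conditions", tuple(conds))

    def _has_gaps(self) -> bool:
        covered = 0
        for onset, dur, _ in self.intervals:
            a = math.floor(onset / self.tr)
            b = math.floor((onset + dur) / self.tr)
            covered += max(0, min(b, self.n_frames) - min(a, self.n_frames))
        return covered < self.n_frames

    @property
    def duration_s(self) -> float:
        return self.n_frames * self.tr

    def frame_labels(self) -> np.ndarray:
        """Per-frame condition labels (length ``n_frames``, dtype object)."""
        labels = np.full(self.n_frames, self.rest_label, dtype=object)
        for onset, dur, cond in self.intervals:
            a = math.floor(onset / self.tr)
            b = math.floor((onset + dur) / self.tr)
            labels[a : min(b, self.n_frames)] = cond
        return labels

    def condition_mask(self, condition: str) -> np.ndarray:
        """Boolean frame mask for one condition."""
        return self.frame_labels() == condition

    def onsets(self, condition: str | None = None) -> np.ndarray:
        """Interval onsets in seconds, optionally restricted to one condition."""
        return np.array(
            [o for o, _, c in self.intervals if condition is None or c == condition]
        )


def _cycle_design(
    n_cycles: int,
    off_s: float,
    on_s: float,
    on_labels: list[str],
    tr: float,
    off_first: bool = True,
) -> BlockDesign:
    intervals = []
    t = 0.0
    for i in range(n_cycles):
        if off_first:
            t += off_s
        on_label = on_labels[i % len(on_labels)]
        intervals.append((t, on_s, on_label))
        t += on_s
        if not off_first:
            t += off_s
    total = n_cycles * (off_s + on_s)
    return BlockDesign(
        intervals=tuple(intervals),
        tr=tr,
        n_frames=int(total / tr + 1e-9),
        rest_label="off",
    )


def _hcp_wm_design(tr: float) -> BlockDesign:
    # Two n-back task blocks (2.5 s cue + 25 s of trials each) followed by a
    # 15 s fixation block, repeated four times: 8 task + 4 fixation blocks.
    intervals = []
    t = 0.0
    order = ["0back", "2back", "2back", "0back", "0back", "2back", "2back", "0back"]
    bi = 0
    for _ in range(4):
        for _ in range(2):
            intervals.append((t, 27.5, order[bi]))
            t += 27.5
            bi += 1
        intervals.append((t, 15.0, "fixation"))
        t += 15.0
    return BlockDesign(
        intervals=tuple(intervals),
        tr=tr,
        n_frames=int(t / tr + 1e-9),
        rest_label="fixation",
    )


DESIGN_PRESETS = {
    # Five 60 s ON/OFF cycles, 40 s off then 20 s on.
    "tvb": lambda tr: _cycle_design(5, 40.0, 20.0, ["on"], tr),
    # Twenty trials of 40 s off and 20 s on, alternating two ON regimes,
    # 1200 s total.
    "nengo": lambda tr: _cycle_design(20, 40.0, 20.0, ["on1", "on2"], tr),
    # Eight 27.5 s n-back task blocks and four 15 s fixation blocks.
    "hcp_wm": _hcp_wm_design,
}


def make_block_design(
    spec: str | list[tuple[float, float, str]],
    tr: float,
    n_frames: int | None = None,
    rest_label: str = REST_LABEL,
) -> BlockDesign:
    """Build a :class:`BlockDesign` from a named preset or explicit intervals.

    Presets: ``"tvb"`` (five 60 s ON/OFF cycles, 20 s ON), ``"nengo"``
    (20 trials of 40 s OFF / 20 s ON alternating two ON regimes, 1200 s),
    ``"hcp_wm"`` (8 n-back task blocks + 4 fixation blocks).
    """
    if tr <= 0:
        raise DesignError(f"tr must be positive, got {tr}")
    if isinstance(spec, str):
        try:
            design = DESIGN_PRESETS[spec](tr)
        except KeyError:
            raise DesignError(
                f"unknown preset {spec!r}; available: {sorted(DESIGN_PRESETS)}"
            ) from None
        if n_frames is not None:
            design = BlockDesign(
                design.intervals, tr, n_frames, rest_label=design.rest_label
            )
        return design
    intervals = tuple((float(o), float(d), str(c)) for o, d, c in spec)
    if n_frames is None:
        n_frames = max(math.floor((o + d) / tr) for o, d, _ in intervals)
    return BlockDesign(intervals, tr, n_frames, rest_label=rest_label)
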