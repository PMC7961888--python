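"""Antagonist-ratio biofeedback: the extensor ratio and the game engines.

The control signal for both games is the *extensor ratio*

    ER = extensor / (extensor + flexor)

computed from the mean normalized activity of the two antagonists over a
trial window.  ER near 1 means individuated extension, near 0.5 strong
co-contraction, near 0 individuated flexion.

*SkeeBall* awards points per trial by binning ER and sampling from a
per-bin outcome distribution (the default table rewards higher
individuation with higher expected score).  *Blinko* maps ER to the start
slot of a chip on a pegged board and drops it through a symmetric random
walk with reflecting walls.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ProtocolError, ScoreTableError
from .pipeline import Envelope

#: Below this summed mean activity the ratio denominator is considered zero.
DENOM_FLOOR = 1e-6


def extensor_ratio(ext_mean: float, flex_mean: float, floor: float = DENOM_FLOOR) -> float:
    """``ext / (ext + flex)`` with a degenerate rule for a near-zero denominator.

    When ``ext_mean + flex_mean < floor`` no activity was recorded; the
    ratio is undefined and reported as 0.5 (indistinguishable from perfect
    co-activation).  Use :func:`is_degenerate` to detect this case.
    """
    if ext_mean < 0 or flex_mean < 0:
        raise ValueError("mean activities must be nonnegative")
    total = ext_mean + flex_mean
    if total < floor:
        return 0.5
    return ext_mean / total


def is_degenerate(ext_mean: float, flex_mean: float, floor: float = DENOM_FLOOR) -> bool:
    """True when the summed activity is below the denominator floor."""
    return ext_mean + flex_mean < floor


def trial_er(
    env: Envelope,
    onset_s: float,
    window_s: float = 2.0,
    ext_channel: str = "extensor",
    flex_channel: str = "flexor",
) -> tuple[float, float, float]:
    """Mean activities over ``[onset, onset + window)`` and their extensor ratio.

    Returns ``(er, ext_mean, flex_mean)``.
    """
    i0 = int(round(onset_s * env.fs_hz))
    i1 = int(round((onset_s + window_s) * env.fs_hz))
    if i0 < 0 or i1 > env.n_samples or i1 <= i0:
        raise ProtocolError(
            f"trial window [{onset_s}, {onset_s + window_s}) s outside the "
            f"{env.n_samples / env.fs_hz:.3f} s envelope"
        )
    ext_mean = float(env.channel(ext_channel)[i0:i1].mean())
    flex_mean = float(env.channel(flex_channel)[i0:i1].mean())
    return extensor_ratio(ext_mean, flex_mean), ext_mean, flex_mean


@dataclass(frozen=True)
class ScoreBin:
    """One ER bin: ``er_low < ER <= er_high`` with an outcome distribution."""

    er_low: float
    er_high: float
    outcomes: tuple[tuple[int, float], ...]  # (points, probability)


@dataclass(frozen=True)
class ScoreTable:
    """Ordered ER bins partitioning (0, 1]; ER exactly 0 uses the bottom bin."""

    bins: tuple[ScoreBin, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "bins", tuple(
            b if isinstance(b, ScoreBin) else ScoreBin(b[0], b[1], tuple(map(tuple, b[2])))
            for b in self.bins
        ))
        if not self.bins:
            raise ScoreTableError("score table has no bins")
        prev_high = 0.0
        for b in self.bins:
            if b.er_low != prev_high:
                raise ScoreTableError(
                    f"bins must partition (0, 1]: bin starts at {b.er_low}, "
                    f"expected {prev_high}"
                )
            if b.er_high <= b.er_low:
                raise ScoreTableError(f"empty bin ({b.er_low}, {b.er_high}]")
            if not b.outcomes:
                raise ScoreTableError("bin has no outcomes")
            psum = sum(p for _, p in b.outcomes)
            if abs(psum - 1.0) > 1e-9:
                raise ScoreTableError(
                    f"outcome probabilities in bin ({b.er_low}, {b.er_high}] "
                    f"sum to {psum}, not 1"
                )
            if any(pts < 0 or p < 0 for pts, p in b.outcomes):
                raise ScoreTableError("points and probabilities must be nonnegative")
            prev_high = b.er_high
        if abs(prev_high - 1.0) > 1e-12:
            raise ScoreTableError(f"top bin ends at {prev_high}, must reach 1")

    def match(self, er: float) -> int:
        """Index of the bin containing ``er`` (lower-exclusive, upper-inclusive)."""
        if not (0 <= er <= 1):
            raise ValueError(f"ER {er} outside [0, 1]")
        for i, b in enumerate(self.bins):
            if (er > b.er_low or (i == 0 and er == 0.0)) and er <= b.er_high:
                return i
        raise ScoreTableError(f"no bin matched ER {er}")  # pragma: no cover

    def expected_points(self) -> list[float]:
        """Expected score per bin."""
        return [sum(pts * p for pts, p in b.outcomes) for b in self.bins]


#: Default scoring: higher individuation earns a higher expected score.
#: The published table's top bin ends at 0.99; it is extended to 1.0 here
#: so that perfect individuation still scores.
DEFAULT_SCORE_TABLE = ScoreTable(bins=(
    ScoreBin(0.0, 0.2, ((0, 1.0),)),
    ScoreBin(0.2, 0.4, ((10, 0.2), (0, 0.8))),
    ScoreBin(0.4, 0.6, ((20, 0.4), (10, 0.6))),
    ScoreBin(0.6, 0.9, ((30, 0.4), (20, 0.6))),
    ScoreBin(0.9, 1.0, ((30, 1.0),)),
))


def score_skeeball(
    er: float,
    table: ScoreTable = DEFAULT_SCORE_TABLE,
    rng: np.random.Generator | None = None,
) -> int:
    """Sample the points for one trial from the matched bin's distribution.

    Deterministic (no randomness consumed) when the bin has a single
    certain outcome.
    """
    b = table.bins[table.match(er)]
    if len(b.outcomes) == 1:
        return b.outcomes[0][0]
    if rng is None:
        rng = np.random.default_rng()
    u = rng.random()
    acc = 0.0
    for pts, p in b.outcomes:
        acc += p
        if u < acc:
            return pts
    return b.outcomes[-1][0]


@dataclass
class TrialResult:
    """Outcome of one movement-attempt trial."""

    index: int
    onset_s: float
    er: float
    ext_mean: float
    flex_mean: float
    points: int
    bin: int
    degenerate: bool = False


@dataclass
class SessionLog:
    """Per-trial results and the cumulative score of one game session."""

    trials: list[TrialResult]
    meta: dict = field(default_factory=dict)

    @property
    def final_score(self) -> int:
        return sum(t.points for t in self.trials)

    @property
    def cumulative(self) -> list[int]:
        out, acc = [], 0
        for t in self.trials:
            acc += t.points
            out.append(acc)
        return out


def play_session(
    env: Envelope,
    onsets: list[float],
    table: ScoreTable = DEFAULT_SCORE_TABLE,
    rng: np.random.Generator | int | None = 0,
    window_s: float = 2.0,
) -> SessionLog:
    """Score every trial of a processed session.

    A degenerate trial (no measurable activity in its window) is scored as
    ER 0.5 — the co-activation bin — and flagged for audit.
    """
    if list(onsets) != sorted(onsets):
        raise ProtocolError("trial onsets must be sorted")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    trials = []
    for k, onset in enumerate(onsets):
        er, ext_mean, flex_mean = trial_er(env, onset, window_s)
        degenerate = is_degenerate(ext_mean, flex_mean)
        b = table.match(er)
        pts = score_skeeball(er, table, rng)
        trials.append(TrialResult(
            index=k, onset_s=float(onset), er=er, ext_mean=ext_mean,
            flex_mean=flex_mean, points=pts, bin=b, degenerate=degenerate,
        ))
    return SessionLog(trials=trials, meta={"window_s": window_s, "n_trials": len(trials)})


@dataclass(frozen=True)
class BlinkoBoard:
    """Pegged chance board: slot point labels and number of peg rows."""

    slot_values: tuple[int, ...] = (100, 500, 1000, 0, 10000, 0, 1000, 500, 100)
    n_rows: int = 8

    def __post_init__(self) -> None:
        if len(self.slot_values) % 2 == 0:
            raise ValueError("board needs an odd number of slots")
        if self.n_rows < 0:
            raise ValueError("n_rows must be nonnegative")

    @property
    def n_slots(self) -> int:
        return len(self.slot_values)


def blinko_start_slot(er: float, board: BlinkoBoard = BlinkoBoard()) -> int:
    """Map ER onto the top of the board: 0 → leftmost, 0.5 → center, 1 → rightmost."""
    if not (0 <= er <= 1):
        raise ValueError(f"ER {er} outside [0, 1]")
    return int(round(er * (board.n_slots - 1)))


def blinko_drop(
    start: int,
    board: BlinkoBoard = BlinkoBoard(),
    rng: np.random.Generator | int | None = 0,
) -> tuple[int, int]:
    """Drop the chip: ``n_rows`` independent ±half-slot steps, walls reflect.

    Returns ``(landing slot, points)``.
    """
    if not (0 <= start < board.n_slots):
        raise ValueError(f"start slot {start} outside [0, {board.n_slots - 1}]")
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    # position in half-slot units so a peg deflection is one integer step
    pos = 2 * start
    hi = 2 * (board.n_slots - 1)
    for _ in range(board.n_rows):
        pos += 1 if rng.random() < 0.5 else -1
        if pos < 0:
            pos = -pos
        elif pos > hi:
            pos = 2 * hi - pos
    slot = int(round(pos / 2))
    return slot, board.slot_values[slot]
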