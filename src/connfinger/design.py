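"""Block design of the physical/colour judgement task and its regressors.

A run is 23 blocks of 18 s (414 s, 207 volumes at TR 2 s): 10 physical
judgement blocks, 10 colour judgement blocks and 3 rest blocks fixed at
block positions 1, 12 and 23 (1-based). Each non-rest block contains two
cue-movie-response triplets (1 s text cue, 6 s movie, 2 s response). The
20 task blocks are arranged in a pseudorandom palindromic order: the second
half mirrors the first, which balances the pairwise ordering of block types
across the run.

Condition regressors model the 1-s cue events only, convolved with a
gamma-variate haemodynamic response peaking at 4.7 s; movie and response
variance is left to the residual. ``whole_block=True`` switches to 18-s
block regressors for sensitivity analyses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "Block",
    "Event",
    "BlockDesign",
    "build_block_design",
    "hrf_gamma",
    "convolve_design",
]

BLOCK_S = 18.0
N_BLOCKS = 23
REST_POSITIONS = (1, 12, 23)  # 1-based
CUE_S = 1.0
MOVIE_S = 6.0
RESPONSE_S = 2.0

# Gamma-variate h(t) = (t/(p*q))**p * exp(p - t/q); unit peak at t = p*q.
HRF_P = 8.6
HRF_Q = 0.547
HRF_PEAK_S = HRF_P * HRF_Q  # 4.7042 s


@dataclass(frozen=True)
class Block:
    index: int          # 1-based position in the run
    block_type: str     # rest | physics | colour
    onset_s: float
    duration_s: float


@dataclass(frozen=True)
class Event:
    event_type: str     # cue_physics | cue_colour | movie | response
    onset_s: float
    duration_s: float


@dataclass
class BlockDesign:
    """Ordered blocks plus cue/movie/response micro-structure on a TR grid."""

    blocks: list[Block]
    events: list[Event]
    tr_s: float

    def __post_init__(self) -> None:
        onsets = [b.onset_s for b in self.blocks]
        if onsets != sorted(onsets):
            raise ValueError("blocks must be ordered by onset")
        for a, b in zip(self.blocks, self.blocks[1:]):
            if not np.isclose(a.onset_s + a.duration_s, b.onset_s):
                raise ValueError("blocks must be contiguous and non-overlapping")

    @property
    def total_duration_s(self) -> float:
        return float(sum(b.duration_s for b in self.blocks))

    @property
    def n_volumes(self) -> int:
        n = self.total_duration_s / self.tr_s
        if abs(n - round(n)) > 1e-9:
            raise ValueError("total duration is not a multiple of TR")
        return int(round(n))

    def block_type_sequence(self) -> list[str]:
        return [b.block_type for b in self.blocks]

    def task_type_sequence(self) -> list[str]:
        return [b.block_type for b in self.blocks if b.block_type != "rest"]

    def events_of(self, event_type: str) -> list[Event]:
        return [e for e in self.events if e.event_type == event_type]

    def to_frame(self) -> pd.DataFrame:
        """Events table as a 3-column (onset, duration, condition) frame."""
        return pd.DataFrame(
            [(e.onset_s, e.duration_s, e.event_type) for e in self.events],
            columns=["onset", "duration", "condition"],
        )

    def write_events_tsv(self, path: str | Path) -> None:
        self.to_frame().to_csv(path, sep="\t", index=False)


def build_block_design(seed: int, tr_s: float = 2.0) -> BlockDesign:
    """Build one run's design with a seed-dependent palindromic task order.

    The first 10 task blocks are a random shuffle of 5 physics + 5 colour;
    the last 10 mirror them, so reversing the 20-element task sequence
    reproduces it and every ordered pair of block types occurs equally often
    in both directions.
    """
    rng = np.random.default_rng(seed)
    half = ["physics"] * 5 + ["colour"] * 5
    rng.shuffle(half)
    task_order = half + half[::-1]

    rest_at = set(REST_POSITIONS)
    blocks: list[Block] = []
    events: list[Event] = []
    task_iter = iter(task_order)
    for pos in range(1, N_BLOCKS + 1):
        onset = (pos - 1) * BLOCK_S
        btype = "rest" if pos in rest_at else next(task_iter)
        blocks.append(Block(pos, btype, onset, BLOCK_S))
        if btype == "rest":
            continue
        cue_name = f"cue_{btype}"
        for rep in range(2):  # two cue-movie-response triplets per block
            t0 = onset + rep * (CUE_S + MOVIE_S + RESPONSE_S)
            events.append(Event(cue_name, t0, CUE_S))
            events.append(Event("movie", t0 + CUE_S, MOVIE_S))
            events.append(Event("response", t0 + CUE_S + MOVIE_S, RESPONSE_S))
    return BlockDesign(blocks, events, tr_s)


def hrf_gamma(t_s: np.ndarray | float, p: float = HRF_P, q: float = HRF_Q) -> np.ndarray:
    """Gamma-variate haemodynamic response, unit peak at t = p*q (4.7 s).

    h(t) = (t/(p*q))**p * exp(p - t/q) for t >= 0.
    """
    t = np.asarray(t_s, dtype=float)
    if np.any(t < 0):
        raise ValueError("hrf_gamma requires t >= 0")
    with np.errstate(divide="ignore"):
        h = np.where(t > 0, (t / (p * q)) ** p * np.exp(p - t / q), 0.0)
    return h if h.ndim else float(h)


def _boxcar_at_tr(events: list[Event], tr_s: float, n_vol: int) -> np.ndarray:
    """Sample event boxcars on the TR grid as the covered fraction of each TR.

    A 1-TR-long event aligned to the grid samples to a single 1, so an
    impulse regressor convolves to the hrf sampled at 0, TR, 2*TR, ...;
    events off the grid (the second cue in each block) contribute their
    overlap fraction to the volumes they straddle.
    """
    box = np.zeros(n_vol)
    for e in events:
        lo, hi = e.onset_s, e.onset_s + e.duration_s
        first = int(np.floor(lo / tr_s))
        last = int(np.ceil(hi / tr_s))
        for v in range(max(first, 0), min(last, n_vol)):
            overlap = min(hi, (v + 1) * tr_s) - max(lo, v * tr_s)
            if overlap > 0:
                box[v] += overlap / tr_s
    return box


def convolve_design(design: BlockDesign, hrf=hrf_gamma, whole_block: bool = False,
                    n_volumes: int | None = None) -> pd.DataFrame:
    """HRF-convolved condition regressors, one column per condition.

    Returns a (T, 2) DataFrame with columns ``physics_cue`` and
    ``colour_cue`` (``physics_block``/``colour_block`` with
    ``whole_block=True``). The boxcar is sampled at TR, discretely convolved
    with the hrf sampled at 0, TR, 2*TR, ... and truncated to T volumes.
    """
    tr = design.tr_s
    T = n_volumes if n_volumes is not None else design.n_volumes
    kernel = hrf(np.arange(T) * tr)
    cols = {}
    for cond in ("physics", "colour"):
        if whole_block:
            evs = [Event(f"{cond}_block", b.onset_s, b.duration_s)
                   for b in design.blocks if b.block_type == cond]
            name = f"{cond}_block"
        else:
            evs = design.events_of(f"cue_{cond}")
            name = f"{cond}_cue"
        box = _boxcar_at_tr(evs, tr, T)
        cols[name] = np.convolve(box, kernel)[:T]
    return pd.DataFrame(cols)
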