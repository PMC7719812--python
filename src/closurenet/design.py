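"""Fragmented-stimulus and presentation-design generation.

Stimuli are line drawings decomposed into drawable segments.  Segments are
randomly and cumulatively deleted to produce seven nested fragmentation
levels: level 1 is the complete picture and the proportion of deleted
segments at level ``L`` is ``1 - 0.7**(L - 1)``, so level 7 retains only
~11.8 % of segments.  Scrambled control stimuli are built by permuting the
tiles of a 16 x 16 grid covering the image.

Two presentation designs are generated:

* ERP blocks following the ascending method of limits (AML): each picture
  sequence steps through fragmentation levels 6 → 3 until the observer
  reports identification; a block holds 10 distinct pictures of which 5
  repeat after one or two intervening sequences (15 sequences per block).
* Blocked fMRI sessions at TR resolution: 9-TR stimulus runs of one
  condition (primed / unprimed / scrambled), with 4 TRs of rest at the
  start of every block and between runs.

All randomness flows through an explicit integer seed per call; there is
no module-level RNG state.
"""

from __future__ import annotations

import dataclasses
import json
import math
from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "Picture",
    "FragmentSequence",
    "Presentation",
    "ErpBlockDesign",
    "SessionDesign",
    "N_LEVELS",
    "ERP_LEVEL_SCHEDULE",
    "ERP_TIMING_MS",
    "FMRI_CONDITIONS",
    "deletion_proportion",
    "fragment_picture",
    "scramble_picture",
    "build_erp_block",
    "build_fmri_session",
    "erp_block_to_table",
    "session_to_table",
    "masks_to_json",
]

#: Number of fragmentation levels per picture (level 1 = complete).
N_LEVELS = 7

#: AML level schedule within one ERP picture sequence (most to least
#: fragmented of the levels used).
ERP_LEVEL_SCHEDULE = (6, 5, 4, 3)

#: ERP trial timing: image, blank, response prompt, blank (ms).
ERP_TIMING_MS = {"image": 750, "blank_post_image": 800, "prompt": 200, "blank_post_prompt": 2200}

#: Non-rest fMRI conditions.
FMRI_CONDITIONS = ("primed", "unprimed", "scrambled")


@dataclass(frozen=True)
class Picture:
    """A line drawing as an ordered list of drawable segment indices."""

    picture_id: str
    segments: tuple[int, ...]

    def __post_init__(self) -> None:
        if len(self.segments) < 1:
            raise ValueError("picture must contain at least one segment")
        if len(set(self.segments)) != len(self.segments):
            raise ValueError("segment ids must be unique")

    @property
    def n_segments(self) -> int:
        return len(self.segments)


@dataclass(frozen=True)
class FragmentSequence:
    """Nested fragmentation levels of one picture.

    ``levels[L]`` is the frozenset of segment ids retained at level ``L``;
    deletion is cumulative following ``deletion_order``, so the retained
    sets are nested (level k+1 is a subset of level k) and level 1 retains
    every segment.
    """

    picture_id: str
    levels: dict[int, frozenset[int]]
    deletion_order: tuple[int, ...]
    seed: int


@dataclass(frozen=True)
class Presentation:
    """One picture-sequence presentation slot in an ERP block."""

    sequence_slot: int
    picture_id: str
    is_repeat: bool
    repeat_lag: int | None  # intervening sequences between initial and repeat
    level_schedule: tuple[int, ...] = ERP_LEVEL_SCHEDULE


@dataclass(frozen=True)
class ErpBlockDesign:
    """An ERP block: 15 picture-sequence presentations, 5 of them repeats."""

    presentations: tuple[Presentation, ...]
    timing_ms: dict[str, int] = field(default_factory=lambda: dict(ERP_TIMING_MS))
    seed: int = 0

    @property
    def n_presentations(self) -> int:
        return len(self.presentations)


@dataclass(frozen=True)
class SessionDesign:
    """A blocked fMRI session schedule at TR resolution."""

    schedule: tuple[str, ...]  # one condition label per TR ("rest" or a condition)
    tr_ms: int = 2000
    run_length_tr: int = 9
    rest_length_tr: int = 4
    n_blocks: int = 0
    runs_per_block: int = 0
    seed: int = 0

    @property
    def total_tr(self) -> int:
        return len(self.schedule)

    def onsets(self) -> pd.DataFrame:
        """Run onsets/durations (TR units), one row per stimulus run."""
        rows = []
        sched = self.schedule
        t = 0
        while t < len(sched):
            if sched[t] != "rest":
                start = t
                cond = sched[t]
                while t < len(sched) and sched[t] == cond:
                    t += 1
                rows.append({"condition": cond, "onset_tr": start, "duration_tr": t - start})
            else:
                t += 1
        return pd.DataFrame(rows, columns=["condition", "onset_tr", "duration_tr"])


def deletion_proportion(level: int) -> float:
    """Proportion of segments deleted at a fragmentation level.

    Level 1 is the complete picture; the proportion deleted at level ``L``
    is ``1 - 0.7**(L - 1)``.
    """
    if not 1 <= int(level) <= N_LEVELS or int(level) != level:
        raise ValueError(f"level must be an integer in 1..{N_LEVELS}, got {level!r}")
    return 1.0 - 0.7 ** (int(level) - 1)


def _round_half_away(x: float) -> int:
    # round-half-away-from-zero; x is nonnegative here
    return int(math.floor(x + 0.5))


def fragment_picture(picture: Picture, seed: int) -> FragmentSequence:
    """Cumulatively delete segments to produce the 7 nested levels.

    A single seeded permutation of the segment ids fixes the deletion
    order; level ``L`` removes the first ``round(n * deletion_proportion(L))``
    segments of that order (round half away from zero), so retained sets
    are nested by construction and identical seeds give identical output.
    """
    n = picture.n_segments
    rng = np.random.default_rng(seed)
    order = tuple(int(s) for s in rng.permutation(np.asarray(picture.segments)))
    levels: dict[int, frozenset[int]] = {}
    for level in range(1, N_LEVELS + 1):
        n_del = _round_half_away(n * deletion_proportion(level))
        levels[level] = frozenset(picture.segments) - frozenset(order[:n_del])
    return FragmentSequence(picture_id=picture.picture_id, levels=levels,
                            deletion_order=order, seed=int(seed))


def scramble_picture(
    image: np.ndarray,
    seed: int,
    grid: tuple[int, int] = (16, 16),
    permutation: Sequence[int] | None = None,
) -> np.ndarray:
    """Scramble an image by permuting the tiles of a 16 x 16 grid.

    The image is split into ``grid`` tiles (zero-padded symmetrically when
    its dimensions are not divisible), the tiles are permuted by a seeded
    draw (or by ``permutation`` when given, e.g. the identity), and the
    result is reassembled.  The multiset of tile contents is preserved.
    """
    img = np.asarray(image)
    if img.ndim != 2:
        raise ValueError(f"expected a 2-D intensity grid, got ndim={img.ndim}")
    gr, gc = grid
    pr = (-img.shape[0]) % gr
    pc = (-img.shape[1]) % gc
    img = np.pad(img, ((pr // 2, pr - pr // 2), (pc // 2, pc - pc // 2)))
    th, tw = img.shape[0] // gr, img.shape[1] // gc
    tiles = (img.reshape(gr, th, gc, tw).swapaxes(1, 2).reshape(gr * gc, th, tw))
    if permutation is None:
        perm = np.random.default_rng(seed).permutation(gr * gc)
    else:
        perm = np.asarray(permutation)
        if sorted(perm.tolist()) != list(range(gr * gc)):
            raise ValueError("permutation must be a permutation of the tile indices")
    tiles = tiles[perm]
    out = tiles.reshape(gr, gc, th, tw).swapaxes(1, 2).reshape(gr * th, gc * tw)
    return out


def build_erp_block(pictures: Sequence[Picture], seed: int) -> ErpBlockDesign:
    """Arrange 10 distinct pictures into one 15-sequence AML block.

    Five pictures are presented once and five twice; the repeat of a
    picture follows its initial presentation after one or two intervening
    sequences, drawn at random.  Repeated sequences reuse the identical
    fragment masks (the design carries one picture_id per slot; mask reuse
    is keying fragmentation by picture_id + one seed).
    """
    if len(pictures) != 10:
        raise ValueError(f"an ERP block requires exactly 10 pictures, got {len(pictures)}")
    ids = [p.picture_id for p in pictures]
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate picture ids in block")
    rng = np.random.default_rng(seed)
    for _attempt in range(1000):
        order = [ids[i] for i in rng.permutation(10)]
        repeated = set(rng.choice(order, size=5, replace=False).tolist())
        slots: list[tuple[str, bool, int | None]] = []
        pending: dict[int, tuple[str, int]] = {}  # due slot -> (picture, lag)
        queue = list(order)
        ok = True
        slot = 0
        while slot < 15:
            if slot in pending:
                pic, lag = pending.pop(slot)
                slots.append((pic, True, lag))
            elif queue:
                pic = queue.pop(0)
                slots.append((pic, False, None))
                if pic in repeated:
                    lags = [1, 2]
                    rng.shuffle(lags)
                    placed = False
                    for lag in lags:
                        due = slot + lag + 1
                        if due not in pending and due < 15:
                            pending[due] = (pic, lag)
                            placed = True
                            break
                    if not placed:
                        ok = False
                        break
            else:
                ok = False  # nothing due and no new pictures left
                break
            slot += 1
        if ok and len(slots) == 15 and not pending and not queue:
            pres = tuple(
                Presentation(sequence_slot=i, picture_id=pic, is_repeat=rep, repeat_lag=lag)
                for i, (pic, rep, lag) in enumerate(slots)
            )
            return ErpBlockDesign(presentations=pres, seed=int(seed))
    raise RuntimeError("could not place repeats within the block (should not happen)")


def build_fmri_session(n_blocks: int, runs_per_block: int, run_order_seed: int) -> SessionDesign:
    """Build a blocked fMRI schedule at TR resolution.

    Each block starts with 4 rest TRs, then ``runs_per_block`` stimulus
    runs of 9 TRs each, separated by 4 rest TRs.  Run conditions cycle
    through primed / unprimed / scrambled in an order randomized once from
    ``run_order_seed`` (the same schedule then serves every participant).
    """
    if n_blocks < 1 or runs_per_block < 1:
        raise ValueError("n_blocks and runs_per_block must be positive")
    rng = np.random.default_rng(run_order_seed)
    run_len, rest_len = 9, 4
    schedule: list[str] = []
    for _b in range(n_blocks):
        conds: list[str] = []
        while len(conds) < runs_per_block:
            block_order = [FMRI_CONDITIONS[i] for i in rng.permutation(len(FMRI_CONDITIONS))]
            conds.extend(block_order)
        conds = conds[:runs_per_block]
        schedule.extend(["rest"] * rest_len)
        for r, cond in enumerate(conds):
            if r > 0:
                schedule.extend(["rest"] * rest_len)
            schedule.extend([cond] * run_len)
    return SessionDesign(schedule=tuple(schedule), run_length_tr=run_len,
                         rest_length_tr=rest_len, n_blocks=int(n_blocks),
                         runs_per_block=int(runs_per_block), seed=int(run_order_seed))


# ---------------------------------------------------------------------------
# serialization: tab-delimited tables + JSON headers, RLE masks


def erp_block_to_table(block: ErpBlockDesign) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "sequence_slot": p.sequence_slot,
                "picture_id": p.picture_id,
                "is_repeat": int(p.is_repeat),
                "repeat_lag": p.repeat_lag if p.repeat_lag is not None else "",
                "level_schedule": "-".join(map(str, p.level_schedule)),
            }
            for p in block.presentations
        ]
    )


def session_to_table(design: SessionDesign) -> pd.DataFrame:
    return pd.DataFrame({"tr": np.arange(design.total_tr), "condition": list(design.schedule)})


def _rle(indices: Sequence[int]) -> list[list[int]]:
    runs: list[list[int]] = []
    for i in sorted(indices):
        if runs and i == runs[-1][0] + runs[-1][1]:
            runs[-1][1] += 1
        else:
            runs.append([int(i), 1])
    return runs


def masks_to_json(seq: FragmentSequence) -> str:
    """Run-length-encoded retained-segment lists per level, as JSON."""
    payload = {
        "picture_id": seq.picture_id,
        "seed": seq.seed,
        "levels": {str(k): _rle(sorted(v)) for k, v in seq.levels.items()},
    }
    return json.dumps(payload, indent=1, sort_keys=True)


def save_design(table: pd.DataFrame, header: dict, path_tsv, path_json) -> None:
    """Write a design table as TSV plus a JSON header of constants/seeds."""
    table.to_csv(path_tsv, sep="\t", index=False)
    with open(path_json, "w") as fh:
        json.dump(header, fh, indent=1, sort_keys=True)
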