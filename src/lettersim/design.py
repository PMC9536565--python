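"""Counterbalanced trial designs for the two behavioral experiments.

Visual search: one session (HIT) per (target position x font x
target-distractor assignment) cell; every unordered letter pair appears
exactly once per HIT, so slow or fast participants influence all pairs
equally.  At full scale (6 positions, 20 fonts, 2 assignments) this yields
240 HITs of C(26,2) = 325 trials.

Speeded categorization: each HIT has two blocks with different target
letters; each block pairs its target with a fixed number of non-target
letters, each repeated on 8 non-match trials, with an equal number of
match trials to balance response bias.  At full scale (13 pairs per block)
each HIT has 416 trials and the ordered (target, non-target) universe has
26*25 = 650 members, distributed near-uniformly over HITs.
"""

from __future__ import annotations

import itertools
import json
import string
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .rdm import canonical_pairs

__all__ = [
    "SearchTrial",
    "SearchHITSpec",
    "CategBlock",
    "CategTrial",
    "CategHITSpec",
    "generate_search_designs",
    "generate_categ_designs",
    "search_design_table",
    "categ_design_table",
]

LOWERCASE = string.ascii_lowercase


@dataclass
class SearchTrial:
    pair: tuple[str, str]  # canonical unordered pair (later letter, earlier letter)
    target: str
    position: int  # 1-based display position


@dataclass
class SearchHITSpec:
    hit_id: str
    font: str
    position: int
    assignment: int  # 0: first-listed pair member is the target; 1: the other
    trials: list[SearchTrial]


@dataclass
class CategBlock:
    target: str
    nontargets: list[str]


@dataclass
class CategTrial:
    block: int  # 0 or 1
    presented: str
    font: str
    match: bool


@dataclass
class CategHITSpec:
    hit_id: str
    blocks: list[CategBlock]
    trials: list[CategTrial]


def generate_search_designs(
    n_positions: int,
    fonts,
    n_assignments: int,
    seed: int,
    alphabet: str = LOWERCASE,
) -> list[SearchHITSpec]:
    """One odd-one-out HIT per (position, font, assignment) combination.

    Within each HIT every unordered pair of ``alphabet`` occurs exactly
    once, with the HIT's fixed target position and target-distractor
    assignment; trial order is shuffled by ``seed``.
    """
    fonts = [str(f) for f in fonts]
    if not fonts:
        raise ValueError("need at least one font")
    if n_positions < 1 or n_assignments < 1:
        raise ValueError("n_positions and n_assignments must be >= 1")
    if len(set(alphabet)) < 2:
        raise ValueError("alphabet must have at least 2 distinct letters")
    pairs = canonical_pairs(list(alphabet))
    rng = np.random.default_rng(seed)
    hits = []
    for pos, font, assign in itertools.product(
        range(1, n_positions + 1), fonts, range(n_assignments)
    ):
        order = rng.permutation(len(pairs))
        trials = [
            SearchTrial(pair=pairs[k], target=pairs[k][assign % 2], position=pos)
            for k in order
        ]
        hit_id = f"search_p{pos}_{font}_a{assign}"
        hits.append(SearchHITSpec(hit_id, font, pos, assign, trials))
    return hits


def _pair_blocks(block_targets: list[str], rng) -> list[tuple[int, int]]:
    # greedily pair block indices so the two blocks of a HIT differ in target
    remaining = list(rng.permutation(len(block_targets)))
    hit_pairs: list[tuple[int, int]] = []
    while remaining:
        a = remaining.pop()
        j = next(
            (k for k, b in enumerate(remaining) if block_targets[b] != block_targets[a]),
            None,
        )
        if j is None:
            # all leftovers share one target; swap into an already-formed HIT
            for hi, (x, y) in enumerate(hit_pairs):
                if block_targets[x] != block_targets[a] != block_targets[y]:
                    b = remaining.pop(0)
                    hit_pairs[hi] = (x, a)
                    hit_pairs.append((y, b))
                    break
            else:
                raise ValueError("cannot pair blocks with distinct targets")
        else:
            b = remaining.pop(j)
            hit_pairs.append((a, b))
    return hit_pairs


def generate_categ_designs(
    alphabet: str,
    reps_per_pair: int,
    n_hits: int,
    seed: int,
    pairs_per_block: int = 13,
    fonts=("font0",),
) -> list[CategHITSpec]:
    """Distribute ordered (target, non-target) pairs over two-block HITs.

    Every ordered pair is assigned to a near-equal number of HITs by
    cycling, per target, through a seeded random permutation of that
    target's non-targets in chunks of ``pairs_per_block``.  Each assigned
    pair contributes ``reps_per_pair`` non-match trials, balanced by an
    equal number of match trials; each trial draws a random font.
    """
    letters = list(alphabet)
    n = len(letters)
    if n < 2:
        raise ValueError("alphabet must have at least 2 letters")
    pairs_per_block = min(pairs_per_block, n - 1)
    n_blocks = 2 * n_hits
    universe = n * (n - 1)
    if n_blocks * pairs_per_block < universe:
        raise ValueError(
            f"{n_hits} HITs x 2 blocks x {pairs_per_block} pairs cannot cover "
            f"all {universe} ordered pairs"
        )
    rng = np.random.default_rng(seed)
    fonts = [str(f) for f in fonts]

    # blocks per target as equal as possible
    base, extra = divmod(n_blocks, n)
    counts = np.full(n, base)
    counts[rng.choice(n, size=extra, replace=False)] += 1

    block_targets: list[str] = []
    block_nontargets: list[list[str]] = []
    for t_idx, target in enumerate(letters):
        others = [l for l in letters if l != target]
        # cyclic window over one fixed permutation: consecutive windows of
        # length <= n-1 contain no duplicates and counts stay within 1
        stream = list(rng.permutation(others))
        cursor = 0
        for _ in range(int(counts[t_idx])):
            chunk = [stream[(cursor + i) % len(stream)] for i in range(pairs_per_block)]
            cursor = (cursor + pairs_per_block) % len(stream)
            block_targets.append(target)
            block_nontargets.append(chunk)

    hit_pairs = _pair_blocks(block_targets, rng)
    hits = []
    for h, (bi, bj) in enumerate(hit_pairs):
        blocks = [
            CategBlock(block_targets[bi], block_nontargets[bi]),
            CategBlock(block_targets[bj], block_nontargets[bj]),
        ]
        trials: list[CategTrial] = []
        for b, blk in enumerate(blocks):
            block_trials = []
            for nt in blk.nontargets:
                for _ in range(reps_per_pair):
                    block_trials.append(
                        CategTrial(b, nt, fonts[rng.integers(len(fonts))], False)
                    )
            for _ in range(len(blk.nontargets) * reps_per_pair):
                block_trials.append(
                    CategTrial(b, blk.target, fonts[rng.integers(len(fonts))], True)
                )
            order = rng.permutation(len(block_trials))
            trials.extend(block_trials[k] for k in order)
        hits.append(CategHITSpec(f"categ_h{h:04d}", blocks, trials))
    return hits


def search_design_table(hits: list[SearchHITSpec]) -> pd.DataFrame:
    """Flatten search HIT specs into a trial-level table."""
    rows = []
    for h in hits:
        for t in h.trials:
            a, b = sorted(t.pair)
            rows.append(
                dict(
                    hit_id=h.hit_id,
                    letter_a=a,
                    letter_b=b,
                    target=t.target,
                    font=h.font,
                    position=t.position,
                )
            )
    return pd.DataFrame(rows)


def categ_design_table(hits: list[CategHITSpec]) -> pd.DataFrame:
    """Flatten categorization HIT specs into a trial-level table."""
    rows = []
    for h in hits:
        for t in h.trials:
            rows.append(
                dict(
                    hit_id=h.hit_id,
                    block=t.block,
                    target=h.blocks[t.block].target,
                    presented=t.presented,
                    font=t.font,
                    match=t.match,
                )
            )
    return pd.DataFrame(rows)


def save_designs_json(hits, path) -> None:
    with open(path, "w") as fh:
        json.dump([asdict(h) for h in hits], fh, indent=1, default=list)
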