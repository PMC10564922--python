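"""miRNA target-site discovery with a duplex free-energy gate.

A seed-complementarity scan (miRNA positions 2-8, G:U wobble allowed)
proposes candidate sites on the target; each candidate is extended into a
local miRNA:target duplex by banded complementarity extension of the
miRNA 3' region (Watson-Crick and G:U pairs, single-strand bulges up to a
configurable length, no internal mismatch loops). The duplex free energy is
the sum of nearest-neighbor stacking terms plus bulge penalties, duplex
initiation and terminal A:U/G:U penalties (see :mod:`cernaforge.nn_params`).
Only sites at or below the energy threshold (default -20 kcal/mol) are
reported, one best site per (miRNA, target) pair.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd

from . import nn_params

_CODE = {"A": 0, "C": 1, "G": 2, "U": 3}
_BASES = "ACGU"

# pair validity / wobble lookup tables indexed by (strand1 code, strand2 code)
_PAIR_OK = np.zeros((4, 4), dtype=bool)
_WOBBLE = np.zeros((4, 4), dtype=bool)
for _x, _y in nn_params.CANONICAL_PAIRS:
    _PAIR_OK[_CODE[_x], _CODE[_y]] = True
for _x, _y in nn_params.WOBBLE_PAIRS:
    _WOBBLE[_CODE[_x], _CODE[_y]] = True


@dataclass(frozen=True)
class DuplexHit:
    """Best energy-gated duplex between one miRNA and one target."""

    mirna_id: str
    target_id: str
    position: int  # 1-based offset of the 5'-most aligned target base
    alignment_score: float
    total_energy: float  # kcal/mol

    def __post_init__(self) -> None:
        if self.position < 1:
            raise ValueError("position must be >= 1")


@dataclass
class TargetConfig:
    energy_threshold: float = -20.0
    seed_start: int = 2  # 1-based miRNA positions, inclusive
    seed_end: int = 8
    max_seed_wobble: int = 1
    max_bulge: int = 3
    match_score: float = 5.0
    wobble_score: float = 1.0

    def __post_init__(self) -> None:
        if self.energy_threshold >= 0:
            raise ValueError("energy_threshold must be negative")
        if not 1 <= self.seed_start < self.seed_end:
            raise ValueError("invalid seed span")


def normalize_rna(seq: str) -> str:
    return seq.upper().replace("T", "U")


def _encode(seq: str) -> np.ndarray:
    arr = np.frombuffer(seq.encode(), dtype=np.uint8)
    codes = np.full(arr.shape, -1, dtype=np.int8)
    for base, code in _CODE.items():
        codes[arr == ord(base)] = code
    if (codes < 0).any():
        raise ValueError("sequence contains non-ACGU characters")
    return codes


def scan_sites(mirna_seq: str, target_seq: str, config: TargetConfig | None = None) -> list[int]:
    """1-based target positions where the miRNA seed finds a complementary match.

    The seed (miRNA positions ``seed_start``..``seed_end``, 5'->3') must pair
    antiparallel with the target window: every position Watson-Crick or G:U,
    with at most ``max_seed_wobble`` wobbles. Overlapping candidates are all
    reported.
    """
    config = config or TargetConfig()
    mirna = normalize_rna(mirna_seq)
    target = normalize_rna(target_seq)
    span = config.seed_end - config.seed_start + 1
    if len(mirna) < config.seed_end or len(target) < span:
        return []
    t_codes = _encode(target)
    seed = _encode(mirna[config.seed_start - 1: config.seed_end])
    # antiparallel: target window base k pairs miRNA seed base (span-1-k)
    seed_rev = seed[::-1]
    windows = np.lib.stride_tricks.sliding_window_view(t_codes, span)
    ok = _PAIR_OK[windows, seed_rev[None, :]]
    wob = _WOBBLE[windows, seed_rev[None, :]]
    good = ok.all(axis=1) & (wob.sum(axis=1) <= config.max_seed_wobble)
    return [int(i) + 1 for i in np.flatnonzero(good)]


def _pair(t_codes: np.ndarray, m_codes: np.ndarray, j: int, i: int) -> tuple[str, str]:
    """(target base, miRNA base) of the pair at 0-based target j / miRNA i."""
    return _BASES[t_codes[j]], _BASES[m_codes[i]]


@dataclass
class DuplexResult:
    total_energy: float
    position: int  # 1-based 5'-most aligned target base
    n_paired: int
    alignment_score: float


def duplex_energy(
    mirna_seq: str, target_seq: str, position: int, config: TargetConfig | None = None
) -> DuplexResult:
    """Energy of the best duplex anchored at a seed candidate ``position``.

    ``position`` is the 1-based target offset of the seed match (as returned
    by :func:`scan_sites`). The miRNA 3' region (positions seed_end+1..L) is
    extended toward the target 5' side by an energy-space dynamic program
    allowing single-strand bulges; miRNA position 1 may stack on the other
    side. More negative energies are more stable.
    """
    config = config or TargetConfig()
    mirna = normalize_rna(mirna_seq)
    target = normalize_rna(target_seq)
    t_codes = _encode(target)
    m_codes = _encode(mirna)
    span = config.seed_end - config.seed_start + 1
    p0 = position - 1  # 0-based target index of the seed match start

    # seed pairing: target p0+k pairs miRNA position (seed_end - k), 1-based
    seed_pairs = [
        (p0 + k, config.seed_end - 1 - k)  # (target idx, miRNA idx), 0-based
        for k in range(span)
    ]
    for j, i in seed_pairs:
        if not _PAIR_OK[t_codes[j], m_codes[i]]:
            raise ValueError(f"position {position} is not a seed match")

    energy = nn_params.DUPLEX_INIT
    score = 0.0
    for j, i in seed_pairs:
        score += config.wobble_score if _WOBBLE[t_codes[j], m_codes[i]] else config.match_score
    # stacks within the seed (target 5'->3')
    for k in range(span - 1):
        j, i = seed_pairs[k]
        energy += nn_params.stack_dg(_pair(t_codes, m_codes, j, i),
                                     _pair(t_codes, m_codes, j + 1, i - 1))

    # optional pairing of miRNA position 1 on the target 3' side of the seed
    pair_3p = seed_pairs[-1]  # (target p0+span-1, miRNA seed_start-1)
    if config.seed_start == 2 and p0 + span < len(target) and \
            _PAIR_OK[t_codes[p0 + span], m_codes[0]]:
        energy += nn_params.stack_dg(_pair(t_codes, m_codes, *pair_3p),
                                     _pair(t_codes, m_codes, p0 + span, 0))
        score += config.wobble_score if _WOBBLE[t_codes[p0 + span], m_codes[0]] \
            else config.match_score
        pair_3p = (p0 + span, 0)

    # 3' supplementary extension: miRNA i > seed_end-1 pairs target j < p0
    maxb = config.max_bulge
    best: dict[tuple[int, int], float] = {(p0, config.seed_end - 1): 0.0}
    frontier = dict(best)
    for _ in range(len(mirna)):  # depth bound; DP states strictly advance
        new_frontier: dict[tuple[int, int], float] = {}
        for (j, i), e in frontier.items():
            outer = _pair(t_codes, m_codes, j, i)
            for gi in range(0, maxb + 1):
                for gj in range(0, maxb + 1):
                    if gi > 0 and gj > 0:
                        continue
                    i2 = i + 1 + gi
                    j2 = j - 1 - gj
                    if i2 >= len(mirna) or j2 < 0:
                        continue
                    if not _PAIR_OK[t_codes[j2], m_codes[i2]]:
                        continue
                    inner = _pair(t_codes, m_codes, j2, i2)
                    gap = gi + gj
                    if gap == 0:
                        de = nn_params.stack_dg(inner, outer)
                    elif gap == 1:
                        de = nn_params.bulge_dg(1) + nn_params.stack_dg(inner, outer)
                    else:
                        de = nn_params.bulge_dg(gap)
                    e2 = e + de
                    key = (j2, i2)
                    if e2 < best.get(key, np.inf):
                        best[key] = e2
                        new_frontier[key] = e2
        if not new_frontier:
            break
        frontier = new_frontier

    # close the duplex at the best extension endpoint
    best_total = np.inf
    best_start = p0
    best_extra_pairs = 0
    for (j, i), e in best.items():
        end_pair = _pair(t_codes, m_codes, j, i)
        total = (energy + e
                 + nn_params.terminal_penalty(end_pair)
                 + nn_params.terminal_penalty(_pair(t_codes, m_codes, *pair_3p)))
        if total < best_total or (total == best_total and j < best_start):
            best_total = total
            best_start = j
            best_extra_pairs = i - (config.seed_end - 1)
    n_paired = span + best_extra_pairs + (1 if pair_3p[1] == 0 else 0)
    # score the 3' extension pairs of the winning endpoint conservatively as matches
    score += config.match_score * best_extra_pairs
    return DuplexResult(
        total_energy=float(best_total),
        position=best_start + 1,
        n_paired=n_paired,
        alignment_score=score,
    )


def predict_targets(
    mirnas: Mapping[str, str],
    targets: Mapping[str, str],
    config: TargetConfig | None = None,
) -> list[DuplexHit]:
    """Energy-gated best duplex per (miRNA, target) pair.

    For every pair the seed scan proposes candidates, each is scored by
    :func:`duplex_energy`, and the most stable site (ties broken by smallest
    position) is kept iff its energy is at or below the threshold. Output is
    ordered by (miRNA, target).
    """
    config = config or TargetConfig()
    if len(set(mirnas)) != len(mirnas) or len(set(targets)) != len(targets):
        raise ValueError("duplicate sequence IDs")
    hits: list[DuplexHit] = []
    for mid in sorted(mirnas):
        mseq = normalize_rna(mirnas[mid])
        for tid in sorted(targets):
            tseq = normalize_rna(targets[tid])
            best: DuplexResult | None = None
            for pos in scan_sites(mseq, tseq, config):
                res = duplex_energy(mseq, tseq, pos, config)
                if best is None or res.total_energy < best.total_energy or (
                    res.total_energy == best.total_energy and res.position < best.position
                ):
                    best = res
            if best is not None and best.total_energy <= config.energy_threshold:
                hits.append(
                    DuplexHit(mid, tid, best.position, best.alignment_score,
                              round(best.total_energy, 2))
                )
    return hits


def hits_to_frame(hits: list[DuplexHit]) -> pd.DataFrame:
    return pd.DataFrame(
        [(h.mirna_id, h.target_id, h.total_energy, h.position, h.alignment_score)
         for h in hits],
        columns=["mirna_id", "target_id", "total_energy", "position", "alignment_score"],
    )


def frame_to_hits(df: pd.DataFrame) -> list[DuplexHit]:
    return [
        DuplexHit(r.mirna_id, r.target_id, int(r.position), float(r.alignment_score),
                  float(r.total_energy))
        for r in df.itertuples(index=False)
    ]
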