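"""Combinatorial barcode calling from multi-round pseudo-color spot tables.

A transcript appears as one spot per barcode round, co-located up to
positional jitter, whose pseudo-colors spell the gene's codeword.  The
decoder reconstructs transcripts per field of view:

1. For each barcode round used as the *seed*, every seed-round spot is
   combined with its nearest neighbour (within a 1.2-pixel closed ball)
   in each other round.  A combination is accepted in pass 1 only when it
   is mutual — each member's nearest seed-round spot is the anchor — and
   its color vector matches a codeword exactly.  Accepted spots are
   consumed.
2. Remaining seed-round spots are re-examined against all neighbour
   choices per round (a round may also be left missing).  Candidate sets
   whose color vector lies within Hamming distance 1 of a unique codeword
   compete; the set with the most rounds present and, within that, the
   minimum summed pairwise distance wins.  Ties between different genes
   are ambiguous and dropped — never broken arbitrarily.
3. The per-seed passes are repeated with every round as seed, calls from
   different seeds that share a gene and at least one member spot are
   merged, and only transcripts supported by at least ``min_seeds`` seeds
   are retained (default: all four, the literal reading of the protocol;
   see the methods note for why 3 is often preferable).

Everything is deterministic: neighbours are ordered by (distance,
spot_id), anchors are processed in spot_id order, and the output is
sorted by (gene_id, x, y).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd

from .codebook import Codebook, nearest_codeword

__all__ = [
    "DecodedTranscript",
    "SeedCall",
    "neighbors_within",
    "decode_seed",
    "consensus",
    "decode_fov",
    "transcripts_to_frame",
]

DEFAULT_RADIUS = 1.2
# pass-2 enumeration guard: beyond this many combinations per anchor the
# per-round neighbour lists are truncated to the nearest few spots
_MAX_COMBOS = 100_000
_TRUNC = 8


@dataclass(frozen=True)
class SeedCall:
    """One per-seed transcript call (intermediate product of decode_seed)."""

    gene_id: str
    seed_round: int
    member_spot_ids: frozenset[int]
    n_rounds_present: int
    hamming_used: int
    total_pair_distance: float


@dataclass(frozen=True)
class DecodedTranscript:
    """A consensus gene call with its member spots and quality metrics."""

    gene_id: str
    fov: int
    x: float
    y: float
    member_spot_ids: frozenset[int]
    n_rounds_present: int
    hamming_used: int
    total_pair_distance: float
    seed_support: int


def _dist(x0: float, y0: float, x1: float, y1: float) -> float:
    return math.hypot(x1 - x0, y1 - y0)


def neighbors_within(
    anchor: tuple[float, float],
    others: pd.DataFrame,
    radius: float = DEFAULT_RADIUS,
) -> pd.DataFrame:
    """Spots of ``others`` within a closed ball of ``radius`` around the anchor.

    Sorted by ascending Euclidean distance, ties broken by spot_id.  The
    ball is closed: a neighbour at exactly ``radius`` is included.
    """
    ax, ay = anchor
    d = np.hypot(others["x"].to_numpy() - ax, others["y"].to_numpy() - ay)
    keep = d <= radius
    out = others.loc[keep].copy()
    out["distance"] = d[keep]
    return out.sort_values(["distance", "spot_id"], kind="mergesort").reset_index(
        drop=True
    )


class _FovSpots:
    """Column-array view of one FOV's spots with an active mask."""

    def __init__(self, spots: pd.DataFrame):
        s = spots.sort_values("spot_id", kind="mergesort")
        self.ids = s["spot_id"].to_numpy(dtype=np.int64)
        self.rounds = s["round"].to_numpy(dtype=np.int64)
        self.colors = s["color"].to_numpy(dtype=np.int64)
        self.x = s["x"].to_numpy(dtype=float)
        self.y = s["y"].to_numpy(dtype=float)
        self.active = np.ones(len(s), dtype=bool)
        self._pos = {int(i): k for k, i in enumerate(self.ids)}

    def round_indices(self, rnd: int) -> np.ndarray:
        return np.nonzero(self.active & (self.rounds == rnd))[0]

    def nearest_in_round(
        self, idx: int, rnd: int, radius: float
    ) -> Optional[int]:
        """Index of the nearest active spot of ``rnd`` within the closed ball."""
        cand = self.round_indices(rnd)
        if len(cand) == 0:
            return None
        d = np.hypot(self.x[cand] - self.x[idx], self.y[cand] - self.y[idx])
        ok = d <= radius
        if not ok.any():
            return None
        cand, d = cand[ok], d[ok]
        order = np.lexsort((self.ids[cand], d))
        return int(cand[order[0]])

    def neighbors_in_round(self, idx: int, rnd: int, radius: float) -> list[int]:
        cand = self.round_indices(rnd)
        if len(cand) == 0:
            return []
        d = np.hypot(self.x[cand] - self.x[idx], self.y[cand] - self.y[idx])
        ok = d <= radius
        cand, d = cand[ok], d[ok]
        order = np.lexsort((self.ids[cand], d))
        return [int(c) for c in cand[order]]

    def consume(self, indices: Sequence[int]) -> None:
        self.active[list(indices)] = False

    def pair_distance_sum(self, indices: Sequence[int]) -> float:
        tot = 0.0
        idx = list(indices)
        for i, a in enumerate(idx):
            for b in idx[i + 1 :]:
                tot += _dist(self.x[a], self.y[a], self.x[b], self.y[b])
        return tot


def decode_seed(
    spots: pd.DataFrame,
    seed_round: int,
    cb: Codebook,
    radius: float = DEFAULT_RADIUS,
    max_hamming: int = 1,
) -> list[SeedCall]:
    """Run the two-pass per-seed combination on one registered FOV.

    Pass 1 accepts mutual-nearest-neighbour combinations that match a
    codeword exactly (computed on a snapshot of the full spot set, so it
    is order-independent; mutuality makes accepted combinations disjoint).
    Pass 2 rescues remaining anchors by Hamming-distance matching, with a
    missing round counted as one mismatch.  Spots of an accepted call are
    consumed; spots dropped as ambiguous stay available until the pass
    ends.
    """
    R = cb.rounds
    if not (1 <= seed_round <= R):
        raise ValueError(f"seed_round {seed_round} outside 1..{R}")
    if len(spots) == 0:
        return []
    fv = _FovSpots(spots)
    other_rounds = [r for r in range(1, R + 1) if r != seed_round]
    calls: list[SeedCall] = []

    # ---- pass 1: mutual NN + exact codeword match, on a snapshot -------
    accepted: list[tuple[str, list[int]]] = []
    for a in fv.round_indices(seed_round):
        members = {seed_round: int(a)}
        ok = True
        for rnd in other_rounds:
            m = fv.nearest_in_round(a, rnd, radius)
            if m is None:
                ok = False
                break
            # mutuality: m's nearest seed-round spot must be the anchor
            back = fv.nearest_in_round(m, seed_round, radius)
            if back != a:
                ok = False
                break
            members[rnd] = m
        if not ok:
            continue
        vector = tuple(int(fv.colors[members[r]]) for r in range(1, R + 1))
        gene = cb.exact_lookup(vector)
        if gene is not None:
            accepted.append((gene, [members[r] for r in range(1, R + 1)]))
    for gene, idxs in accepted:
        calls.append(
            SeedCall(
                gene_id=gene,
                seed_round=seed_round,
                member_spot_ids=frozenset(int(fv.ids[i]) for i in idxs),
                n_rounds_present=R,
                hamming_used=0,
                total_pair_distance=fv.pair_distance_sum(idxs),
            )
        )
        fv.consume(idxs)

    # ---- pass 2: Hamming-distance rescue, sequential in spot_id order --
    for a in fv.round_indices(seed_round):
        if not fv.active[a]:
            continue
        neigh = {rnd: fv.neighbors_in_round(a, rnd, radius) for rnd in other_rounds}
        n_combo = 1
        for rnd in other_rounds:
            n_combo *= len(neigh[rnd]) + 1
        if n_combo > _MAX_COMBOS:
            neigh = {rnd: lst[:_TRUNC] for rnd, lst in neigh.items()}
        candidates: list[tuple[int, float, tuple[int, ...], str, int]] = []
        for combo in itertools.product(
            *[[None] + neigh[rnd] for rnd in other_rounds]
        ):
            chosen = dict(zip(other_rounds, combo))
            missing = sum(1 for v in chosen.values() if v is None)
            if missing > max_hamming:
                continue
            vector = []
            for r in range(1, R + 1):
                if r == seed_round:
                    vector.append(int(fv.colors[a]))
                else:
                    m = chosen[r]
                    vector.append(None if m is None else int(fv.colors[m]))
            res = nearest_codeword(vector, cb, max_dist=max_hamming)
            if res.status != "match":
                continue
            idxs = [int(a)] + [m for m in combo if m is not None]
            candidates.append(
                (
                    len(idxs),  # rounds present (maximise)
                    fv.pair_distance_sum(idxs),  # then minimise
                    tuple(sorted(int(fv.ids[i]) for i in idxs)),
                    res.gene_id,
                    res.distance,
                )
            )
        if not candidates:
            continue
        best_size = max(c[0] for c in candidates)
        tier = [c for c in candidates if c[0] == best_size]
        best_d = min(c[1] for c in tier)
        tier = [c for c in tier if c[1] == best_d]
        genes = {c[3] for c in tier}
        if len(genes) > 1:
            continue  # ambiguous at the minimum: dropped
        size, dsum, id_tuple, gene, hd = min(tier, key=lambda c: c[2])
        idxs = [fv._pos[i] for i in id_tuple]
        calls.append(
            SeedCall(
                gene_id=gene,
                seed_round=seed_round,
                member_spot_ids=frozenset(id_tuple),
                n_rounds_present=size,
                hamming_used=int(hd),
                total_pair_distance=dsum,
            )
        )
        fv.consume(idxs)

    return calls


def consensus(
    per_seed: Sequence[Sequence[SeedCall]],
    spots: pd.DataFrame,
    cb: Codebook,
    min_seeds: int = 4,
) -> list[DecodedTranscript]:
    """Merge per-seed calls and retain transcripts seen by ≥ ``min_seeds`` seeds.

    Calls from different seeds are the same physical transcript when they
    share the gene and at least one member spot (the weakest relation that
    identifies per-seed duplicates); merged coordinates are the centroid
    over the union of member spots.  A rare residual spot conflict between
    two retained transcripts is resolved deterministically in favour of
    higher seed support, then lower summed pair distance.
    """
    if min_seeds > cb.rounds:
        raise ValueError(f"min_seeds {min_seeds} > rounds {cb.rounds}")
    flat = [c for calls in per_seed for c in calls]
    if not flat:
        return []

    parent = list(range(len(flat)))

    def find(i: int) -> int:
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    def union(i: int, j: int) -> None:
        ri, rj = find(i), find(j)
        if ri != rj:
            parent[max(ri, rj)] = min(ri, rj)

    spot_to_calls: dict[int, list[int]] = {}
    for k, call in enumerate(flat):
        for sid in call.member_spot_ids:
            spot_to_calls.setdefault(sid, []).append(k)
    for sid, ks in spot_to_calls.items():
        for i in range(len(ks)):
            for j in range(i + 1, len(ks)):
                if flat[ks[i]].gene_id == flat[ks[j]].gene_id:
                    union(ks[i], ks[j])

    groups: dict[int, list[SeedCall]] = {}
    for k, call in enumerate(flat):
        groups.setdefault(find(k), []).append(call)

    coords = spots.set_index("spot_id")[["x", "y"]]
    fovs = spots["fov"].unique()
    fov = int(fovs[0]) if len(fovs) else -1
    merged: list[DecodedTranscript] = []
    for calls in groups.values():
        seeds = {c.seed_round for c in calls}
        if len(seeds) < min_seeds:
            continue
        members = frozenset().union(*(c.member_spot_ids for c in calls))
        xy = coords.loc[sorted(members)]
        rounds_present = spots.set_index("spot_id").loc[sorted(members), "round"].nunique()
        merged.append(
            DecodedTranscript(
                gene_id=calls[0].gene_id,
                fov=fov,
                x=float(xy["x"].mean()),
                y=float(xy["y"].mean()),
                member_spot_ids=members,
                n_rounds_present=int(rounds_present),
                hamming_used=min(c.hamming_used for c in calls),
                total_pair_distance=min(c.total_pair_distance for c in calls),
                seed_support=len(seeds),
            )
        )

    # deterministic post-hoc resolution of residual cross-gene spot sharing
    merged.sort(
        key=lambda t: (
            -t.seed_support,
            t.total_pair_distance,
            t.gene_id,
            tuple(sorted(t.member_spot_ids)),
        )
    )
    used: set[int] = set()
    retained: list[DecodedTranscript] = []
    for t in merged:
        if used & t.member_spot_ids:
            continue
        used |= t.member_spot_ids
        retained.append(t)
    retained.sort(key=lambda t: (t.gene_id, t.x, t.y))
    return retained


def decode_fov(
    spots: pd.DataFrame,
    cb: Codebook,
    radius: float = DEFAULT_RADIUS,
    max_hamming: int = 1,
    min_seeds: int = 4,
) -> list[DecodedTranscript]:
    """Decode one registered FOV: every round as seed, then consensus.

    If the table lacks a unique ``spot_id`` column, canonical ids are
    assigned by sorting on (round, color, x, y, intensity), which makes
    the output invariant to input row order.
    """
    if len(spots) == 0:
        return []
    spots = spots.copy()
    if "spot_id" not in spots.columns or spots["spot_id"].duplicated().any():
        cols = [c for c in ["round", "color", "x", "y", "intensity"] if c in spots.columns]
        spots = spots.sort_values(cols, kind="mergesort").reset_index(drop=True)
        spots["spot_id"] = np.arange(len(spots))
    if spots["fov"].nunique() > 1:
        raise ValueError("decode_fov expects a single FOV; split the table first")
    per_seed = [
        decode_seed(spots, seed_round, cb, radius=radius, max_hamming=max_hamming)
        for seed_round in range(1, cb.rounds + 1)
    ]
    return consensus(per_seed, spots, cb, min_seeds=min_seeds)


def transcripts_to_frame(transcripts: Sequence[DecodedTranscript]) -> pd.DataFrame:
    """Tidy DataFrame view of decoded transcripts."""
    return pd.DataFrame(
        [
            {
                "gene_id": t.gene_id,
                "fov": t.fov,
                "x": t.x,
                "y": t.y,
                "n_rounds_present": t.n_rounds_present,
                "hamming_used": t.hamming_used,
                "total_pair_distance": t.total_pair_distance,
                "seed_support": t.seed_support,
            }
            for t in transcripts
        ],
        columns=[
            "gene_id",
            "fov",
            "x",
            "y",
            "n_rounds_present",
            "hamming_used",
            "total_pair_distance",
            "seed_support",
        ],
    )
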