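"""Combinatorial pseudo-color codebooks with Hamming-distance guarantees.

In sequential FISH, a gene is identified by a *codeword*: a vector of
pseudo-colors, one per barcode round.  Decoding tolerates a single
erroneous or missing round when the codebook's minimum pairwise Hamming
distance is at least 3 (the distance-1 balls around codewords are then
disjoint, so nearest-codeword correction is unambiguous).

This module constructs such codebooks, serialises them to JSON, and
answers nearest-codeword queries in which a missing round (no detected
spot) counts as a mismatch.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Iterable, Optional, Sequence

import numpy as np

__all__ = [
    "Codeword",
    "Codebook",
    "MatchResult",
    "CapacityError",
    "hamming",
    "generate_codebook",
    "nearest_codeword",
]


class CapacityError(ValueError):
    """Requested code size exceeds what the search achieved.

    Attributes
    ----------
    achieved : int
        Largest codeword count found before giving up.
    """

    def __init__(self, requested: int, achieved: int) -> None:
        self.requested = requested
        self.achieved = achieved
        super().__init__(
            f"could not construct {requested} codewords; achieved {achieved}"
        )


@dataclass(frozen=True)
class Codeword:
    """A gene's barcode: one pseudo-color per round, colors in 1..P."""

    gene_id: str
    colors: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "colors", tuple(int(c) for c in self.colors))


@dataclass(frozen=True)
class MatchResult:
    """Outcome of a nearest-codeword query.

    ``status`` is one of ``"match"`` (unique nearest codeword within the
    distance cap), ``"ambiguous"`` (two or more codewords tie at the
    minimal distance) or ``"no_match"`` (minimal distance exceeds the cap).
    """

    status: str
    gene_id: Optional[str] = None
    distance: Optional[int] = None


def hamming(a: Sequence, b: Sequence) -> int:
    """Number of positions at which two color vectors differ.

    ``None`` entries (a round with no spot) always count as mismatches,
    even against another ``None``: a missing observation carries no
    evidence of agreement.

    Raises
    ------
    ValueError
        If the vectors have different lengths.
    """
    if len(a) != len(b):
        raise ValueError(f"length mismatch: {len(a)} vs {len(b)}")
    d = 0
    for x, y in zip(a, b):
        if x is None or y is None or x != y:
            d += 1
    return d


@dataclass
class Codebook:
    """A set of codewords over ``rounds`` barcode rounds and palette 1..P."""

    rounds: int
    palette_size: int
    min_hamming: int
    codewords: list[Codeword] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.validate()
        self._by_colors = {cw.colors: cw.gene_id for cw in self.codewords}
        self._by_gene = {cw.gene_id: cw for cw in self.codewords}

    def validate(self) -> None:
        genes = [cw.gene_id for cw in self.codewords]
        if len(set(genes)) != len(genes):
            raise ValueError("duplicate gene_ids in codebook")
        vecs = [cw.colors for cw in self.codewords]
        if len(set(vecs)) != len(vecs):
            raise ValueError("duplicate color vectors in codebook")
        for cw in self.codewords:
            if len(cw.colors) != self.rounds:
                raise ValueError(
                    f"{cw.gene_id}: codeword length {len(cw.colors)} != rounds {self.rounds}"
                )
            if any(c < 1 or c > self.palette_size for c in cw.colors):
                raise ValueError(f"{cw.gene_id}: color outside 1..{self.palette_size}")
        for i, a in enumerate(self.codewords):
            for b in self.codewords[i + 1 :]:
                d = hamming(a.colors, b.colors)
                if d < self.min_hamming:
                    raise ValueError(
                        f"codewords {a.gene_id}/{b.gene_id} at distance {d} "
                        f"< min_hamming {self.min_hamming}"
                    )

    # -- queries ---------------------------------------------------------

    def __len__(self) -> int:
        return len(self.codewords)

    @property
    def gene_ids(self) -> list[str]:
        return [cw.gene_id for cw in self.codewords]

    def exact_lookup(self, colors: Sequence[int]) -> Optional[str]:
        """Gene whose codeword equals ``colors`` exactly, or None."""
        return self._by_colors.get(tuple(colors))

    def codeword_for(self, gene_id: str) -> Codeword:
        return self._by_gene[gene_id]

    # -- serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        return {
            "rounds": self.rounds,
            "palette_size": self.palette_size,
            "min_hamming": self.min_hamming,
            "codewords": [
                {"gene": cw.gene_id, "colors": list(cw.colors)}
                for cw in self.codewords
            ],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "Codebook":
        return cls(
            rounds=int(d["rounds"]),
            palette_size=int(d["palette_size"]),
            min_hamming=int(d["min_hamming"]),
            codewords=[
                Codeword(gene_id=e["gene"], colors=tuple(e["colors"]))
                for e in d["codewords"]
            ],
        )

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=1)

    @classmethod
    def from_json(cls, path) -> "Codebook":
        with open(path) as fh:
            return cls.from_dict(json.load(fh))


def _greedy_code(order: np.ndarray, words: np.ndarray, n: int, min_hamming: int) -> list[tuple[int, ...]]:
    """Greedy scan of ``words`` in the given order, keeping distance-compatible words."""
    chosen: list[np.ndarray] = []
    for idx in order:
        w = words[idx]
        ok = True
        for c in chosen:
            if int(np.sum(c != w)) < min_hamming:
                ok = False
                break
        if ok:
            chosen.append(w)
            if len(chosen) == n:
                break
    return [tuple(int(x) for x in w) for w in chosen]


def generate_codebook(
    n_genes: int,
    rounds: int = 4,
    palette_size: int = 4,
    min_hamming: int = 3,
    seed: int = 0,
    gene_prefix: str = "gene",
    max_restarts: int = 50,
) -> Codebook:
    """Build a codebook of ``n_genes`` codewords with pairwise distance ≥ ``min_hamming``.

    Greedy scan over a seeded shuffle of the full P^R space; a greedy pass
    that falls short is restarted with a fresh shuffle (same seed stream),
    because greedy codes are maximal but not always maximum.  Deterministic
    for a fixed seed.

    Raises
    ------
    CapacityError
        If no restart reaches ``n_genes``; carries the best achieved count.
    """
    if n_genes < 1:
        raise ValueError("n_genes must be >= 1")
    if palette_size < 2:
        raise ValueError("palette_size must be >= 2")
    if not (1 <= min_hamming <= rounds):
        raise ValueError("min_hamming must be in 1..rounds")

    # full enumeration of P^R color vectors (colors 1..P)
    grids = np.meshgrid(*[np.arange(1, palette_size + 1)] * rounds, indexing="ij")
    words = np.stack([g.ravel() for g in grids], axis=1)

    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(97,)))
    best: list[tuple[int, ...]] = []
    for _ in range(max_restarts):
        order = rng.permutation(len(words))
        chosen = _greedy_code(order, words, n_genes, min_hamming)
        if len(chosen) > len(best):
            best = chosen
        if len(best) >= n_genes:
            break
    if len(best) < n_genes:
        raise CapacityError(n_genes, len(best))

    width = len(str(n_genes - 1))
    codewords = [
        Codeword(gene_id=f"{gene_prefix}{i:0{width}d}", colors=colors)
        for i, colors in enumerate(best)
    ]
    return Codebook(
        rounds=rounds,
        palette_size=palette_size,
        min_hamming=min_hamming,
        codewords=codewords,
    )


def nearest_codeword(
    query: Sequence, cb: Codebook, max_dist: int = 1
) -> MatchResult:
    """Match a (possibly partial) color vector to the nearest codeword.

    Missing rounds are ``None`` entries and count as mismatches, so a
    3-of-4 partial barcode sits at distance ≥ 1 from every codeword but can
    still be rescued when ``max_dist`` ≥ 1.

    Returns a unique nearest codeword at distance ≤ ``max_dist`` as
    ``"match"``; a tie at the minimal distance as ``"ambiguous"``; a
    minimal distance above the cap as ``"no_match"``.  Ambiguity is a
    first-class outcome — ties are never broken arbitrarily.
    """
    if len(query) != cb.rounds:
        raise ValueError(f"query length {len(query)} != rounds {cb.rounds}")
    best_d = cb.rounds + 1
    best_genes: list[str] = []
    for cw in cb.codewords:
        d = hamming(query, cw.colors)
        if d < best_d:
            best_d = d
            best_genes = [cw.gene_id]
        elif d == best_d:
            best_genes.append(cw.gene_id)
    if best_d > max_dist:
        return MatchResult("no_match", None, None)
    if len(best_genes) > 1:
        return MatchResult("ambiguous", None, best_d)
    return MatchResult("match", best_genes[0], best_d)
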