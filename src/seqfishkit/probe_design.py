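"""Primary- and readout-probe design for sequential FISH panels.

Primary (target) probes are 28-nt windows of a gene's exonic sequence with
a melting temperature in a configurable band (default 50–80 °C), screened
for off-target binding by exact 17-mer matches against every other gene in
the supplied transcriptome (both strands), then thinned to a non-overlapping
set of 17–32 probes per gene.  Readout probes are random sequences with GC
in [0.40, 0.60] that share no 10-mer — on either strand — with a reference
index or with each other.

The k-mer screens substitute for a local BLAST search: exact k-mer matching
at k = 17 (off-target) and k = 10 (readout orthogonality) is the decision
rule actually applied, gapped alignment is out of scope.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from Bio.Seq import Seq
from Bio.SeqUtils import MeltingTemp as _mt

__all__ = [
    "ProbeCandidate",
    "ReadoutProbe",
    "KmerIndex",
    "GeneProbeSet",
    "InvalidSequenceError",
    "ReadoutGenerationError",
    "gc_fraction",
    "melting_temperature",
    "reverse_complement",
    "candidate_windows",
    "build_kmer_index",
    "offtarget_filter",
    "select_gene_probes",
    "generate_readouts",
    "design_probes",
]

PROBE_LENGTH = 28
OFFTARGET_K = 17
READOUT_K = 10

_VALID = set("ACGT")


class InvalidSequenceError(ValueError):
    pass


class ReadoutGenerationError(RuntimeError):
    """Attempt budget exhausted before ``n`` readouts were accepted."""

    def __init__(self, requested: int, achieved: int) -> None:
        self.requested = requested
        self.achieved = achieved
        super().__init__(
            f"generated {achieved} of {requested} readouts before exhausting attempts"
        )


def _check_dna(sequence: str) -> str:
    if not sequence:
        raise InvalidSequenceError("empty sequence")
    s = sequence.upper()
    if not set(s) <= _VALID:
        bad = sorted(set(s) - _VALID)
        raise InvalidSequenceError(f"non-ACGT characters: {bad}")
    return s


def reverse_complement(sequence: str) -> str:
    return str(Seq(sequence).reverse_complement())


def gc_fraction(sequence: str) -> float:
    """(#G + #C) / length for an ACGT sequence."""
    s = _check_dna(sequence)
    return (s.count("G") + s.count("C")) / len(s)


def melting_temperature(
    sequence: str,
    salt_molar: float = 0.05,
    strand_conc_molar: float = 250e-12,
) -> float:
    """Duplex melting temperature in °C, nearest-neighbor thermodynamics.

    Uses the unified nearest-neighbor parameter set (SantaLucia 1998) with
    an entropic monovalent-salt correction, at the given Na+ concentration
    (default 50 mM) and per-strand concentration (default 250 pM, non
    self-complementary assumption).  Only the band edges are biologically
    meaningful here; conditions are configurable and recorded by callers.
    """
    s = _check_dna(sequence)
    if len(s) < 8:
        raise InvalidSequenceError("sequence shorter than 8 nt")
    return float(
        _mt.Tm_NN(
            s,
            nn_table=_mt.DNA_NN3,
            Na=salt_molar * 1e3,  # mM
            dnac1=strand_conc_molar * 1e9,  # nM
            dnac2=strand_conc_molar * 1e9,
            saltcorr=5,
        )
    )


@dataclass(frozen=True)
class ProbeCandidate:
    """A 28-nt window of a gene's exonic sequence; 0-based half-open [start, start+28)."""

    gene_id: str
    start: int
    sequence: str
    tm_celsius: float
    gc: float


@dataclass(frozen=True)
class ReadoutProbe:
    readout_id: str
    sequence: str
    gc: float


@dataclass
class GeneProbeSet:
    """Selection outcome for one gene; ``accepted`` is False for rejected genes."""

    gene_id: str
    probes: list[ProbeCandidate]
    accepted: bool
    achieved: int


class KmerIndex:
    """Exact k-mer → source-id map over a sequence collection.

    When built with ``include_reverse_complement`` every k-mer of the
    reverse complement is indexed too, so queries are strand-aware like the
    BLAST screen this stands in for.
    """

    def __init__(self, k: int, include_reverse_complement: bool = True) -> None:
        if k < 1:
            raise ValueError("k must be >= 1")
        self.k = k
        self.include_reverse_complement = include_reverse_complement
        self._map: dict[str, set[str]] = {}

    def add_sequence(self, source_id: str, sequence: str) -> None:
        s = _check_dna(sequence)
        strands = [s]
        if self.include_reverse_complement:
            strands.append(reverse_complement(s))
        for strand in strands:
            for i in range(len(strand) - self.k + 1):
                self._map.setdefault(strand[i : i + self.k], set()).add(source_id)

    def sources(self, kmer: str) -> set[str]:
        if len(kmer) != self.k:
            raise ValueError(f"query length {len(kmer)} != k {self.k}")
        return self._map.get(kmer.upper(), set())

    def __contains__(self, kmer: str) -> bool:
        return bool(self.sources(kmer))

    def __len__(self) -> int:
        return len(self._map)


def build_kmer_index(
    sequences: Mapping[str, str] | Iterable[tuple[str, str]],
    k: int,
    include_reverse_complement: bool = True,
) -> KmerIndex:
    """Index every length-k substring of every record under its source id."""
    idx = KmerIndex(k, include_reverse_complement)
    items = sequences.items() if isinstance(sequences, Mapping) else sequences
    for source_id, seq in items:
        if len(seq) >= k:
            idx.add_sequence(source_id, seq)
    return idx


def candidate_windows(
    gene_id: str,
    exon_sequence: str,
    length: int = PROBE_LENGTH,
    tm_lo: float = 50.0,
    tm_hi: float = 80.0,
    salt_molar: float = 0.05,
    strand_conc_molar: float = 250e-12,
) -> list[ProbeCandidate]:
    """All length-28 windows with Tm in [tm_lo, tm_hi] (inclusive), ascending start."""
    s = exon_sequence.upper()
    out: list[ProbeCandidate] = []
    for start in range(len(s) - length + 1):
        window = s[start : start + length]
        tm = melting_temperature(window, salt_molar, strand_conc_molar)
        if tm_lo <= tm <= tm_hi:
            out.append(
                ProbeCandidate(
                    gene_id=gene_id,
                    start=start,
                    sequence=window,
                    tm_celsius=tm,
                    gc=gc_fraction(window),
                )
            )
    return out


def offtarget_filter(
    candidates: Sequence[ProbeCandidate], index: KmerIndex
) -> list[ProbeCandidate]:
    """Drop candidates with any 17-mer hit in a gene other than their own.

    The index must be built with k = 17 over the full transcriptome; a
    candidate is retained iff every 17-mer of its sequence maps only to its
    own gene.  The result does not depend on candidate input order.
    """
    if index.k != OFFTARGET_K:
        raise ValueError(f"off-target index must have k={OFFTARGET_K}, got {index.k}")
    kept = []
    for cand in candidates:
        clean = True
        for i in range(len(cand.sequence) - OFFTARGET_K + 1):
            hits = index.sources(cand.sequence[i : i + OFFTARGET_K])
            if hits - {cand.gene_id}:
                clean = False
                break
        if clean:
            kept.append(cand)
    return kept


def select_gene_probes(
    candidates: Sequence[ProbeCandidate],
    min_n: int = 17,
    max_n: int = 32,
) -> GeneProbeSet:
    """Greedy left-to-right selection of non-overlapping windows, capped at max_n.

    Greedy by ascending start is optimal for interval scheduling of
    equal-length windows, so the achieved count is the maximum attainable.
    A gene yielding fewer than ``min_n`` non-overlapping probes is rejected
    (reported, never silently dropped).
    """
    if not candidates:
        return GeneProbeSet(gene_id="", probes=[], accepted=False, achieved=0)
    gene_ids = {c.gene_id for c in candidates}
    if len(gene_ids) != 1:
        raise ValueError("candidates must all come from one gene")
    ordered = sorted(candidates, key=lambda c: c.start)
    chosen: list[ProbeCandidate] = []
    next_free = -1
    for cand in ordered:
        if cand.start >= next_free:
            chosen.append(cand)
            next_free = cand.start + len(cand.sequence)
            if len(chosen) == max_n:
                break
    gene_id = ordered[0].gene_id
    if len(chosen) < min_n:
        return GeneProbeSet(gene_id=gene_id, probes=[], accepted=False, achieved=len(chosen))
    return GeneProbeSet(gene_id=gene_id, probes=chosen, accepted=True, achieved=len(chosen))


def _kmers(sequence: str, k: int) -> set[str]:
    return {sequence[i : i + k] for i in range(len(sequence) - k + 1)}


def generate_readouts(
    n: int,
    length: int = 20,
    index: Optional[KmerIndex] = None,
    seed: int = 0,
    gc_lo: float = 0.40,
    gc_hi: float = 0.60,
    max_attempts_per_probe: int = 10_000,
) -> list[ReadoutProbe]:
    """Random orthogonal readout sequences.

    Each accepted readout has GC in [gc_lo, gc_hi] and shares no 10-mer on
    either strand with the reference ``index`` (k must be 10 when given) or
    with any previously accepted readout.  Deterministic for a fixed seed.

    Raises
    ------
    ReadoutGenerationError
        If the attempt budget runs out; carries the achieved count.
    """
    if length < READOUT_K:
        raise ValueError(f"readout length must be >= {READOUT_K}")
    if index is not None and index.k != READOUT_K:
        raise ValueError(f"reference index must have k={READOUT_K}, got {index.k}")

    rng = np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=(11,)))
    bases = np.array(list("ACGT"))
    accepted: list[ReadoutProbe] = []
    used_kmers: set[str] = set()
    attempts = 0
    budget = n * max_attempts_per_probe
    while len(accepted) < n:
        if attempts >= budget:
            raise ReadoutGenerationError(n, len(accepted))
        attempts += 1
        seq = "".join(rng.choice(bases, size=length))
        gc = gc_fraction(seq)
        if not (gc_lo <= gc <= gc_hi):
            continue
        both = _kmers(seq, READOUT_K) | _kmers(reverse_complement(seq), READOUT_K)
        if used_kmers & both:
            continue
        if index is not None and any(km in index for km in both):
            continue
        accepted.append(
            ReadoutProbe(readout_id=f"readout{len(accepted):02d}", sequence=seq, gc=gc)
        )
        used_kmers |= both
    return accepted


def design_probes(
    transcriptome: Mapping[str, str],
    tm_lo: float = 50.0,
    tm_hi: float = 80.0,
    min_n: int = 17,
    max_n: int = 32,
) -> tuple[dict[str, GeneProbeSet], KmerIndex]:
    """End-to-end primary-probe design against a gene → exonic-sequence map.

    Returns the per-gene selection outcome (accepted and rejected genes
    both present) and the 17-mer index used for the off-target screen.
    """
    index = build_kmer_index(transcriptome, k=OFFTARGET_K, include_reverse_complement=True)
    results: dict[str, GeneProbeSet] = {}
    for gene_id, seq in transcriptome.items():
        cands = candidate_windows(gene_id, seq, tm_lo=tm_lo, tm_hi=tm_hi)
        cands = offtarget_filter(cands, index)
        res = select_gene_probes(cands, min_n=min_n, max_n=max_n)
        if not res.gene_id:
            res.gene_id = gene_id
        results[gene_id] = res
    return results, index
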