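"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written in plain Python loops, deliberately avoiding
the package's own code paths and vectorised shortcuts, so agreement with
the package is evidence of correctness rather than tautology.
"""

from __future__ import annotations

import itertools
import math


# --------------------------------------------------------------------------
# sequences
# --------------------------------------------------------------------------

_COMP = str.maketrans("ACGT", "TGCA")


def revcomp(s: str) -> str:
    return s.translate(_COMP)[::-1]


def naive_gc(s: str) -> float:
    n = 0
    for ch in s:
        if ch in "GC":
            n += 1
    return n / len(s)


def naive_kmer_hit(query: str, k: int, subject: str, both_strands: bool = True) -> bool:
    """Does any k-mer of `query` occur in `subject` (either strand)?"""
    subjects = [subject, revcomp(subject)] if both_strands else [subject]
    for i in range(len(query) - k + 1):
        km = query[i : i + k]
        for sub in subjects:
            if km in sub:
                return True
    return False


def shared_kmer(a: str, b: str, k: int, both_strands: bool = True) -> bool:
    """Do two sequences share any k-mer, considering both strands of each?"""
    seen = set()
    for s in ([a, revcomp(a)] if both_strands else [a]):
        for i in range(len(s) - k + 1):
            seen.add(s[i : i + k])
    for s in ([b, revcomp(b)] if both_strands else [b]):
        for i in range(len(s) - k + 1):
            if s[i : i + k] in seen:
                return True
    return False


# SantaLucia 1998 unified nearest-neighbor parameters (dH kcal/mol, dS cal/mol/K)
_NN = {
    "AA": (-7.9, -22.2), "AT": (-7.2, -20.4), "TA": (-7.2, -21.3),
    "CA": (-8.5, -22.7), "GT": (-8.4, -22.4), "CT": (-7.8, -21.0),
    "GA": (-8.2, -22.2), "CG": (-10.6, -27.2), "GC": (-9.8, -24.4),
    "GG": (-8.0, -19.9),
}


def manual_nn_tm(seq: str, na_molar: float = 0.05, conc_molar: float = 250e-12) -> float:
    """Hand-summed nearest-neighbor melting temperature (°C).

    Unified duplex parameters with terminal-pair initiation, entropic
    monovalent-salt correction 0.368·(N−1)·ln[Na+], and the
    non-self-complementary concentration factor CT = c1 − c2/2.
    """
    dh, ds = 0.0, 0.0
    for end in (seq[0], seq[-1]):
        if end in "AT":
            dh += 2.3
            ds += 4.1
        else:
            dh += 0.1
            ds += -2.8
    for i in range(len(seq) - 1):
        pair = seq[i : i + 2]
        if pair not in _NN:
            pair = revcomp(pair)
        h, s = _NN[pair]
        dh += h
        ds += s
    ds += 0.368 * (len(seq) - 1) * math.log(na_molar)
    ct = conc_molar - conc_molar / 2.0
    return 1000.0 * dh / (ds + 1.987 * math.log(ct)) - 273.15


def exhaustive_interval_selection(starts: list[int], length: int) -> int:
    """Maximum number of mutually non-overlapping equal-length windows.

    Exhaustive search over all subsets; only usable for ~20 windows.
    """
    best = 0
    n = len(starts)
    for mask in range(1 << n):
        chosen = sorted(starts[i] for i in range(n) if mask >> i & 1)
        if all(b - a >= length for a, b in zip(chosen, chosen[1:])):
            best = max(best, len(chosen))
    return best


# --------------------------------------------------------------------------
# codes
# --------------------------------------------------------------------------

def naive_hamming(a, b) -> int:
    assert len(a) == len(b)
    d = 0
    for i in range(len(a)):
        if a[i] is None or b[i] is None or a[i] != b[i]:
            d += 1
    return d


# --------------------------------------------------------------------------
# decoding
# --------------------------------------------------------------------------

def _nearest(spots, anchor, rnd, radius, active):
    """(index of nearest spot of `rnd` within the closed ball, or None)."""
    best = None
    for i, s in enumerate(spots):
        if not active[i] or s["round"] != rnd:
            continue
        d = math.hypot(s["x"] - anchor["x"], s["y"] - anchor["y"])
        if d <= radius:
            key = (d, s["spot_id"])
            if best is None or key < best[0]:
                best = (key, i)
    return None if best is None else best[1]


def _neighbors(spots, anchor, rnd, radius, active):
    out = []
    for i, s in enumerate(spots):
        if not active[i] or s["round"] != rnd:
            continue
        d = math.hypot(s["x"] - anchor["x"], s["y"] - anchor["y"])
        if d <= radius:
            out.append(((d, s["spot_id"]), i))
    out.sort()
    return [i for _, i in out]


def _nearest_code(vector, code_by_gene, max_dist):
    best_d, best_genes = None, []
    for gene, colors in code_by_gene.items():
        d = naive_hamming(vector, colors)
        if best_d is None or d < best_d:
            best_d, best_genes = d, [gene]
        elif d == best_d:
            best_genes.append(gene)
    if best_d > max_dist:
        return None, None
    if len(best_genes) > 1:
        return "ambiguous", best_d
    return best_genes[0], best_d


def _pair_sum(spots, idxs):
    tot = 0.0
    for i, a in enumerate(idxs):
        for b in idxs[i + 1 :]:
            tot += math.hypot(
                spots[a]["x"] - spots[b]["x"], spots[a]["y"] - spots[b]["y"]
            )
    return tot


def oracle_decode_seed(spots, seed_round, code_by_gene, rounds, radius, max_hamming):
    """Reference per-seed decoding by exhaustive enumeration.

    `spots` is a list of dicts (spot_id, round, color, x, y), sorted by
    spot_id.  Returns a list of call dicts.
    """
    exact = {tuple(v): g for g, v in code_by_gene.items()}
    active = [True] * len(spots)
    other_rounds = [r for r in range(1, rounds + 1) if r != seed_round]
    calls = []

    # pass 1 on the full snapshot
    accepted = []
    for ai, a in enumerate(spots):
        if a["round"] != seed_round:
            continue
        members = {seed_round: ai}
        ok = True
        for rnd in other_rounds:
            m = _nearest(spots, a, rnd, radius, active)
            if m is None or _nearest(spots, spots[m], seed_round, radius, active) != ai:
                ok = False
                break
            members[rnd] = m
        if not ok:
            continue
        vec = tuple(spots[members[r]]["color"] for r in range(1, rounds + 1))
        if vec in exact:
            accepted.append((exact[vec], [members[r] for r in range(1, rounds + 1)]))
    for gene, idxs in accepted:
        calls.append(
            {
                "gene": gene,
                "seed": seed_round,
                "members": frozenset(spots[i]["spot_id"] for i in idxs),
                "hamming": 0,
                "dsum": _pair_sum(spots, idxs),
            }
        )
        for i in idxs:
            active[i] = False

    # pass 2, sequential in spot_id order
    for ai, a in enumerate(spots):
        if a["round"] != seed_round or not active[ai]:
            continue
        neigh = {r: _neighbors(spots, a, r, radius, active) for r in other_rounds}
        candidates = []
        for combo in itertools.product(*[[None] + neigh[r] for r in other_rounds]):
            chosen = dict(zip(other_rounds, combo))
            if sum(1 for v in chosen.values() if v is None) > max_hamming:
                continue
            vec = []
            for r in range(1, rounds + 1):
                if r == seed_round:
                    vec.append(a["color"])
                else:
                    m = chosen[r]
                    vec.append(None if m is None else spots[m]["color"])
            gene, hd = _nearest_code(vec, code_by_gene, max_hamming)
            if gene is None or gene == "ambiguous":
                continue
            idxs = [ai] + [m for m in combo if m is not None]
            candidates.append(
                (
                    len(idxs),
                    _pair_sum(spots, idxs),
                    tuple(sorted(spots[i]["spot_id"] for i in idxs)),
                    gene,
                    hd,
                    idxs,
                )
            )
        if not candidates:
            continue
        best_size = max(c[0] for c in candidates)
        tier = [c for c in candidates if c[0] == best_size]
        best_d = min(c[1] for c in tier)
        tier = [c for c in tier if c[1] == best_d]
        if len({c[3] for c in tier}) > 1:
            continue
        size, dsum, ids, gene, hd, idxs = min(tier, key=lambda c: c[2])
        calls.append(
            {"gene": gene, "seed": seed_round, "members": frozenset(ids),
             "hamming": hd, "dsum": dsum}
        )
        for i in idxs:
            active[i] = False
    return calls


def oracle_decode_fov(spots, code_by_gene, rounds, radius=1.2, max_hamming=1,
                      min_seeds=4):
    """Reference whole-FOV decoding; returns the called gene multiset."""
    spots = sorted(spots, key=lambda s: s["spot_id"])
    flat = []
    for seed_round in range(1, rounds + 1):
        flat.extend(
            oracle_decode_seed(spots, seed_round, code_by_gene, rounds, radius,
                               max_hamming)
        )
    # union-find merge: same gene + shared member spot
    parent = list(range(len(flat)))

    def find(i):
        while parent[i] != i:
            parent[i] = parent[parent[i]]
            i = parent[i]
        return i

    for i in range(len(flat)):
        for j in range(i + 1, len(flat)):
            if flat[i]["gene"] == flat[j]["gene"] and flat[i]["members"] & flat[j]["members"]:
                ri, rj = find(i), find(j)
                if ri != rj:
                    parent[max(ri, rj)] = min(ri, rj)

    groups = {}
    for i, call in enumerate(flat):
        groups.setdefault(find(i), []).append(call)

    merged = []
    for calls in groups.values():
        seeds = {c["seed"] for c in calls}
        if len(seeds) < min_seeds:
            continue
        members = frozenset().union(*(c["members"] for c in calls))
        merged.append(
            {
                "gene": calls[0]["gene"],
                "members": members,
                "support": len(seeds),
                "dsum": min(c["dsum"] for c in calls),
            }
        )
    merged.sort(
        key=lambda t: (-t["support"], t["dsum"], t["gene"], tuple(sorted(t["members"])))
    )
    used = set()
    genes = []
    for t in merged:
        if used & t["members"]:
            continue
        used |= t["members"]
        genes.append(t["gene"])
    return sorted(genes)


# --------------------------------------------------------------------------
# quantification / scoring
# --------------------------------------------------------------------------

def pairwise_dedup(cells, radius):
    """Reference duplicate-cell resolution by explicit pair enumeration.

    `cells` is a list of dicts (cell_id, fov, x, y, n). Returns retained ids.
    """
    pairs = []
    for i in range(len(cells)):
        for j in range(i + 1, len(cells)):
            a, b = cells[i], cells[j]
            if a["fov"] == b["fov"]:
                continue
            d = math.hypot(a["x"] - b["x"], a["y"] - b["y"])
            if d <= radius:
                lo, hi = sorted([a["cell_id"], b["cell_id"]])
                pairs.append((d, lo, hi))
    pairs.sort()
    info = {c["cell_id"]: c for c in cells}
    removed = set()
    for _, a, b in pairs:
        if a in removed or b in removed:
            continue
        ca, cb = info[a], info[b]
        if ca["n"] < cb["n"]:
            removed.add(a)
        elif cb["n"] < ca["n"]:
            removed.add(b)
        elif ca["fov"] != cb["fov"]:
            removed.add(a if ca["fov"] > cb["fov"] else b)
        else:
            removed.add(max(a, b))
    return [c["cell_id"] for c in cells if c["cell_id"] not in removed]


def double_loop_scores(values, labels, genes):
    """F, M, S per (type, gene) by explicit counting.

    `values` is a list of per-cell lists; returns dict
    (type, gene) -> (fraction, mean, score).
    """
    types = sorted(set(labels))
    out = {}
    for t in types:
        rows = [values[i] for i in range(len(labels)) if labels[i] == t]
        for gi, g in enumerate(genes):
            col = [r[gi] for r in rows]
            frac = sum(1 for v in col if v > 0) / len(col)
            mean = sum(col) / len(col)
            out[(t, g)] = (frac, mean, frac * mean)
    return out
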