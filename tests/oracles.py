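"""Independent brute-force oracles used by the test suite.

These deliberately avoid the implementation's algorithms: folding is
checked against exhaustive structure enumeration, clustering against an
O(n^2) pairwise pass, and target scanning against a position-by-position
checker.
"""

from __future__ import annotations

from srnapipe.fold import HAIRPIN_CLOSURE, MIN_LOOP, PAIR_ENERGY

_COMPL = {"A": "T", "C": "G", "G": "C", "T": "A"}
_WOBBLE = {("G", "T"), ("T", "G")}


def enumerate_min_energy(seq: str) -> float:
    """Minimum energy over all pseudoknot-free structures, by explicit
    enumeration of every pair set."""
    seq = seq.upper().replace("U", "T")
    n = len(seq)
    memo: dict[tuple[int, int], list[list[tuple[int, int]]]] = {}

    def structs(i: int, j: int):
        if (i, j) in memo:
            return memo[(i, j)]
        if j - i < MIN_LOOP + 1:
            memo[(i, j)] = [[]]
            return memo[(i, j)]
        out = list(structs(i + 1, j))
        for k in range(i + MIN_LOOP + 1, j + 1):
            if (seq[i], seq[k]) in PAIR_ENERGY:
                for inner in structs(i + 1, k - 1):
                    for rest in structs(k + 1, j):
                        out.append([(i, k)] + inner + rest)
        memo[(i, j)] = out
        return out

    def energy(pairs) -> float:
        e = 0.0
        for i, j in pairs:
            e += PAIR_ENERGY[(seq[i], seq[j])]
            if not any(i < a and b < j for a, b in pairs):
                e += HAIRPIN_CLOSURE
        return e

    return min(energy(p) for p in structs(0, n - 1))


def brute_force_clusters(seqs_with_libs, len_sim: float = 0.8):
    """O(n^2) reference clustering: longest-first assignment by direct
    pairwise substring checks, returning {representative: counts}."""
    from collections import Counter

    counts: dict[str, Counter] = {}
    for s, lib in seqs_with_libs:
        counts.setdefault(s.upper(), Counter())[lib] += 1
    uniq = sorted(counts, key=lambda s: (-len(s), s))
    assignment: dict[str, str] = {}
    reps: list[str] = []
    for s in uniq:
        chosen = None
        for r in reps:
            if len(s) / len(r) >= len_sim and r.find(s) != -1:
                chosen = r
                break
        if chosen is None:
            reps.append(s)
            assignment[s] = s
        else:
            assignment[s] = chosen
    out: dict[str, Counter] = {r: Counter() for r in reps}
    for s, r in assignment.items():
        out[r].update(counts[s])
    return {r: dict(c) for r, c in out.items()}


def plant_sites_by_scan(
    mirna: str,
    transcript: str,
    seed_defect_max: int = 1,
    rest_defect_max: int = 3,
    mfe_max: float = -20.0,
):
    """Position-by-position plant-mode site checker.

    For every placement, walk the antiparallel duplex base by base,
    counting defects and summing pair energies with explicit lookups.
    Returns (start, seed_defects, rest_defects, energy) tuples without
    overlap resolution.
    """
    m = mirna.upper().replace("U", "T")
    t = transcript.upper().replace("U", "T")
    L = len(m)
    hits = []
    for p in range(len(t) - L + 1):
        seed_d = rest_d = 0
        e = 0.0
        for i in range(L):
            tb = t[p + L - 1 - i]
            if _COMPL[m[i]] == tb:
                e += -3.0 if m[i] in "GC" else -2.0
            elif (m[i], tb) in _WOBBLE:
                e += -1.0
                if i < 8:
                    seed_d += 1
                else:
                    rest_d += 1
            else:
                if i < 8:
                    seed_d += 1
                else:
                    rest_d += 1
        if seed_d <= seed_defect_max and rest_d <= rest_defect_max and e <= mfe_max:
            hits.append((p, seed_d, rest_d, e))
    return hits


def animal_sites_by_scan(mirna: str, transcript: str):
    """Exhaustive 6-mer seed-site checker (reverse complement by hand)."""
    m = mirna.upper().replace("U", "T")
    t = transcript.upper().replace("U", "T")
    seed = m[1:7]
    rc = "".join(_COMPL[b] for b in reversed(seed))
    return [p for p in range(len(t) - 5) if t[p : p + 6] == rc]
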