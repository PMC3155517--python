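"""Secondary-structure prediction for hairpin screening.

The default engine is a dynamic program that minimizes a simple additive
energy: each base pair contributes a stability term (G:C -3.0, A:U -2.0,
G:U -1.0 kcal/mol) and every hairpin-loop closure costs +4.0 kcal/mol;
loops must span at least 3 unpaired nucleotides.  The model is a
deliberately transparent stand-in for a full nearest-neighbour treatment:
its minima can be verified by exhaustive enumeration on short sequences,
and the engine is pluggable so a thermodynamic folder (RNAfold) can be
substituted where available.
"""

from __future__ import annotations

import math
import shutil
import subprocess

import numpy as np

PAIR_ENERGY = {
    ("G", "C"): -3.0,
    ("C", "G"): -3.0,
    ("A", "T"): -2.0,
    ("T", "A"): -2.0,
    ("G", "T"): -1.0,
    ("T", "G"): -1.0,
}
HAIRPIN_CLOSURE = 4.0
MIN_LOOP = 3

_INF = math.inf


def _clean(seq: str) -> str:
    s = seq.upper().replace("U", "T")
    if any(b not in "ACGTN" for b in s):
        bad = sorted({b for b in s if b not in "ACGTN"})
        raise ValueError(f"invalid alphabet symbols {bad} in sequence")
    return s


def pair_energy(a: str, b: str) -> float:
    return PAIR_ENERGY.get((a, b), _INF)


def pair_table(structure: str) -> list[int]:
    """Partner index per position (-1 = unpaired) from dot-bracket."""
    pt = [-1] * len(structure)
    stack: list[int] = []
    for i, c in enumerate(structure):
        if c == "(":
            stack.append(i)
        elif c == ")":
            if not stack:
                raise ValueError("unbalanced structure string")
            j = stack.pop()
            pt[i], pt[j] = j, i
        elif c != ".":
            raise ValueError(f"invalid structure symbol {c!r}")
    if stack:
        raise ValueError("unbalanced structure string")
    return pt


def structure_energy(seq: str, structure: str) -> float:
    """Energy of a given structure under the simple additive model.

    A hairpin closure is a pair enclosing no other pair.
    """
    s = _clean(seq)
    if len(s) != len(structure):
        raise ValueError("sequence/structure length mismatch")
    pt = pair_table(structure)
    e = 0.0
    for i, j in ((i, pt[i]) for i in range(len(s)) if pt[i] > i):
        pe = pair_energy(s[i], s[j])
        if pe is _INF or not np.isfinite(pe):
            raise ValueError(f"non-pairable bases {s[i]}{s[j]} at {i},{j}")
        if j - i - 1 < MIN_LOOP and all(pt[k] == -1 for k in range(i + 1, j)):
            raise ValueError(f"hairpin loop shorter than {MIN_LOOP} at {i},{j}")
        e += pe
        if all(pt[k] == -1 for k in range(i + 1, j)):
            e += HAIRPIN_CLOSURE
    return e


class SimpleFoldEngine:
    """Built-in minimum-energy folder (see module docstring).

    ``fold`` returns a dot-bracket witness structure and the minimum
    energy.  Ties are broken deterministically (prefer pairing, smallest
    split point) so repeated runs give identical structures.
    """

    max_length = 400

    def fold(self, seq: str) -> tuple[str, float]:
        s = _clean(seq)
        n = len(s)
        if n == 0:
            return "", 0.0
        if n > self.max_length:
            raise ValueError(f"sequence longer than {self.max_length} nt")
        enc = np.frombuffer(s.encode(), dtype=np.uint8)
        # energy lookup: 5x5 table indexed by base codes (N never pairs)
        codes = np.full(256, 4, dtype=np.int8)
        for b, k in zip(b"ACGT", range(4)):
            codes[b] = k
        ecode = codes[enc]
        etab = np.full((5, 5), _INF)
        for (a, b), v in PAIR_ENERGY.items():
            etab["ACGT".index(a), "ACGT".index(b)] = v

        Wp = np.full((n, n), _INF)
        V = np.full((n, n), _INF)
        W = np.zeros((n, n))
        for d in range(MIN_LOOP + 1, n):
            i = np.arange(0, n - d)
            j = i + d
            pe = etab[ecode[i], ecode[j]]
            if d - 2 >= MIN_LOOP + 1:
                inner = Wp[i + 1, j - 1]
            else:
                inner = np.full(len(i), _INF)
            V[i, j] = pe + np.minimum(HAIRPIN_CLOSURE, inner)
            best = V[i, j].copy()
            for m in range(d):
                t1 = Wp[i, i + m] + W[i + m + 1, j]
                t2 = W[i, i + m] + Wp[i + m + 1, j]
                np.minimum(best, t1, out=best)
                np.minimum(best, t2, out=best)
            Wp[i, j] = best
            W[i, j] = np.minimum(best, 0.0)

        mfe = float(W[0, n - 1])
        struct = ["."] * n
        eps = 1e-9
        stack: list[tuple[int, int, str]] = [(0, n - 1, "W")]
        while stack:
            i, j, state = stack.pop()
            if j - i < MIN_LOOP + 1:
                continue
            if state == "W":
                if Wp[i, j] < -eps:
                    stack.append((i, j, "Wp"))
                continue
            if state == "Wp":
                if abs(Wp[i, j] - V[i, j]) < eps:
                    stack.append((i, j, "V"))
                    continue
                found = False
                for m in range(j - i):
                    k = i + m
                    if abs(Wp[i, j] - (Wp[i, k] + W[k + 1, j])) < eps:
                        stack.append((i, k, "Wp"))
                        stack.append((k + 1, j, "W"))
                        found = True
                        break
                    if abs(Wp[i, j] - (W[i, k] + Wp[k + 1, j])) < eps:
                        stack.append((i, k, "W"))
                        stack.append((k + 1, j, "Wp"))
                        found = True
                        break
                if not found:  # pragma: no cover - defensive
                    raise AssertionError("traceback failed")
                continue
            # state == "V": i pairs with j
            struct[i], struct[j] = "(", ")"
            inner = Wp[i + 1, j - 1] if j - 1 - (i + 1) >= MIN_LOOP + 1 else _INF
            if inner < HAIRPIN_CLOSURE - eps:
                stack.append((i + 1, j - 1, "Wp"))
            # else hairpin loop: nothing inside
        return "".join(struct), mfe


def fold_sequence(seq: str, engine=None) -> tuple[str, float]:
    """Fold one sequence with the given engine (default: built-in DP)."""
    return (engine or SimpleFoldEngine()).fold(seq)


class RNAfoldEngine:
    """Optional backend calling the ViennaRNA ``RNAfold`` executable."""

    max_length = 10000

    def __init__(self, executable: str = "RNAfold"):
        self.executable = executable
        if shutil.which(executable) is None:
            raise RuntimeError(f"{executable} not found on PATH")

    def fold(self, seq: str) -> tuple[str, float]:
        rna = _clean(seq).replace("T", "U")
        out = subprocess.run(
            [self.executable, "--noPS"],
            input=rna + "\n",
            capture_output=True,
            text=True,
            check=True,
        ).stdout.splitlines()
        line = out[1]
        struct = line.split()[0]
        mfe = float(line[line.rindex("(") + 1 : line.rindex(")")])
        return struct, mfe


def get_engine(name: str = "simple"):
    if name == "simple":
        return SimpleFoldEngine()
    if name == "rnafold":
        return RNAfoldEngine()
    raise ValueError(f"unknown fold engine {name!r}")
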