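"""miRNA target prediction on spliced transcripts.

Two binding modes are scanned.  Animal-like: a perfect reverse-
complement match of miRNA nucleotides 2-7 (the 6-mer seed).  Plant-like:
the full-length miRNA is placed ungapped against the transcript and
kept when the 8-nt 5' seed region carries at most one defect, the
remainder at most three, and the duplex energy is at most -20 kcal/mol.
A G:U wobble counts as a defect but still contributes -1 kcal/mol to the
duplex.  Sites are assigned to 5'UTR / CDS / 3'UTR by their midpoint
when the transcript carries start/stop-codon annotation, and target sets
are ranked for functional bias as the ratio of GO-term representation
among targets to the genome-wide representation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genome import GeneModel, as_dna, revcomp

HYBRID_MFE_MAX = -20.0
SEED_DEFECT_MAX = 1
REST_DEFECT_MAX = 3
SEED_REGION = (0, 8)  # miRNA positions 1-8 from the 5' end

# duplex pair energies; wobble G:U pairs get -1 but count as defects
_PAIR_E = {("G", "C"): -3.0, ("C", "G"): -3.0, ("A", "T"): -2.0, ("T", "A"): -2.0}
_WOBBLE_E = {("G", "T"): -1.0, ("T", "G"): -1.0}


@dataclass
class TargetHit:
    mirna_id: str
    transcript_id: str
    start: int  # transcript coordinates, half-open
    end: int
    mode: str  # animal | plant
    mismatches_in_seed: int = 0
    mismatches_outside: int = 0
    gaps: int = 0
    hybrid_mfe: float = 0.0
    region: str = "unknown"


def duplex_energy(mirna: str, site: str) -> float:
    """Energy of the ungapped antiparallel duplex of a miRNA over a
    transcript site (both given 5'->3'; equal lengths)."""
    m = as_dna(mirna)
    s = as_dna(site)
    e = 0.0
    for i, b in enumerate(m):
        t = s[len(s) - 1 - i]
        e += _PAIR_E.get((b, t), _WOBBLE_E.get((b, t), 0.0))
    return e


def scan_animal_sites(
    mirna_id: str, mirna: str, transcript_id: str, transcript: str
) -> list[TargetHit]:
    """All exact reverse-complement matches of miRNA nt 2-7."""
    m = as_dna(mirna)
    t = as_dna(transcript)
    if len(t) < 6 or len(m) < 7:
        return []
    motif = revcomp(m[1:7])
    hits = []
    p = t.find(motif)
    while p != -1:
        hits.append(
            TargetHit(
                mirna_id=mirna_id,
                transcript_id=transcript_id,
                start=p,
                end=p + 6,
                mode="animal",
                hybrid_mfe=duplex_energy(m[1:7], t[p : p + 6]),
            )
        )
        p = t.find(motif, p + 1)
    return hits


def scan_plant_sites(
    mirna_id: str,
    mirna: str,
    transcript_id: str,
    transcript: str,
    mfe_max: float = HYBRID_MFE_MAX,
    seed_defect_max: int = SEED_DEFECT_MAX,
    rest_defect_max: int = REST_DEFECT_MAX,
    resolve_overlaps: bool = True,
) -> list[TargetHit]:
    """Full-length ungapped plant-style sites.

    The duplex is modelled without bulges: miRNA position i pairs
    transcript position p + L - 1 - i for a site starting at p.  Defects
    are non-Watson-Crick positions (G:U wobbles included); budgets are
    independent for the seed (miRNA nt 1-8) and the remainder.  Among
    mutually overlapping candidate sites only the lowest-energy one is
    kept (leftmost on ties).
    """
    m = as_dna(mirna)
    t = as_dna(transcript)
    L = len(m)
    if L < 18:
        raise ValueError("plant-mode scanning requires miRNA length >= 18")
    n = len(t) - L + 1
    if n <= 0:
        return []
    code = np.full(256, 4, dtype=np.int8)
    for b, k in zip(b"ACGT", range(4)):
        code[b] = k
    tc = code[np.frombuffer(t.encode(), dtype=np.uint8)]
    mc = code[np.frombuffer(m.encode(), dtype=np.uint8)]
    etab = np.zeros((5, 5))
    ptab = np.zeros((5, 5), dtype=bool)  # Watson-Crick pair (not a defect)
    for (a, b), v in _PAIR_E.items():
        etab["ACGT".index(a), "ACGT".index(b)] = v
        ptab["ACGT".index(a), "ACGT".index(b)] = True
    for (a, b), v in _WOBBLE_E.items():
        etab["ACGT".index(a), "ACGT".index(b)] = v

    energy = np.zeros(n)
    seed_def = np.zeros(n, dtype=int)
    rest_def = np.zeros(n, dtype=int)
    s0, s1 = SEED_REGION
    for i in range(L):
        tpos = tc[L - 1 - i : L - 1 - i + n]
        energy += etab[mc[i], tpos]
        defect = ~ptab[mc[i], tpos]
        if s0 <= i < s1:
            seed_def += defect
        else:
            rest_def += defect
    ok = (seed_def <= seed_defect_max) & (rest_def <= rest_defect_max) & (
        energy <= mfe_max
    )
    hits = [
        TargetHit(
            mirna_id=mirna_id,
            transcript_id=transcript_id,
            start=int(p),
            end=int(p) + L,
            mode="plant",
            mismatches_in_seed=int(seed_def[p]),
            mismatches_outside=int(rest_def[p]),
            gaps=0,
            hybrid_mfe=float(energy[p]),
        )
        for p in np.nonzero(ok)[0]
    ]
    if resolve_overlaps:
        hits = _resolve_overlaps(hits)
    return hits


def _resolve_overlaps(hits: list[TargetHit]) -> list[TargetHit]:
    """Keep the lowest-energy site among mutually overlapping ones."""
    kept: list[TargetHit] = []
    for h in sorted(hits, key=lambda h: (h.hybrid_mfe, h.start)):
        if all(h.end <= k.start or h.start >= k.end for k in kept):
            kept.append(h)
    return sorted(kept, key=lambda h: h.start)


def assign_region(hit: TargetHit, gene: GeneModel) -> str:
    """5'UTR / CDS / 3'UTR by site midpoint, in transcript coordinates.

    Falls back to ``unknown`` when the transcript lacks start/stop-codon
    (UTR) annotation.
    """
    if not gene.has_utr_annotation:
        return "unknown"
    bounds = gene.cds_transcript_bounds()
    if bounds is None:
        return "unknown"
    cs, ce = bounds
    mid = (hit.start + hit.end - 1) // 2
    if mid < cs:
        return "five-utr"
    if mid >= ce:
        return "three-utr"
    return "cds"


def go_ratio(
    target_genes: set[str],
    go_map: dict[str, set[str]],
    all_genes: set[str],
) -> pd.DataFrame:
    """GO functional-bias ranking.

    For each term annotated on at least one target: the fraction of
    target genes carrying the term divided by the fraction of all genes
    carrying it, sorted by descending ratio.  Terms absent from the
    genome-wide set are excluded with a warning.
    """
    targets = target_genes & set(go_map)
    if not targets:
        return pd.DataFrame(
            columns=["term", "target_fraction", "genome_fraction", "ratio"]
        ).set_index("term")
    genome_terms: dict[str, int] = {}
    for g in all_genes:
        for term in go_map.get(g, ()):  # genome-wide term frequencies
            genome_terms[term] = genome_terms.get(term, 0) + 1
    rows = []
    target_terms: dict[str, int] = {}
    for g in targets:
        for term in go_map[g]:
            target_terms[term] = target_terms.get(term, 0) + 1
    for term, cnt in target_terms.items():
        if term not in genome_terms:
            warnings.warn(f"GO term {term} absent from the genome set; excluded")
            continue
        tf = cnt / len(target_genes)
        gf = genome_terms[term] / len(all_genes)
        rows.append((term, tf, gf, tf / gf))
    df = pd.DataFrame(rows, columns=["term", "target_fraction", "genome_fraction", "ratio"])
    return df.sort_values(["ratio", "term"], ascending=[False, True]).set_index("term")


def read_go_map(path) -> dict[str, set[str]]:
    """gene-id <TAB> GO:NNNNNNN, one pair per line."""
    out: dict[str, set[str]] = {}
    with open(path) as fh:
        for ln in fh:
            if not ln.strip() or ln.startswith("#"):
                continue
            gene, term = ln.rstrip("\n").split("\t")[:2]
            out.setdefault(gene, set()).add(term)
    return out
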