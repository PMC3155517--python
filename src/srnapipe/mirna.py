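"""miRNA candidate prediction.

A candidate mature tag (18-24 nt, not repeat-derived) is tested by
excising genomic precursors around each alignment, folding them, and
applying structural filters: the hairpin minimum free energy must be
below -20 kcal/mol, the terminal loop of the stem carrying the mature
arm must span at least 10 nt, the mature arm may not contain an
unpaired run longer than 3 nt, and the arm must lie on a single side of
the hairpin.  A passing locus is reported when the mature sequence is
seen in at least two libraries, or when a read from the predicted
miRNA* arm (the partner strand of the duplex, 2-nt 3' overhang) is seen
in any library.  Candidates are finally placed in exon / intron /
intergenic context and screened against known mature miRNAs by a
10-nt 5' seed comparison tolerating one mismatch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .fold import SimpleFoldEngine, pair_table
from .genome import GenomeBundle, revcomp
from .tags import Alignment, TagRecord

DEFAULT_FLANK = 100
DEFAULT_LEAD = 20
MFE_MAX = -20.0
LOOP_MIN = 10
BULGE_MAX = 3
STAR_TOL = 3
MIN_MATURE, MAX_MATURE = 18, 24


@dataclass
class HairpinCandidate:
    tag: TagRecord
    alignment: Alignment
    precursor_interval: tuple[str, int, int, str]
    precursor: str
    structure: str = ""
    mfe: float = 0.0
    loop_length: int = -1
    max_bulge: int = -1
    mature_span: tuple[int, int] = (0, 0)  # precursor coordinates
    star_interval: Alignment | None = None
    verdicts: dict[str, bool] = field(default_factory=dict)

    @property
    def passed(self) -> bool:
        return bool(self.verdicts) and all(self.verdicts.values())


@dataclass
class MirnaCall:
    mature: str
    tag: TagRecord
    alignment: Alignment
    candidate: HairpinCandidate
    star_sequence: str | None
    libraries_with_mature: list[str]
    libraries_with_star: list[str]
    locus_class: str  # exon | intron | intergenic
    seed_hits: list[tuple[str, int, int]] = field(default_factory=list)


def _max_unpaired_run(pt: list[int], start: int, end: int) -> int:
    run = best = 0
    for i in range(start, end):
        if pt[i] == -1:
            run += 1
            best = max(best, run)
        else:
            run = 0
    return best


def _walk_to_loop(pt: list[int], a: int, b: int) -> int | None:
    """Follow a stem inward from pair (a, b); return the terminal loop
    length, or None if the stem opens into a multiloop."""
    while True:
        inner = [k for k in range(a + 1, b) if pt[k] != -1 and a < pt[k] < b]
        if not inner:
            return b - a - 1
        k = min(inner)
        l = pt[k]
        if any(x > l for x in inner):
            return None  # branched interior: not a simple hairpin
        a, b = k, l


def assess_precursor(
    precursor: str,
    mature_span: tuple[int, int],
    engine=None,
    mfe_max: float = MFE_MAX,
    loop_min: int = LOOP_MIN,
    bulge_max: int = BULGE_MAX,
) -> dict:
    """Fold a precursor and apply the structural filters to the mature arm.

    Returns a dict with structure, mfe, loop_length, max_bulge,
    star_span (precursor coordinates, half-open, with 2-nt 3' extension)
    and per-filter verdicts.
    """
    engine = engine or SimpleFoldEngine()
    structure, mfe = engine.fold(precursor)
    pt = pair_table(structure)
    m0, m1 = mature_span
    out = {
        "structure": structure,
        "mfe": mfe,
        "loop_length": -1,
        "max_bulge": -1,
        "star_span": None,
        "verdicts": {"mfe": mfe < mfe_max},
    }
    partners = [pt[i] for i in range(m0, m1) if pt[i] != -1]
    if not partners:
        out["verdicts"].update(arm=False, loop=False, bulge=False)
        return out
    on_3p = all(p < m0 for p in partners)
    on_5p = all(p >= m1 for p in partners)
    out["verdicts"]["arm"] = on_3p or on_5p
    if not out["verdicts"]["arm"]:
        out["verdicts"].update(loop=False, bulge=False)
        return out
    out["max_bulge"] = _max_unpaired_run(pt, m0, m1)
    out["verdicts"]["bulge"] = out["max_bulge"] <= bulge_max
    # innermost mature pair: the one closest to the loop
    if on_5p:
        a = max(i for i in range(m0, m1) if pt[i] != -1)
        b = pt[a]
    else:
        b = min(i for i in range(m0, m1) if pt[i] != -1)
        a = pt[b]
        a, b = min(a, b), max(a, b)
    loop = _walk_to_loop(pt, a, b)
    out["loop_length"] = -1 if loop is None else loop
    out["verdicts"]["loop"] = loop is not None and loop >= loop_min
    smin, smax = min(partners), max(partners)
    out["star_span"] = (smin, min(len(precursor), smax + 1 + 2))
    return out


def excise_precursors(
    tag_len: int,
    aln: Alignment,
    genome: GenomeBundle,
    flank: int = DEFAULT_FLANK,
    lead: int = DEFAULT_LEAD,
) -> list[tuple[tuple[str, int, int, str], str, tuple[int, int]]]:
    """Both precursor excisions for one alignment.

    One places the mature tag near the 5' end of the precursor (star arm
    expected downstream), the other near the 3' end.  Returns
    (genome interval, precursor sequence oriented with the tag, mature
    span in precursor coordinates).
    """
    chrom_seq = genome.chromosomes[aln.chrom]
    n = len(chrom_seq)
    out = []
    if aln.strand == "+":
        windows = [
            (max(0, aln.start - lead), min(n, aln.end + flank)),
            (max(0, aln.start - flank), min(n, aln.end + lead)),
        ]
    else:
        windows = [
            (max(0, aln.start - flank), min(n, aln.end + lead)),
            (max(0, aln.start - lead), min(n, aln.end + flank)),
        ]
    for ws, we in windows:
        seq = chrom_seq[ws:we]
        if aln.strand == "+":
            m0 = aln.start - ws
        else:
            seq = revcomp(seq)
            m0 = we - aln.end
        out.append(((aln.chrom, ws, we, aln.strand), seq, (m0, m0 + tag_len)))
    return out


def _precursor_to_genome(
    interval: tuple[str, int, int, str], span: tuple[int, int]
) -> Alignment:
    chrom, ws, we, strand = interval
    s, e = span
    if strand == "+":
        return Alignment(chrom, ws + s, ws + e, strand)
    return Alignment(chrom, we - e, we - s, strand)


def evaluate_hairpin(
    tag: TagRecord,
    aln: Alignment,
    genome: GenomeBundle,
    engine=None,
    flank: int = DEFAULT_FLANK,
    mfe_max: float = MFE_MAX,
    loop_min: int = LOOP_MIN,
    bulge_max: int = BULGE_MAX,
) -> HairpinCandidate:
    """Evaluate both excisions at one alignment; keep the better one.

    A passing excision beats a failing one; among equals the lower
    folding energy wins.
    """
    best: HairpinCandidate | None = None
    for interval, seq, span in excise_precursors(tag.length, aln, genome, flank):
        res = assess_precursor(seq, span, engine, mfe_max, loop_min, bulge_max)
        cand = HairpinCandidate(
            tag=tag,
            alignment=aln,
            precursor_interval=interval,
            precursor=seq,
            structure=res["structure"],
            mfe=res["mfe"],
            loop_length=res["loop_length"],
            max_bulge=res["max_bulge"],
            mature_span=span,
            star_interval=(
                _precursor_to_genome(interval, res["star_span"])
                if res["star_span"]
                else None
            ),
            verdicts=res["verdicts"],
        )
        if (
            best is None
            or (cand.passed and not best.passed)
            or (cand.passed == best.passed and cand.mfe < best.mfe)
        ):
            best = cand
    assert best is not None
    return best


def evidence_ok(n_libraries_with_mature: int, star_seen: bool) -> bool:
    """Expression-evidence rule: mature in >=2 libraries, or a miRNA*
    read in at least one library."""
    return n_libraries_with_mature >= 2 or star_seen


def overlaps_repeat(tag: TagRecord, genome: GenomeBundle) -> bool:
    return any(
        genome.annotations.repeat_tree(a.chrom).overlap(a.start, a.end)
        for a in tag.alignments
    )


def locus_class(tag: TagRecord, genome: GenomeBundle) -> str:
    """Exon / intron / intergenic context, majority vote over alignments
    with precedence exon > intron > intergenic at each alignment."""
    votes = {"exon": 0, "intron": 0, "intergenic": 0}
    for a in tag.alignments:
        ann = genome.annotations
        if ann.exon_tree(a.chrom).overlap(a.start, a.end):
            votes["exon"] += 1
        elif ann.gene_tree(a.chrom).overlap(a.start, a.end):
            votes["intron"] += 1
        else:
            votes["intergenic"] += 1
    return max(votes, key=lambda k: (votes[k], -["exon", "intron", "intergenic"].index(k)))


def _has_nearby_tag(tag: TagRecord, tags: list[TagRecord], dist: int) -> bool:
    for a in tag.alignments:
        for t in tags:
            if t.sequence == tag.sequence:
                continue
            for b in t.alignments:
                if (
                    b.chrom == a.chrom
                    and b.strand == a.strand
                    and b.start < a.end + dist
                    and b.end > a.start - dist
                ):
                    return True
    return False


def _find_star_tags(
    star: Alignment, tags: list[TagRecord], exclude: str, tol: int = STAR_TOL
) -> list[TagRecord]:
    hits = []
    for t in tags:
        if t.sequence == exclude:
            continue
        for a in t.alignments:
            if (
                a.chrom == star.chrom
                and a.strand == star.strand
                and abs(a.start - star.start) <= tol
                and abs(a.end - star.end) <= tol
            ):
                hits.append(t)
                break
    return hits


def predict_mirnas(
    tags: list[TagRecord],
    genome: GenomeBundle,
    engine=None,
    flank: int = DEFAULT_FLANK,
    mfe_max: float = MFE_MAX,
    loop_min: int = LOOP_MIN,
    bulge_max: int = BULGE_MAX,
    star_tol: int = STAR_TOL,
) -> list[MirnaCall]:
    engine = engine or SimpleFoldEngine()
    calls: list[MirnaCall] = []
    for tag in tags:
        if not (MIN_MATURE <= tag.length <= MAX_MATURE):
            continue
        if "degradation" in tag.flags or not tag.alignments:
            continue
        if overlaps_repeat(tag, genome):
            continue
        # cheap evidence screen first: folding is the expensive step and
        # a tag with one library and no possible star read can never be called
        libs = tag.libraries()
        if len(libs) < 2 and not _has_nearby_tag(tag, tags, flank + 2 * STAR_TOL):
            continue
        best: HairpinCandidate | None = None
        for aln in sorted(tag.alignments):
            cand = evaluate_hairpin(
                tag, aln, genome, engine, flank, mfe_max, loop_min, bulge_max
            )
            if cand.passed:
                best = cand
                break
        if best is None:
            continue
        star_tags = (
            _find_star_tags(best.star_interval, tags, tag.sequence, star_tol)
            if best.star_interval
            else []
        )
        star_libs = sorted({lib for t in star_tags for lib in t.libraries()})
        if not evidence_ok(len(libs), bool(star_tags)):
            continue
        star_seq = None
        if star_tags:
            star_seq = max(star_tags, key=lambda t: (t.total_count, t.sequence)).sequence
        calls.append(
            MirnaCall(
                mature=tag.sequence,
                tag=tag,
                alignment=best.alignment,
                candidate=best,
                star_sequence=star_seq,
                libraries_with_mature=sorted(libs),
                libraries_with_star=star_libs,
                locus_class=locus_class(tag, genome),
            )
        )
    return _dedup_duplexes(calls, star_tol)


def _dedup_duplexes(calls: list[MirnaCall], tol: int) -> list[MirnaCall]:
    """Collapse mature/star pairs called from the same hairpin.

    When two calls each sit on the other's predicted star arm they are two
    arms of one duplex; the more abundant tag is kept as the mature call.
    """

    def on_star(a: Alignment, star: Alignment | None) -> bool:
        return (
            star is not None
            and a.chrom == star.chrom
            and a.strand == star.strand
            and abs(a.start - star.start) <= tol
            and abs(a.end - star.end) <= tol
        )

    drop: set[int] = set()
    for i, x in enumerate(calls):
        for j in range(i + 1, len(calls)):
            y = calls[j]
            if on_star(x.alignment, y.candidate.star_interval) and on_star(
                y.alignment, x.candidate.star_interval
            ):
                keep_x = (x.tag.total_count, y.mature) >= (y.tag.total_count, x.mature)
                drop.add(j if keep_x else i)
    return [c for k, c in enumerate(calls) if k not in drop]


def match_known_mirnas(
    calls: list[MirnaCall],
    known: dict[str, str],
    seed_len: int = 10,
    max_mismatch: int = 1,
) -> None:
    """Annotate calls with known-miRNA seed hits, in place.

    A hit is an ungapped placement of the first ``seed_len`` nt of a known
    mature miRNA on the candidate with at most ``max_mismatch`` mismatches
    (90% identity over 10 nt).
    """
    for call in calls:
        cand = call.mature.upper().replace("U", "T")
        hits = []
        for name, seq in known.items():
            seed = seq.upper().replace("U", "T")[:seed_len]
            if len(seed) < seed_len or len(cand) < seed_len:
                continue
            best = None
            for off in range(len(cand) - seed_len + 1):
                mm = sum(1 for a, b in zip(seed, cand[off : off + seed_len]) if a != b)
                if best is None or mm < best[1]:
                    best = (off, mm)
            if best is not None and best[1] <= max_mismatch:
                hits.append((name, best[0], best[1]))
        call.seed_hits = sorted(hits)
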