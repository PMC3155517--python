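"""From raw reads to mapped unique tags.

454-style reads are stripped of their flanking linkers (Nelson 5',
Modban 3'); a linker may lack up to 3 terminal nucleotides but internal
errors are not tolerated.  SOLiD reads are decoded from colorspace and
rescued by alignment-trimming: the longest genomic match anchored at the
read start determines the true insert length, discarding the adapter
continuation that pads every 35-color read.  Surviving inserts are
collapsed to unique tags (a shorter sequence joins a longer one when it
is an exact substring covering at least 80% of its length), screened
against an rRNA/tRNA reference to drop degradation products, and mapped
back to the genome allowing one mismatch.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

import pandas as pd

from .genome import GenomeBundle, revcomp
from .tags import Alignment, TagRecord

NELSON_5P = "ATCGTAGGCACCTGAAA"
MODBAN_3P = "ACTGTAGGCACCATCAAT"

DEFAULT_MAX_MISSING = 4  # reads with >= this many missing linker nt are dropped
DEFAULT_MIN_INSERT = 16
DEFAULT_LEN_SIM = 0.8
DEFAULT_DEGR_COV = 0.70
DEFAULT_DEGR_IDENT = 0.90


@dataclass(frozen=True)
class Rejection:
    read_id: str
    reason: str


# ----------------------------------------------------------------------
# 454 adapter excision


def trim_454_adapters(
    seq: str,
    five_adapter: str = NELSON_5P,
    three_adapter: str = MODBAN_3P,
    max_missing: int = DEFAULT_MAX_MISSING,
) -> tuple[str | None, str | None]:
    """Excise the insert between the two linkers.

    Returns (insert, None) on success or (None, reason).  A linker match
    may lack up to ``max_missing - 1`` terminal nucleotides (the 5' end
    of the 5' linker, the 3' end of the 3' linker); no internal
    mismatches are allowed.
    """
    seq = seq.upper()
    start = None
    for miss in range(max_missing):
        stub = five_adapter[miss:]
        if stub and seq.startswith(stub):
            start = len(stub)
            break
    if start is None:
        return None, "no-5-adapter"
    end = None
    for miss in range(max_missing):
        stub = three_adapter[: len(three_adapter) - miss]
        if stub and seq.endswith(stub):
            end = len(seq) - len(stub)
            break
    if end is None:
        return None, "no-3-adapter"
    if end <= start:
        return None, "empty-insert"
    return seq[start:end], None


# ----------------------------------------------------------------------
# genome k-mer index and SOLiD alignment-trimming


class KmerIndex:
    """Exact k-mer location index over the forward genome strands."""

    def __init__(self, genome: GenomeBundle, k: int):
        self.k = k
        self.genome = genome
        self.index: dict[str, list[tuple[str, int]]] = defaultdict(list)
        for chrom, seq in sorted(genome.chromosomes.items()):
            for i in range(len(seq) - k + 1):
                self.index[seq[i : i + k]].append((chrom, i))

    def positions(self, kmer: str) -> list[tuple[str, int]]:
        return self.index.get(kmer, [])


def _mismatch_positions(a: str, b: str, limit: int) -> list[int] | None:
    """Positions where a and b differ, or None once ``limit`` is exceeded."""
    out = []
    for i, (x, y) in enumerate(zip(a, b)):
        if x != y:
            out.append(i)
            if len(out) > limit:
                return None
    return out


def align_trim_solid(
    decoded: str,
    index: KmerIndex,
    min_insert: int = DEFAULT_MIN_INSERT,
) -> tuple[list[tuple[str, Alignment]], str | None]:
    """Rescue a decoded SOLiD read by its longest anchored genomic match.

    The match must start at read position 0 (sequencing proceeds from the
    ligation site) on either strand.  Retained if (a) a perfect match of
    extent >= min_insert, trimmed to that extent, or failing that (b) the
    full read matches with exactly one mismatch.  Returns the list of
    equally-best (insert, alignment) placements, or a rejection reason.
    """
    decoded = decoded.upper()
    L = len(decoded)
    k = index.k
    if L < max(k, min_insert):
        return [], "too-short"

    best_perfect: list[tuple[str, Alignment]] = []
    best_extent = 0
    one_mm: list[tuple[str, Alignment]] = []

    for strand in "+-":
        query = decoded if strand == "+" else revcomp(decoded)
        # seeds anchored at both ends of the read cover a mismatch in
        # either half when testing the 1-mismatch full-length case
        seeds = {0, L - k} if L >= 2 * k else {0}
        cand: set[tuple[str, int]] = set()
        for off in seeds:
            for chrom, pos in index.positions(query[off : off + k]):
                cand.add((chrom, pos - off))
        for chrom, gstart in sorted(cand):
            seq = index.genome.chromosomes[chrom]
            if gstart < 0 or gstart + L > len(seq):
                continue
            window = seq[gstart : gstart + L]
            mm = _mismatch_positions(window, query, 1)
            if mm is None:
                mmpos = None
            else:
                mmpos = mm
            # perfect anchored prefix extent in *read* orientation
            if strand == "+":
                read_win = window
            else:
                read_win = revcomp(window)
            ext = 0
            while ext < L and read_win[ext] == decoded[ext]:
                ext += 1
            if ext >= min_insert:
                insert = decoded[:ext]
                if strand == "+":
                    aln = Alignment(chrom, gstart, gstart + ext, "+", 0)
                else:
                    aln = Alignment(chrom, gstart + L - ext, gstart + L, "-", 0)
                if ext > best_extent:
                    best_extent = ext
                    best_perfect = [(insert, aln)]
                elif ext == best_extent and (insert, aln) not in best_perfect:
                    best_perfect.append((insert, aln))
            if mmpos is not None and len(mmpos) == 1:
                one_mm.append((decoded, Alignment(chrom, gstart, gstart + L, strand, 1)))

    if best_perfect:
        return sorted(best_perfect, key=lambda x: x[1]), None
    if one_mm:
        return sorted(one_mm, key=lambda x: x[1]), None
    return [], "unmapped"


# ----------------------------------------------------------------------
# redundancy clustering


def cluster_unique(
    inserts: list[tuple[str, str]], len_sim: float = DEFAULT_LEN_SIM
) -> list[TagRecord]:
    """Collapse inserts into unique tags.

    A sequence joins an existing cluster when it is an exact substring of
    the representative and covers at least ``len_sim`` of its length
    (CD-HIT at 100% identity, length cutoff 0.8).  Representatives are
    assigned longest-first (ties lexicographic) so the representative is
    always the longest member.
    """
    counts: dict[str, Counter] = defaultdict(Counter)
    for seq, lib in inserts:
        counts[seq.upper()][lib] += 1
    order = sorted(counts, key=lambda s: (-len(s), s))
    reps: list[str] = []
    members: dict[str, list[str]] = {}
    for seq in order:
        home = None
        for rep in reps:
            if len(seq) >= len_sim * len(rep) and seq in rep:
                home = rep
                break
        if home is None:
            reps.append(seq)
            members[seq] = [seq]
        else:
            members[home].append(seq)
    tags = []
    for rep in reps:
        agg: Counter = Counter()
        for m in members[rep]:
            agg.update(counts[m])
        tags.append(TagRecord(sequence=rep, counts=dict(agg)))
    return tags


# ----------------------------------------------------------------------
# degradation filtering


def _best_local_hit(tag: str, ref: str, aligner) -> tuple[float, float, float]:
    """(score, identity, tag-coverage) of the best local alignment of the
    tag (either orientation) against one reference sequence."""
    best = (0.0, 0.0, 0.0)
    for query in (tag, revcomp(tag)):
        alns = aligner.align(ref, query)
        if len(alns) == 0 or alns.score <= 0:
            continue
        aln = alns[0]
        tcoords, qcoords = aln.aligned
        matches = 0
        cols = 0
        for (ts, te), (qs, qe) in zip(tcoords, qcoords):
            cols += te - ts
            matches += sum(1 for i in range(te - ts) if ref[ts + i] == query[qs + i])
        if cols == 0:
            continue
        # identity over the full local alignment length, gap columns included
        qspan = qcoords[-1][1] - qcoords[0][0]
        tspan = tcoords[-1][1] - tcoords[0][0]
        length = cols + (qspan - cols) + (tspan - cols)
        identity = matches / length
        coverage = qspan / len(tag)
        if aln.score > best[0]:
            best = (float(aln.score), identity, coverage)
    return best


def filter_degradation(
    tags: list[TagRecord],
    ncrna_ref: list[tuple[str, str, str]],
    coverage_min: float = DEFAULT_DEGR_COV,
    identity_min: float = DEFAULT_DEGR_IDENT,
) -> tuple[list[TagRecord], list[TagRecord]]:
    """Remove rRNA/tRNA degradation products.

    ``ncrna_ref`` holds (id, class_label, sequence) records.  A tag is
    removed when a local alignment to an rRNA/tRNA/"ribosomal" reference
    covers >= coverage_min of the tag at >= identity_min identity; a tag
    whose best-scoring reference hit is annotated miRNA is always kept.
    Returns (kept, removed); removed tags carry the ``degradation`` flag.
    """
    from Bio import Align

    aligner = Align.PairwiseAligner(
        mode="local",
        match_score=1,
        mismatch_score=-1,
        open_gap_score=-2,
        extend_gap_score=-1,
    )
    degr_classes = {"rRNA", "tRNA", "ribosomal"}
    kept, removed = [], []
    for tag in tags:
        best_score = 0.0
        best_class = None
        flagged = False
        for _, cls, seq in ncrna_ref:
            score, ident, cov = _best_local_hit(tag.sequence, seq, aligner)
            if score > best_score:
                best_score, best_class = score, cls
            if cls in degr_classes and cov >= coverage_min and ident >= identity_min:
                flagged = True
        if flagged and best_class != "miRNA":
            tag.flags.add("degradation")
            removed.append(tag)
        else:
            kept.append(tag)
    return kept, removed


# ----------------------------------------------------------------------
# genome mapping


def map_to_genome(
    tags: list[TagRecord],
    index: KmerIndex,
    max_mismatch: int = 1,
) -> tuple[list[TagRecord], list[TagRecord]]:
    """Record every genomic occurrence of each tag with <= 1 mismatch.

    Both strands are searched; tags without any such occurrence are
    returned separately (reason: unmapped).
    """
    k = index.k
    kept, dropped = [], []
    for tag in tags:
        seq = tag.sequence
        L = len(seq)
        alns: set[Alignment] = set()
        if L >= 2 * k or (max_mismatch == 0 and L >= k):
            for strand in "+-":
                query = seq if strand == "+" else revcomp(seq)
                cand: set[tuple[str, int]] = set()
                offsets = (0, k) if L >= 2 * k else (0,)
                for off in offsets:
                    for chrom, pos in index.positions(query[off : off + k]):
                        cand.add((chrom, pos - off))
                for chrom, gstart in cand:
                    cseq = index.genome.chromosomes[chrom]
                    if gstart < 0 or gstart + L > len(cseq):
                        continue
                    mm = _mismatch_positions(cseq[gstart : gstart + L], query, max_mismatch)
                    if mm is not None:
                        alns.add(Alignment(chrom, gstart, gstart + L, strand, len(mm)))
        tag.alignments = sorted(alns)
        if tag.alignments:
            kept.append(tag)
        else:
            tag.flags.add("unmapped")
            dropped.append(tag)
    return kept, dropped


# ----------------------------------------------------------------------
# statistics


def tag_stats(tags: list[TagRecord]) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-library length histogram and 5' nucleotide frequency table.

    Both are computed over unique sequences (a tag counts once per
    library in which it was observed); 5' frequencies are reported in RNA
    letters and sum to 1 per library.
    """
    libs = sorted({lib for t in tags for lib in t.libraries()})
    length_counts: dict[str, Counter] = {lib: Counter() for lib in libs}
    nt_counts: dict[str, Counter] = {lib: Counter() for lib in libs}
    for t in tags:
        first = t.sequence[0].replace("T", "U")
        for lib in t.libraries():
            length_counts[lib][t.length] += 1
            nt_counts[lib][first] += 1
    lengths = sorted({l for c in length_counts.values() for l in c})
    len_df = pd.DataFrame(
        {lib: [length_counts[lib].get(l, 0) for l in lengths] for lib in libs},
        index=pd.Index(lengths, name="length"),
    )
    nts = ["A", "C", "G", "U"]
    nt_df = pd.DataFrame(
        {
            lib: [
                nt_counts[lib].get(nt, 0) / max(1, sum(nt_counts[lib].values()))
                for nt in nts
            ]
            for lib in libs
        },
        index=pd.Index(nts, name="nt5"),
    )
    return len_df, nt_df
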