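"""Endogenous siRNA classification.

Tags that are not miRNA candidates are classified with repeat
precedence: any alignment overlapping an annotated repeat makes the tag
a repeat-associated siRNA (rasiRNA), tabulated by transposable-element
family.  The remainder are oriented against the gene models: sense
(overlapping a gene span on the same strand), antisense (opposite
strand), intergenic, or mixed when different alignments disagree.
Cross-platform agreement of rasiRNA sets is estimated by ungapped local
alignment with a BLAST-style E-value cutoff.
"""

from __future__ import annotations

import math
import warnings
from collections import Counter, defaultdict
from dataclasses import dataclass, field

import pandas as pd

from .genome import GenomeBundle, revcomp
from .tags import TagRecord

# Karlin-Altschul constants for ungapped +1/-3 nucleotide scoring
LAMBDA = 1.33
KAPPA = 0.621
DEFAULT_EVALUE = 1e-5
MIN_REPEAT_OVERLAP = 1


@dataclass
class SirnaCall:
    tag: TagRecord
    klass: str  # rasirna | nat-sense | nat-antisense | intergenic | mixed
    repeat_family: str | None = None
    sub_labels: list[str] = field(default_factory=list)  # per alignment


def call_rasirna(
    tags: list[TagRecord],
    genome: GenomeBundle,
    min_overlap: int = MIN_REPEAT_OVERLAP,
) -> tuple[list[SirnaCall], pd.DataFrame]:
    """rasiRNA calls plus the per-library repeat-family percentage table.

    A tag is repeat-associated when any alignment overlaps a repeat
    interval by at least ``min_overlap`` nt.  The family table counts
    unique tags per repeat class per library; columns sum to 100.
    """
    calls = []
    fam_counts: dict[str, Counter] = defaultdict(Counter)
    for tag in tags:
        families = []
        for a in tag.alignments:
            for iv in genome.annotations.repeat_tree(a.chrom).overlap(a.start, a.end):
                if min(iv.end, a.end) - max(iv.begin, a.start) >= min_overlap:
                    families.append(iv.data.class_label)
        if not families:
            continue
        family = Counter(families).most_common(1)[0][0]
        calls.append(SirnaCall(tag=tag, klass="rasirna", repeat_family=family))
        for lib in tag.libraries():
            fam_counts[lib][family] += 1
    libs = sorted(fam_counts)
    classes = sorted({f for c in fam_counts.values() for f in c})
    table = pd.DataFrame(
        {
            lib: [
                100.0 * fam_counts[lib].get(cls, 0) / max(1, sum(fam_counts[lib].values()))
                for cls in classes
            ]
            for lib in libs
        },
        index=pd.Index(classes, name="repeat_class"),
    )
    return calls, table


def _best_ungapped_score(a: str, b: str, match: int = 1, mismatch: int = -3) -> int:
    """Best ungapped local alignment score between two sequences
    (forward orientation), by Kadane's rule over every diagonal."""
    best = 0
    la, lb = len(a), len(b)
    for off in range(-(la - 1), lb):
        run = 0
        for i in range(max(0, -off), min(la, lb - off)):
            run = max(0, run) + (match if a[i] == b[i + off] else mismatch)
            best = max(best, run)
    return best


def cross_library_match(
    set_a: list[TagRecord],
    set_b: list[TagRecord],
    evalue_max: float = DEFAULT_EVALUE,
    lam: float = LAMBDA,
    kappa: float = KAPPA,
) -> float:
    """Fraction of tags in A with an ungapped match in B at E <= cutoff.

    E = K * m * n * exp(-lambda * S) with m the query length and n the
    total length of set B.  Both orientations of the query are tried.
    The measure is asymmetric in (A, B) by construction.
    """
    if not set_b:
        warnings.warn("empty comparison set: match fraction is 0")
        return 0.0
    n_db = sum(t.length for t in set_b)
    matched = 0
    for qa in set_a:
        m = qa.length
        # smallest score that can reach the cutoff for this query
        s_needed = math.log(kappa * m * n_db / evalue_max) / lam
        hit = False
        for query in (qa.sequence, revcomp(qa.sequence)):
            for tb in set_b:
                s = _best_ungapped_score(query, tb.sequence)
                if s >= s_needed:
                    hit = True
                    break
            if hit:
                break
        if hit:
            matched += 1
    return matched / len(set_a) if set_a else 0.0


def classify_nat_sirna(
    tags: list[TagRecord], genome: GenomeBundle
) -> tuple[list[SirnaCall], pd.DataFrame]:
    """Orient non-repeat, non-miRNA tags against the gene models.

    Per alignment: sense when overlapping a gene span on the same strand,
    antisense on the opposite strand, intergenic otherwise.  The
    tag-level class is the single sub-label, or ``mixed``.  Gene overlap
    uses the full gene span (pre-mRNA, introns included) since antisense
    pairing acts on the primary transcript.
    """
    calls = []
    for tag in tags:
        subs = []
        for a in tag.alignments:
            genes = genome.annotations.gene_tree(a.chrom).overlap(a.start, a.end)
            if not genes:
                subs.append("intergenic")
            else:
                strands = {iv.data.strand for iv in genes}
                if a.strand in strands:
                    subs.append("nat-sense")
                else:
                    subs.append("nat-antisense")
        klass = subs[0] if len(set(subs)) == 1 else "mixed"
        calls.append(SirnaCall(tag=tag, klass=klass, sub_labels=subs))
    return calls, summarize_distribution({c.tag.sequence: c.klass for c in calls}, tags)


def summarize_distribution(
    class_by_seq: dict[str, str], tags: list[TagRecord]
) -> pd.DataFrame:
    """Percentage of tags per class per library (unique-tag weighting)."""
    libs = sorted({lib for t in tags for lib in t.libraries()})
    counts: dict[str, Counter] = {lib: Counter() for lib in libs}
    for t in tags:
        klass = class_by_seq.get(t.sequence)
        if klass is None:
            continue
        for lib in t.libraries():
            counts[lib][klass] += 1
    classes = sorted({k for c in counts.values() for k in c})
    return pd.DataFrame(
        {
            lib: [
                100.0 * counts[lib].get(cls, 0) / max(1, sum(counts[lib].values()))
                for cls in classes
            ]
            for lib in libs
        },
        index=pd.Index(classes, name="class"),
    )


def distribution_summary(
    tags: list[TagRecord],
    mirna_sequences: set[str],
    rasirna_calls: list[SirnaCall],
    nat_calls: list[SirnaCall],
    weighting: str = "unique",
) -> pd.DataFrame:
    """Full per-library class distribution over all mapped tags.

    Classes: mirna, rasirna, nat-sense, nat-antisense, intergenic, mixed.
    Percentages per library sum to 100.  ``weighting`` is "unique"
    (tags) or "reads" (library read counts).
    """
    klass: dict[str, str] = {}
    for seq in mirna_sequences:
        klass[seq] = "mirna"
    for c in rasirna_calls:
        klass.setdefault(c.tag.sequence, "rasirna")
    for c in nat_calls:
        klass.setdefault(c.tag.sequence, c.klass)
    libs = sorted({lib for t in tags for lib in t.libraries()})
    counts: dict[str, Counter] = {lib: Counter() for lib in libs}
    for t in tags:
        cls = klass.get(t.sequence)
        if cls is None:
            continue
        for lib in t.libraries():
            w = t.counts.get(lib, 0) if weighting == "reads" else 1
            counts[lib][cls] += w
    classes = sorted({k for c in counts.values() for k in c})
    return pd.DataFrame(
        {
            lib: [
                100.0 * counts[lib].get(cls, 0) / max(1, sum(counts[lib].values()))
                for cls in classes
            ]
            for lib in libs
        },
        index=pd.Index(classes, name="class"),
    )
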