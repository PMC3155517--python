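"""Genome and annotation model plus readers for the external formats.

All coordinates are 0-based half-open internally.  GFF3 (1-based closed)
and RepeatMasker ``.out`` (1-based closed) are converted at the I/O
boundary and converted back on write.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field

from Bio import SeqIO
from intervaltree import IntervalTree

COMPLEMENT = str.maketrans("ACGTUNacgtun", "TGCAANtgcaan")


def revcomp(seq: str) -> str:
    return seq.translate(COMPLEMENT)[::-1]


def as_dna(seq: str) -> str:
    return seq.upper().replace("U", "T")


from .errors import FormatError, ValidationError  # noqa: F401  (re-exported)


#: RepeatMasker family name -> controlled repeat class vocabulary.  Keys
#: already containing a class prefix (``LTR/Copia``) pass through untouched.
REPEAT_CLASS_MAP = {
    "Copia": "LTR/Copia",
    "Gypsy": "LTR/Gypsy",
    "Harbinger": "DNA/Harbinger",
    "PIF-Harbinger": "DNA/Harbinger",
    "MuDR": "DNA/MuDR",
    "MULE-MuDR": "DNA/MuDR",
    "hAT": "DNA/hAT",
    "Mariner": "DNA/TcMar",
    "TcMar": "DNA/TcMar",
    "L1": "LINE/L1",
    "LINE": "LINE/L1",
    "Simple_repeat": "Simple_repeat",
    "Low_complexity": "Low_complexity",
}


def repeat_class(family: str) -> str:
    if "/" in family:
        return family
    return REPEAT_CLASS_MAP.get(family, f"Unknown/{family}")


@dataclass(frozen=True)
class RepeatInterval:
    chrom: str
    start: int
    end: int
    strand: str
    family: str
    class_label: str


@dataclass(frozen=True)
class NcRnaInterval:
    chrom: str
    start: int
    end: int
    strand: str
    class_label: str  # rRNA | tRNA | miRNA | other


@dataclass
class GeneModel:
    """A protein-coding gene: exon chain, CDS and optional UTR intervals."""

    gene_id: str
    chrom: str
    strand: str
    exons: list[tuple[int, int]]
    cds: list[tuple[int, int]] = field(default_factory=list)
    five_utr: list[tuple[int, int]] = field(default_factory=list)
    three_utr: list[tuple[int, int]] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.exons = sorted(self.exons)
        self.cds = sorted(self.cds)
        self.five_utr = sorted(self.five_utr)
        self.three_utr = sorted(self.three_utr)
        for s, e in self.exons:
            if s >= e:
                raise ValidationError(f"{self.gene_id}: empty exon [{s},{e})")
        for (s0, e0), (s1, e1) in zip(self.exons, self.exons[1:]):
            if e0 > s1:
                raise ValidationError(f"{self.gene_id}: overlapping exons")
        for s, e in self.cds:
            if not any(s >= xs and e <= xe for xs, xe in self.exons):
                raise ValidationError(
                    f"{self.gene_id}: CDS [{s},{e}) outside exons"
                )

    @property
    def has_utr_annotation(self) -> bool:
        return bool(self.cds) and bool(self.five_utr or self.three_utr)

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def introns(self) -> list[tuple[int, int]]:
        return [
            (e0, s1)
            for (_, e0), (s1, _) in zip(self.exons, self.exons[1:])
            if s1 > e0
        ]

    # ---- transcript-space helpers (used by the target scanner) ----

    def genome_to_transcript(self, pos: int) -> int | None:
        """Map a genomic position to spliced-transcript coordinates."""
        off = 0
        tpos = None
        for s, e in self.exons:
            if s <= pos < e:
                tpos = off + (pos - s)
                break
            off += e - s
        if tpos is None:
            return None
        if self.strand == "-":
            tlen = sum(e - s for s, e in self.exons)
            tpos = tlen - 1 - tpos
        return tpos

    def transcript_sequence(self, chrom_seq: str) -> str:
        seq = "".join(chrom_seq[s:e] for s, e in self.exons)
        return revcomp(seq) if self.strand == "-" else seq

    def cds_transcript_bounds(self) -> tuple[int, int] | None:
        """CDS [start, end) in transcript coordinates, or None without CDS."""
        if not self.cds:
            return None
        pts = []
        for s, e in self.cds:
            for g in (s, e - 1):
                t = self.genome_to_transcript(g)
                if t is not None:
                    pts.append(t)
        if not pts:
            return None
        return min(pts), max(pts) + 1


@dataclass
class AnnotationSet:
    genes: list[GeneModel] = field(default_factory=list)
    repeats: list[RepeatInterval] = field(default_factory=list)
    ncrna: list[NcRnaInterval] = field(default_factory=list)

    def __post_init__(self) -> None:
        self._repeat_trees: dict[str, IntervalTree] | None = None
        self._gene_trees: dict[str, IntervalTree] | None = None
        self._exon_trees: dict[str, IntervalTree] | None = None

    def repeat_tree(self, chrom: str) -> IntervalTree:
        if self._repeat_trees is None:
            trees: dict[str, IntervalTree] = {}
            for r in self.repeats:
                trees.setdefault(r.chrom, IntervalTree()).addi(r.start, r.end, r)
            self._repeat_trees = trees
        return self._repeat_trees.get(chrom, IntervalTree())

    def gene_tree(self, chrom: str) -> IntervalTree:
        if self._gene_trees is None:
            trees: dict[str, IntervalTree] = {}
            for g in self.genes:
                s, e = g.span
                trees.setdefault(g.chrom, IntervalTree()).addi(s, e, g)
            self._gene_trees = trees
        return self._gene_trees.get(chrom, IntervalTree())

    def exon_tree(self, chrom: str) -> IntervalTree:
        if self._exon_trees is None:
            trees: dict[str, IntervalTree] = {}
            for g in self.genes:
                for s, e in g.exons:
                    trees.setdefault(g.chrom, IntervalTree()).addi(s, e, g)
            self._exon_trees = trees
        return self._exon_trees.get(chrom, IntervalTree())


@dataclass
class GenomeBundle:
    """Reference sequences plus interval annotations in one coordinate frame."""

    chromosomes: dict[str, str]
    annotations: AnnotationSet

    def __post_init__(self) -> None:
        self.validate()

    def validate(self) -> None:
        lens = {c: len(s) for c, s in self.chromosomes.items()}
        items: list[tuple[str, str, int, int]] = []
        for g in self.annotations.genes:
            s, e = g.span
            items.append((g.gene_id, g.chrom, s, e))
        for r in self.annotations.repeats:
            items.append((r.family, r.chrom, r.start, r.end))
        for n in self.annotations.ncrna:
            items.append((n.class_label, n.chrom, n.start, n.end))
        for name, chrom, s, e in items:
            if chrom not in lens:
                raise ValidationError(
                    f"annotation {name!r} on unknown chromosome {chrom!r}"
                )
            if s < 0 or e > lens[chrom]:
                raise ValidationError(
                    f"annotation {name!r} [{s},{e}) exceeds {chrom} "
                    f"length {lens[chrom]}"
                )

    def genic_intervals(self, chrom: str) -> list[tuple[int, int]]:
        """Merged gene spans on one chromosome."""
        spans = sorted(
            g.span for g in self.annotations.genes if g.chrom == chrom
        )
        merged: list[tuple[int, int]] = []
        for s, e in spans:
            if merged and s <= merged[-1][1]:
                merged[-1] = (merged[-1][0], max(merged[-1][1], e))
            else:
                merged.append((s, e))
        return merged

    def intergenic_intervals(self, chrom: str) -> list[tuple[int, int]]:
        """Complement of the gene spans on one chromosome."""
        out: list[tuple[int, int]] = []
        prev = 0
        for s, e in self.genic_intervals(chrom):
            if s > prev:
                out.append((prev, s))
            prev = e
        n = len(self.chromosomes[chrom])
        if prev < n:
            out.append((prev, n))
        return out


# ----------------------------------------------------------------------
# readers


def read_fasta(path: str | os.PathLike) -> dict[str, str]:
    seqs: dict[str, str] = {}
    for rec in SeqIO.parse(str(path), "fasta"):
        seqs[rec.id] = str(rec.seq).upper()
    return seqs


def read_gff_genes(path: str | os.PathLike) -> list[GeneModel]:
    """Parse gene models from GFF3 (1-based closed -> half-open)."""
    import gffutils

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
    )
    genes: list[GeneModel] = []
    for gene in db.features_of_type("gene", order_by="start"):
        exons, cds, futr, tutr = [], [], [], []
        for child in db.children(gene, order_by="start"):
            iv = (child.start - 1, child.end)
            if child.featuretype == "exon":
                exons.append(iv)
            elif child.featuretype == "CDS":
                cds.append(iv)
            elif child.featuretype == "five_prime_UTR":
                futr.append(iv)
            elif child.featuretype == "three_prime_UTR":
                tutr.append(iv)
        if not exons:
            exons = [(gene.start - 1, gene.end)]
        genes.append(
            GeneModel(
                gene_id=gene.id,
                chrom=gene.seqid,
                strand=gene.strand,
                exons=exons,
                cds=cds,
                five_utr=futr,
                three_utr=tutr,
            )
        )
    return genes


def write_gff_genes(genes: list[GeneModel], path: str | os.PathLike) -> None:
    """Emit gene models as GFF3 (converting back to 1-based closed)."""
    with open(path, "w") as fh:
        fh.write("##gff-version 3\n")
        for g in sorted(genes, key=lambda g: (g.chrom, g.span[0], g.gene_id)):
            s, e = g.span
            attrs = f"ID={g.gene_id}"
            fh.write(
                f"{g.chrom}\tsrnapipe\tgene\t{s + 1}\t{e}\t.\t{g.strand}\t.\t{attrs}\n"
            )
            mrna = f"{g.gene_id}.t1"
            fh.write(
                f"{g.chrom}\tsrnapipe\tmRNA\t{s + 1}\t{e}\t.\t{g.strand}\t.\t"
                f"ID={mrna};Parent={g.gene_id}\n"
            )
            rows = (
                [("exon", iv) for iv in g.exons]
                + [("CDS", iv) for iv in g.cds]
                + [("five_prime_UTR", iv) for iv in g.five_utr]
                + [("three_prime_UTR", iv) for iv in g.three_utr]
            )
            for i, (ftype, (fs, fe)) in enumerate(rows):
                fh.write(
                    f"{g.chrom}\tsrnapipe\t{ftype}\t{fs + 1}\t{fe}\t.\t"
                    f"{g.strand}\t.\tID={mrna}.{ftype}.{i};Parent={mrna}\n"
                )


def read_repeats(path: str | os.PathLike) -> list[RepeatInterval]:
    """Read repeats from RepeatMasker ``.out`` or 6-column BED.

    BED name column carries the family label; both inputs are mapped onto
    the controlled class vocabulary.
    """
    path = str(path)
    out: list[RepeatInterval] = []
    with open(path) as fh:
        lines = fh.readlines()
    # RepeatMasker .out starts with a "SW perc perc perc query..." header
    is_rm = any(
        ln.split()[:1] == ["SW"] or ln.lstrip().startswith("score")
        for ln in lines[:3]
        if ln.strip()
    )
    if not is_rm and lines:
        first = next((ln for ln in lines if ln.strip()), "")
        is_rm = first.split()[:1] and first.split()[0].isdigit() and len(first.split()) >= 11 and "\t" not in first
    for lineno, ln in enumerate(lines, 1):
        if not ln.strip():
            continue
        if is_rm:
            f = ln.split()
            if not f[0].replace(".", "").isdigit():
                continue  # header lines
            if len(f) < 11:
                raise FormatError(f"{path}:{lineno}: short RepeatMasker line")
            chrom, b, e = f[4], int(f[5]) - 1, int(f[6])
            strand = "-" if f[8] == "C" else "+"
            family, cls = f[9], f[10]
            label = cls if "/" in cls or cls not in ("", ".") else repeat_class(family)
            out.append(RepeatInterval(chrom, b, e, strand, family, repeat_class(label)))
        else:
            f = ln.rstrip("\n").split("\t")
            if len(f) < 4:
                raise FormatError(f"{path}:{lineno}: expected BED with name column")
            strand = f[5] if len(f) > 5 else "+"
            family = f[3]
            out.append(
                RepeatInterval(
                    f[0], int(f[1]), int(f[2]), strand, family, repeat_class(family)
                )
            )
    return out


def read_ncrna(path: str | os.PathLike) -> list[NcRnaInterval]:
    """Read ncRNA intervals from BED6 (name column = class label)."""
    path = str(path)
    out: list[NcRnaInterval] = []
    known = {"rRNA", "tRNA", "miRNA"}
    with open(path) as fh:
        for lineno, ln in enumerate(fh, 1):
            if not ln.strip() or ln.startswith(("#", "track")):
                continue
            f = ln.rstrip("\n").split("\t")
            if len(f) < 4:
                raise FormatError(f"{path}:{lineno}: expected BED with name column")
            name = f[3].split("_")[0]
            cls = name if name in known else "other"
            strand = f[5] if len(f) > 5 else "+"
            out.append(NcRnaInterval(f[0], int(f[1]), int(f[2]), strand, cls))
    return out


def read_genome(
    fasta_path: str | os.PathLike,
    gff_path: str | os.PathLike | None = None,
    repeat_path: str | os.PathLike | None = None,
    ncrna_path: str | os.PathLike | None = None,
) -> GenomeBundle:
    """Load sequences and annotations into one validated bundle."""
    chroms = read_fasta(fasta_path)
    ann = AnnotationSet(
        genes=read_gff_genes(gff_path) if gff_path else [],
        repeats=read_repeats(repeat_path) if repeat_path else [],
        ncrna=read_ncrna(ncrna_path) if ncrna_path else [],
    )
    return GenomeBundle(chromosomes=chroms, annotations=ann)
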