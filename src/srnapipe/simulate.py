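"""Synthetic multi-library small-RNA experiment with planted ground truth.

The generator emulates the experimental design the pipeline is built
for: one adapter-flanked variable-length library (454-style) and two
35-color SOLiD libraries sequenced from a small genome that carries
genes with introns and UTRs, transposable-element families, rRNA/tRNA
loci, designed miRNA hairpins expressing mature and star reads,
repeat-derived tags, antisense tags, and rRNA/tRNA degradation
background.  All randomness flows from one seed; identical
(config, seed) gives byte-identical outputs.

Planted miRNA hairpins are mature + loop + near-complementary star with
two designed non-pairing substitutions in the star arm, so the mature
tag maps uniquely and the hairpin passes the structural filters when
the flanked precursor is folded.
"""

from __future__ import annotations

import os
from collections import defaultdict
from dataclasses import dataclass, field, asdict

import numpy as np

from .colorspace import encode, write_csfasta
from .errors import ConfigurationError
from .genome import (
    AnnotationSet,
    GeneModel,
    GenomeBundle,
    NcRnaInterval,
    RepeatInterval,
    revcomp,
    write_gff_genes,
)
from .preprocess import MODBAN_3P, NELSON_5P

_BASES = np.array(list("ACGT"))

REPEAT_FAMILIES = {
    "Copia": "LTR/Copia",
    "Gypsy": "LTR/Gypsy",
    "Harbinger": "DNA/Harbinger",
    "MuDR": "DNA/MuDR",
}


@dataclass
class SimConfig:
    seed: int = 17
    n_chroms: int = 2
    chrom_length: int = 100_000
    n_genes: int = 40
    intron_rate: float = 0.5
    intron_size: tuple[int, int] = (60, 140)
    n_repeat_loci_per_family: int = 8
    n_mirna_loci: int = 20
    n_antisense_loci: int = 20
    n_rasirna_sources: int = 30
    depth_mean: float = 5.0
    degradation_fraction: float = 0.10
    color_error_rate: float = 0.0
    libraries: tuple[str, ...] = ("L454", "EF", "EC")
    utr_gene_fraction: float = 0.6
    n_target_sites: int = 5
    mirna_loop_len: int = 12
    solid_read_colors: int = 35
    truncation_bias: float = 0.0  # fraction of SOLiD reads cut to 18 nt

    def validate(self) -> None:
        for name in (
            "intron_rate",
            "degradation_fraction",
            "color_error_rate",
            "utr_gene_fraction",
            "truncation_bias",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {v}")
        if self.depth_mean < 0:
            raise ConfigurationError("depth_mean must be >= 0")
        if len(self.libraries) != 3:
            raise ConfigurationError("exactly three library labels expected")


@dataclass
class TruthLocus:
    locus_id: str
    type: str  # mirna | rasirna | natsirna | degradation
    chrom: str
    start: int
    end: int
    strand: str
    mature: str
    star: str | None = None
    star_start: int = -1
    star_end: int = -1
    counts: dict[str, int] = field(default_factory=dict)
    star_counts: dict[str, int] = field(default_factory=dict)


@dataclass
class TruthManifest:
    loci: list[TruthLocus] = field(default_factory=list)

    def of_type(self, t: str) -> list[TruthLocus]:
        return [l for l in self.loci if l.type == t]

    def write(self, path) -> None:
        cols = [
            "locus_id",
            "type",
            "chrom",
            "start",
            "end",
            "strand",
            "mature",
            "star",
            "star_start",
            "star_end",
            "counts",
            "star_counts",
        ]
        with open(path, "w") as fh:
            fh.write("\t".join(cols) + "\n")
            for l in self.loci:
                d = asdict(l)
                d["star"] = l.star or "."
                d["counts"] = ",".join(f"{k}={v}" for k, v in sorted(l.counts.items()))
                d["star_counts"] = (
                    ",".join(f"{k}={v}" for k, v in sorted(l.star_counts.items())) or "."
                )
                fh.write("\t".join(str(d[c]) for c in cols) + "\n")

    @classmethod
    def read(cls, path) -> "TruthManifest":
        loci = []
        with open(path) as fh:
            header = fh.readline().rstrip("\n").split("\t")
            for ln in fh:
                d = dict(zip(header, ln.rstrip("\n").split("\t")))
                counts = {
                    kv.split("=")[0]: int(kv.split("=")[1])
                    for kv in d["counts"].split(",")
                    if kv and kv != "."
                }
                star_counts = {
                    kv.split("=")[0]: int(kv.split("=")[1])
                    for kv in d["star_counts"].split(",")
                    if kv and kv != "."
                }
                loci.append(
                    TruthLocus(
                        locus_id=d["locus_id"],
                        type=d["type"],
                        chrom=d["chrom"],
                        start=int(d["start"]),
                        end=int(d["end"]),
                        strand=d["strand"],
                        mature=d["mature"],
                        star=None if d["star"] == "." else d["star"],
                        star_start=int(d["star_start"]),
                        star_end=int(d["star_end"]),
                        counts=counts,
                        star_counts=star_counts,
                    )
                )
        return cls(loci)


# ----------------------------------------------------------------------
# sequence construction helpers


def _rand_seq(rng, n: int, p=(0.25, 0.25, 0.25, 0.25)) -> str:
    return "".join(rng.choice(_BASES, size=n, p=list(p)))


_NONPAIR = {  # bases that neither pair nor wobble with the key base
    "A": "AC",
    "C": "AC",
    "G": "AG",
    "T": "CT",
}


#: flanking pad planted around each hairpin so precursor excision stays
#: inside designed sequence (precursor flank 100 + mature-side lead + margin)
HAIRPIN_PAD = 130


def design_hairpin(
    rng, mature_len: int, loop_len: int, mature_arm: str
) -> tuple[str, int, int, int, int]:
    """Design a hairpin locus with provably dominant designed pairing.

    The mature arm uses only A/T, the star arm is its reverse complement
    with two interior substitutions to C (which pairs nothing else in
    the locus), and the loop and flanking pads are C-only.  Under the
    additive fold model no base outside the designed duplex can pair, so
    the excised precursor folds into exactly the designed stem: every
    mature base pairs the star arm except the two opposite the designed
    substitutions, the terminal loop spans ``loop_len`` nt, and the MFE
    is -2*(mature_len - 2) + 4 kcal/mol.

    Returns (locus_seq, mature_off, mature_len, star_off, star_len);
    offsets are relative to the locus sequence.
    """
    mature = _rand_seq(rng, mature_len, p=(0.5, 0.0, 0.0, 0.5))
    star = list(revcomp(mature))
    pos = rng.choice(np.arange(4, mature_len - 4), size=2, replace=False)
    for p in sorted(int(x) for x in pos):
        star[p] = "C"
    star_seq = "".join(star)
    loop = "C" * loop_len
    pad = "C" * HAIRPIN_PAD
    if mature_arm == "5p":
        core = mature + loop + star_seq
        m_off, s_off = len(pad), len(pad) + mature_len + loop_len
    else:
        core = star_seq + loop + mature
        m_off, s_off = len(pad) + mature_len + loop_len, len(pad)
    return pad + core + pad, m_off, mature_len, s_off, mature_len


# ----------------------------------------------------------------------
# genome generation


class _Placer:
    """Sequential feature placement with random spacing per chromosome."""

    def __init__(self, rng, chrom_names, chrom_length):
        self.rng = rng
        self.cursors = {c: 300 for c in chrom_names}
        self.limit = chrom_length - 300
        self.order = list(chrom_names)
        self._next = 0

    def place(self, size: int) -> tuple[str, int]:
        for _ in range(len(self.order)):
            chrom = self.order[self._next % len(self.order)]
            self._next += 1
            cur = self.cursors[chrom]
            gap = int(self.rng.integers(80, 300))
            start = cur + gap
            if start + size <= self.limit:
                self.cursors[chrom] = start + size
                return chrom, start
        raise ConfigurationError(
            "infeasible packing: planted loci exceed genome length"
        )


def _split_transcript(exons, cut1, cut2):
    """Split an exon chain at transcript offsets cut1 < cut2 (genomic
    left-to-right transcript order); returns three genomic interval lists."""
    parts: list[list[tuple[int, int]]] = [[], [], []]
    off = 0
    for s, e in exons:
        for lo, hi, idx in ((0, cut1, 0), (cut1, cut2, 1), (cut2, 10**12, 2)):
            a = max(s, s + lo - off)
            b = min(e, s + hi - off)
            if a < b:
                parts[idx].append((a, b))
        off += e - s
    return parts


def generate_genome(config: SimConfig) -> tuple[GenomeBundle, TruthManifest]:
    """Build the genome, its annotations and the truth manifest."""
    config.validate()
    rng = np.random.default_rng([config.seed, 1])
    chrom_names = [f"chr{i + 1}" for i in range(config.n_chroms)]
    chrom_seq = {
        c: list(_rand_seq(rng, config.chrom_length)) for c in chrom_names
    }
    placer = _Placer(rng, chrom_names, config.chrom_length)

    genes: list[GeneModel] = []
    repeats: list[RepeatInterval] = []
    ncrna: list[NcRnaInterval] = []
    truth = TruthManifest()
    libs454, lib_ef, lib_ec = config.libraries

    def paste(chrom: str, pos: int, seq: str) -> None:
        chrom_seq[chrom][pos : pos + len(seq)] = list(seq)

    # --- genes -------------------------------------------------------
    for gi in range(config.n_genes):
        n_exons = 1
        if rng.random() < config.intron_rate:
            n_exons = int(rng.integers(2, 4))
        exon_lens = [int(rng.integers(200, 400)) for _ in range(n_exons)]
        intron_lens = [
            int(rng.integers(*config.intron_size)) for _ in range(n_exons - 1)
        ]
        span = sum(exon_lens) + sum(intron_lens)
        chrom, start = placer.place(span)
        exons = []
        pos = start
        for k, el in enumerate(exon_lens):
            exons.append((pos, pos + el))
            pos += el + (intron_lens[k] if k < n_exons - 1 else 0)
        strand = "+" if gi % 2 == 0 else "-"
        tlen = sum(exon_lens)
        has_utr = rng.random() < config.utr_gene_fraction
        if has_utr:
            c1 = max(30, int(0.15 * tlen))
            c2 = tlen - max(30, int(0.15 * tlen))
            left, mid, right = _split_transcript(exons, c1, c2)
            cds = mid
            futr, tutr = (left, right) if strand == "+" else (right, left)
        else:
            cds, futr, tutr = [], [], []
        genes.append(
            GeneModel(
                gene_id=f"gene{gi + 1:03d}",
                chrom=chrom,
                strand=strand,
                exons=exons,
                cds=cds,
                five_utr=futr,
                three_utr=tutr,
            )
        )

    # --- repeat families ---------------------------------------------
    consensus = {
        fam: _rand_seq(rng, int(rng.integers(260, 380)))
        for fam in REPEAT_FAMILIES
    }
    for fam, cls in REPEAT_FAMILIES.items():
        for _ in range(config.n_repeat_loci_per_family):
            seq = list(consensus[fam])
            n_mut = max(1, int(0.02 * len(seq)))
            for p in rng.choice(len(seq), size=n_mut, replace=False):
                seq[p] = str(rng.choice(_BASES))
            strand = "+" if rng.random() < 0.5 else "-"
            copy = "".join(seq) if strand == "+" else revcomp("".join(seq))
            chrom, start = placer.place(len(copy))
            paste(chrom, start, copy)
            repeats.append(
                RepeatInterval(chrom, start, start + len(copy), strand, fam, cls)
            )

    # --- rRNA / tRNA loci --------------------------------------------
    for i in range(3):
        seq = _rand_seq(rng, 300)
        chrom, start = placer.place(300)
        paste(chrom, start, seq)
        ncrna.append(NcRnaInterval(chrom, start, start + 300, "+", "rRNA"))
    for i in range(4):
        seq = _rand_seq(rng, 75)
        chrom, start = placer.place(75)
        paste(chrom, start, seq)
        ncrna.append(NcRnaInterval(chrom, start, start + 75, "+", "tRNA"))

    # --- miRNA hairpin loci ------------------------------------------
    def _counts(mem_libs, lo=1):
        return {
            lib: max(lo, int(rng.poisson(config.depth_mean))) for lib in mem_libs
        }

    n_two_lib = int(round(0.75 * config.n_mirna_loci))
    for mi in range(config.n_mirna_loci):
        mature_len = int(rng.integers(20, 23))
        arm = "5p" if mi % 2 == 0 else "3p"
        locus, m_off, m_len, s_off, s_len = design_hairpin(
            rng, mature_len, config.mirna_loop_len, arm
        )
        strand = "+" if mi % 4 < 2 else "-"
        planted = locus if strand == "+" else revcomp(locus)
        chrom, start = placer.place(len(planted))
        paste(chrom, start, planted)
        if strand == "+":
            m_start = start + m_off
            s_start = start + s_off
        else:
            m_start = start + len(locus) - m_off - m_len
            s_start = start + len(locus) - s_off - s_len
        mature = locus[m_off : m_off + m_len]
        star_arm = locus[s_off : s_off + s_len]
        if mi < n_two_lib:
            mem = [lib_ef, lib_ec]
            star_mem = [lib_ef] if mi % 2 == 0 else []
        else:
            mem = [lib_ef]
            star_mem = [lib_ef]
        counts = _counts(mem, lo=2)
        total = sum(counts.values())
        star_counts = {}
        for lib in star_mem:
            c = max(1, int(rng.poisson(config.depth_mean / 2)))
            star_counts[lib] = max(1, min(c, total - 1))
        truth.loci.append(
            TruthLocus(
                locus_id=f"mir{mi + 1:03d}",
                type="mirna",
                chrom=chrom,
                start=m_start,
                end=m_start + m_len,
                strand=strand,
                mature=mature,
                star=star_arm if star_counts else None,
                star_start=s_start,
                star_end=s_start + s_len,
                counts=counts,
                star_counts=star_counts,
            )
        )

    # --- rasiRNA tags from repeat copies -----------------------------
    if config.n_rasirna_sources > len(repeats) * 4:
        raise ConfigurationError("n_rasirna_sources too large for repeat count")
    for ri in range(config.n_rasirna_sources):
        rep = repeats[ri % len(repeats)]
        length = int(rng.integers(21, 26))
        off = int(rng.integers(5, rep.end - rep.start - length - 5))
        start = rep.start + off
        strand = "+" if rng.random() < 0.5 else "-"
        truth.loci.append(
            TruthLocus(
                locus_id=f"ras{ri + 1:03d}",
                type="rasirna",
                chrom=rep.chrom,
                start=start,
                end=start + length,
                strand=strand,
                mature="",  # filled after guard fixing
                counts=_counts(list(config.libraries)),
            )
        )

    # --- antisense tags within genes ---------------------------------
    for ai in range(config.n_antisense_loci):
        gene = genes[ai % len(genes)]
        exon = gene.exons[0]
        length = int(rng.integers(25, 31))
        off = int(rng.integers(10, exon[1] - exon[0] - length - 10))
        start = exon[0] + off
        strand = "-" if gene.strand == "+" else "+"
        truth.loci.append(
            TruthLocus(
                locus_id=f"nat{ai + 1:03d}",
                type="natsirna",
                chrom=gene.chrom,
                start=start,
                end=start + length,
                strand=strand,
                mature="",
                counts=_counts(list(config.libraries)),
            )
        )

    # --- plant target sites for the first matures --------------------
    site_genes: list[str] = []
    utr_plus = [g for g in genes if g.has_utr_annotation and g.strand == "+"]
    mirna_loci = truth.of_type("mirna")
    for k in range(min(config.n_target_sites, len(utr_plus), len(mirna_loci))):
        gene = utr_plus[k]
        mature = mirna_loci[k].mature
        site = list(revcomp(mature))
        # two defects outside the seed (miRNA positions 10 and 14 -> site
        # positions L-11 and L-15): substitutions that cannot pair
        L = len(site)
        for mpos in (10, 14):
            spos = L - 1 - mpos
            partner = mature[mpos]
            choices = [c for c in _NONPAIR[partner] if c != site[spos]]
            site[spos] = choices[0] if choices else _NONPAIR[partner][0]
        cds_iv = max(gene.cds, key=lambda iv: iv[1] - iv[0])
        if cds_iv[1] - cds_iv[0] < L + 20:
            continue
        pos = (cds_iv[0] + cds_iv[1] - L) // 2
        paste(gene.chrom, pos, "".join(site))
        site_genes.append(gene.gene_id)

    # --- degradation background fragments ----------------------------
    f = config.degradation_fraction
    if f > 0 and ncrna:
        per_lib_signal = {
            lib: sum(l.counts.get(lib, 0) for l in truth.loci)
            + sum(l.star_counts.get(lib, 0) for l in truth.loci)
            for lib in config.libraries
        }
        di = 0
        for lib in config.libraries:
            n_deg = int(round(per_lib_signal[lib] * f / (1.0 - f)))
            for _ in range(n_deg):
                src = ncrna[int(rng.integers(len(ncrna)))]
                length = int(rng.integers(20, 35))
                start = src.start + int(
                    rng.integers(0, src.end - src.start - length)
                )
                di += 1
                truth.loci.append(
                    TruthLocus(
                        locus_id=f"deg{di:04d}",
                        type="degradation",
                        chrom=src.chrom,
                        start=start,
                        end=start + length,
                        strand="+",
                        mature="",
                        counts={lib: 1},
                    )
                )

    # --- guard bases: stop adapter carry-over extension --------------
    # Alignment-trimming of a SOLiD read extends for as long as the
    # genome continues to match the adapter that pads the read.  The
    # base just 3' of every genomic occurrence of a planted insert (in
    # read orientation) must therefore differ from the first adapter
    # base; repeat-derived inserts occur on sibling copies too, so every
    # <=1-mismatch occurrence is guarded.
    _apply_extension_guards(chrom_seq, truth)

    chromosomes = {c: "".join(s) for c, s in chrom_seq.items()}

    # fill insert sequences from the final genome
    for l in truth.loci:
        sub = chromosomes[l.chrom][l.start : l.end]
        seq = sub if l.strand == "+" else revcomp(sub)
        if l.type == "mirna":
            assert seq == l.mature, "hairpin overwritten during placement"
        else:
            l.mature = seq

    bundle = GenomeBundle(
        chromosomes=chromosomes,
        annotations=AnnotationSet(genes=genes, repeats=repeats, ncrna=ncrna),
    )
    bundle.site_genes = site_genes  # informational: genes carrying planted sites
    return bundle, truth


def _apply_extension_guards(chrom_seq: dict[str, list[str]], truth: TruthManifest) -> None:
    from .genome import AnnotationSet as _AS, GenomeBundle as _GB
    from .preprocess import KmerIndex, map_to_genome
    from .tags import TagRecord

    adapter0 = MODBAN_3P[0]
    comp0 = {"A": "T", "C": "G", "G": "C", "T": "A"}[adapter0]
    tmp = _GB(
        chromosomes={c: "".join(s) for c, s in chrom_seq.items()},
        annotations=_AS(),
    )
    index = KmerIndex(tmp, k=8)
    for l in truth.loci:
        if l.type == "degradation":
            continue
        sub = tmp.chromosomes[l.chrom][l.start : l.end]
        insert = sub if l.strand == "+" else revcomp(sub)
        tag = TagRecord(sequence=insert, counts={"x": 1})
        map_to_genome([tag], index, max_mismatch=1)
        for a in tag.alignments:
            seq = chrom_seq[a.chrom]
            if a.strand == "+":
                if a.end < len(seq) and seq[a.end] == adapter0:
                    seq[a.end] = "C"
            else:
                if a.start > 0 and seq[a.start - 1] == comp0:
                    seq[a.start - 1] = "G"


# ----------------------------------------------------------------------
# read simulation


def solid_template(insert: str, n_colors: int) -> str:
    """Base-space template a SOLiD read of ``n_colors`` colors covers:
    the insert followed by the 3' adapter, cycled as needed."""
    pad = insert + MODBAN_3P * (1 + n_colors // len(MODBAN_3P))
    return pad[:n_colors]


def simulate_reads(
    bundle: GenomeBundle, manifest: TruthManifest, config: SimConfig
) -> dict[str, list]:
    """Emit reads per library.

    The 454-style library holds adapter-flanked base-space reads
    (Nelson linker + insert + Modban linker); SOLiD libraries hold
    (id, primer, colors) records of exactly ``solid_read_colors`` colors
    with i.i.d. color errors at the configured rate.
    """
    config.validate()
    rng = np.random.default_rng([config.seed, 2])
    lib454 = config.libraries[0]
    reads: dict[str, list] = {lib: [] for lib in config.libraries}
    counter = 0

    def emit(lib: str, insert: str, count: int) -> None:
        nonlocal counter
        for _ in range(count):
            counter += 1
            rid = f"{lib}_{counter:06d}"
            if lib == lib454:
                reads[lib].append((rid, NELSON_5P + insert + MODBAN_3P))
            else:
                tmpl = solid_template(insert, config.solid_read_colors)
                if config.truncation_bias and rng.random() < config.truncation_bias:
                    tmpl = solid_template(insert[:18], config.solid_read_colors)
                colors = np.array([int(c) for c in encode(tmpl, "T")])
                if config.color_error_rate > 0:
                    err = rng.random(len(colors)) < config.color_error_rate
                    shift = rng.integers(1, 4, size=len(colors))
                    colors = np.where(err, (colors + shift) % 4, colors)
                reads[lib].append((rid, "T", "".join(map(str, colors))))

    for locus in manifest.loci:
        for lib in config.libraries:
            c = locus.counts.get(lib, 0)
            if c:
                emit(lib, locus.mature, c)
            sc = locus.star_counts.get(lib, 0)
            if sc and locus.star:
                emit(lib, locus.star, sc)
    return reads


# ----------------------------------------------------------------------
# dataset writer


def write_dataset(out_dir, config: SimConfig) -> dict[str, str]:
    """Generate and write the complete synthetic dataset; returns paths."""
    os.makedirs(out_dir, exist_ok=True)
    bundle, manifest = generate_genome(config)
    reads = simulate_reads(bundle, manifest, config)
    rng = np.random.default_rng([config.seed, 3])
    p = {k: os.path.join(out_dir, v) for k, v in {
        "genome": "genome.fa",
        "genes": "genes.gff3",
        "repeats": "repeats.bed",
        "ncrna": "ncrna.bed",
        "ncrna_ref": "ncrna_ref.fa",
        "known_mirnas": "known_mirnas.fa",
        "go_map": "go_map.tsv",
        "reads_454": "reads_454.fa",
        "reads_EF": "reads_EF.csfasta",
        "reads_EC": "reads_EC.csfasta",
        "truth": "truth.tsv",
    }.items()}

    with open(p["genome"], "w") as fh:
        for chrom, seq in sorted(bundle.chromosomes.items()):
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), 80):
                fh.write(seq[i : i + 80] + "\n")
    write_gff_genes(bundle.annotations.genes, p["genes"])
    with open(p["repeats"], "w") as fh:
        for r in bundle.annotations.repeats:
            fh.write(
                f"{r.chrom}\t{r.start}\t{r.end}\t{r.family}\t0\t{r.strand}\n"
            )
    ncrna_counter = defaultdict(int)
    with open(p["ncrna"], "w") as fbed, open(p["ncrna_ref"], "w") as fref:
        for n in bundle.annotations.ncrna:
            ncrna_counter[n.class_label] += 1
            name = f"{n.class_label}_{ncrna_counter[n.class_label]}"
            fbed.write(f"{n.chrom}\t{n.start}\t{n.end}\t{name}\t0\t{n.strand}\n")
            fref.write(
                f">{name}\n{bundle.chromosomes[n.chrom][n.start:n.end]}\n"
            )
        # one planted mature annotated as a known miRNA-class ncRNA, so
        # the degradation filter's miRNA exemption is exercised
        mirnas = manifest.of_type("mirna")
        if mirnas:
            fref.write(f">miRNA_1\n{mirnas[0].mature}\n")

    with open(p["known_mirnas"], "w") as fh:
        mirnas = manifest.of_type("mirna")
        for i in range(10):
            fh.write(f">decoy-mir-{i + 1}\n{_rand_seq(rng, 21)}\n")
        for i, locus in enumerate(mirnas[:3]):
            seq = locus.mature[:10] + _rand_seq(rng, 11)
            fh.write(f">known-mir-{i + 1}\n{seq}\n")

    terms = ["GO:0008150", "GO:0016310", "GO:0055085", "GO:0006139"]
    site_genes = set(getattr(bundle, "site_genes", []))
    with open(p["go_map"], "w") as fh:
        for g in bundle.annotations.genes:
            fh.write(f"{g.gene_id}\t{terms[0]}\n")
            if g.gene_id in site_genes or rng.random() < 0.1:
                fh.write(f"{g.gene_id}\t{terms[1]}\n")
            if rng.random() < 0.3:
                fh.write(f"{g.gene_id}\t{terms[2 + int(rng.integers(2))]}\n")

    with open(p["reads_454"], "w") as fh:
        for rid, seq in reads[config.libraries[0]]:
            fh.write(f">{rid}\n{seq}\n")
    write_csfasta(reads[config.libraries[1]], p["reads_EF"])
    write_csfasta(reads[config.libraries[2]], p["reads_EC"])
    manifest.write(p["truth"])
    return p
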