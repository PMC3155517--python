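"""End-to-end orchestration: preprocess -> coverage -> miRNA -> siRNA ->
targets, plus recovery scoring against a planted-truth manifest."""

from __future__ import annotations

import json
import os
from dataclasses import asdict, dataclass, field

import pandas as pd
import yaml

from . import colorspace, coverage, mirna, preprocess, sirna, targets
from .errors import ConfigurationError, StageError
from .fold import get_engine
from .genome import GenomeBundle, read_fasta, read_genome
from .simulate import TruthManifest
from .tags import TagRecord, write_tag_table


@dataclass
class RunConfig:
    """All paths and thresholds for one pipeline run.

    Threshold defaults are the method's standard operating point:
    precursor flank 100 nt, terminal loop >= 10 nt, mature-arm bulges
    <= 3 nt, hairpin MFE < -20 kcal/mol, clustering at 100% identity
    with 0.8 length similarity, degradation coverage >= 0.70, genome
    mapping <= 1 mismatch, 10 kb bins, 9-of-10 seed identity, E-value
    <= 1e-5, hybrid energy <= -20 kcal/mol.
    """

    genome_fasta: str = ""
    genes_gff: str | None = None
    repeats: str | None = None
    ncrna_bed: str | None = None
    ncrna_ref: str | None = None
    known_mirnas: str | None = None
    go_map: str | None = None
    reads_454: str | None = None
    reads_solid: dict[str, str] = field(default_factory=dict)  # library -> csfasta
    library_454: str = "L454"
    truth: str | None = None
    out_dir: str = "srna_out"

    flank: int = 100
    loop_min: int = 10
    bulge_max: int = 3
    mfe_max: float = -20.0
    cluster_len_sim: float = 0.8
    degr_cov: float = 0.70
    degr_ident: float = 0.90
    min_insert: int = 16
    max_mismatch: int = 1
    adapter_max_missing: int = 4
    bin_size: int = 10000
    seed_len: int = 10
    seed_max_mismatch: int = 1
    evalue_max: float = 1e-5
    hybrid_mfe_max: float = -20.0
    star_tol: int = 3
    fold_engine: str = "simple"
    seed: int = 17

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        known = set(cls.__dataclass_fields__)
        bad = set(data) - known
        if bad:
            raise ConfigurationError(f"unknown config keys: {sorted(bad)}")
        return cls(**data)

    def validate(self) -> None:
        if not self.genome_fasta:
            raise ConfigurationError("genome_fasta is required")
        paths = [
            ("genome_fasta", self.genome_fasta),
            ("genes_gff", self.genes_gff),
            ("repeats", self.repeats),
            ("ncrna_bed", self.ncrna_bed),
            ("ncrna_ref", self.ncrna_ref),
            ("known_mirnas", self.known_mirnas),
            ("go_map", self.go_map),
            ("reads_454", self.reads_454),
            ("truth", self.truth),
        ] + [(f"reads_solid[{k}]", v) for k, v in self.reads_solid.items()]
        for name, p in paths:
            if p is not None and p != "" and not os.path.exists(p):
                raise ConfigurationError(f"{name}: no such file: {p}")


@dataclass
class RecoveryReport:
    """Per planted class: detection counts against the truth manifest."""

    classes: dict[str, dict] = field(default_factory=dict)

    def as_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.classes).T


def _read_ncrna_ref(path) -> list[tuple[str, str, str]]:
    known = {"rRNA", "tRNA", "miRNA", "ribosomal"}
    out = []
    for name, seq in read_fasta(path).items():
        cls = name.split("_")[0]
        out.append((name, cls if cls in known else "other", seq))
    return out


def _reciprocal_overlap(a_start, a_end, b_start, b_end) -> float:
    ov = max(0, min(a_end, b_end) - max(a_start, b_start))
    if ov == 0:
        return 0.0
    return min(ov / (a_end - a_start), ov / (b_end - b_start))


def score_recovery(
    mirna_calls: list,
    rasirna_calls: list,
    nat_calls: list,
    truth: TruthManifest,
    min_overlap: float = 0.9,
) -> RecoveryReport:
    """Match calls to planted loci at >= 90% reciprocal interval overlap."""

    def match(intervals, locus) -> bool:
        return any(
            chrom == locus.chrom
            and strand == locus.strand
            and _reciprocal_overlap(s, e, locus.start, locus.end) >= min_overlap
            for chrom, s, e, strand in intervals
        )

    report = RecoveryReport()
    call_sets = {
        "mirna": [
            [(c.alignment.chrom, c.alignment.start, c.alignment.end, c.alignment.strand)]
            for c in mirna_calls
        ],
        "rasirna": [
            [(a.chrom, a.start, a.end, a.strand) for a in c.tag.alignments]
            for c in rasirna_calls
        ],
        "natsirna": [
            [(a.chrom, a.start, a.end, a.strand) for a in c.tag.alignments]
            for c in nat_calls
            if c.klass == "nat-antisense"
        ],
    }
    for klass, call_ivs in call_sets.items():
        planted = truth.of_type(klass)
        tp = sum(1 for l in planted if any(match(ivs, l) for ivs in call_ivs))
        fn = len(planted) - tp
        fp = sum(
            1 for ivs in call_ivs if not any(match(ivs, l) for l in planted)
        )
        n_calls = len(call_ivs)
        report.classes[klass] = {
            "planted": len(planted),
            "tp": tp,
            "fn": fn,
            "fp": fp,
            "recall": tp / len(planted) if planted else None,
            "precision": (n_calls - fp) / n_calls if n_calls else None,
        }
    return report


def run_all(config: RunConfig) -> dict:
    """Execute every stage, writing per-stage TSVs under ``out_dir``.

    Returns a results dict with the in-memory objects and the stage log.
    Deterministic: the analysis itself draws no random numbers.
    """
    config.validate()
    os.makedirs(config.out_dir, exist_ok=True)
    log: list[dict] = []
    results: dict = {"log": log}

    def stage(name):
        def wrap(fn):
            try:
                return fn()
            except Exception as exc:  # noqa: BLE001
                raise StageError(name, exc) from exc

        return wrap

    # ---- load -------------------------------------------------------
    genome = stage("load")(
        lambda: read_genome(
            config.genome_fasta, config.genes_gff, config.repeats, config.ncrna_bed
        )
    )
    results["genome"] = genome

    # ---- preprocess -------------------------------------------------
    def _preprocess():
        inserts: list[tuple[str, str]] = []
        rejections: list[tuple[str, str, str]] = []
        n_in = {}
        if config.reads_454:
            reads = list(read_fasta(config.reads_454).items())
            n_in[config.library_454] = len(reads)
            for rid, seq in reads:
                ins, reason = preprocess.trim_454_adapters(
                    seq, max_missing=config.adapter_max_missing
                )
                if ins is None:
                    rejections.append((config.library_454, rid, reason))
                else:
                    inserts.append((ins, config.library_454))
        index = preprocess.KmerIndex(genome, k=8)
        for lib, path in sorted(config.reads_solid.items()):
            recs = colorspace.read_csfasta(path)
            n_in[lib] = len(recs)
            for rid, primer, colors in recs:
                decoded = colorspace.decode(primer, colors)
                placements, reason = preprocess.align_trim_solid(
                    decoded, index, min_insert=config.min_insert
                )
                if not placements:
                    rejections.append((lib, rid, reason))
                else:
                    inserts.append((placements[0][0], lib))
        # conservation: every input read is either kept or rejected
        kept_by_lib = {}
        for _, lib in inserts:
            kept_by_lib[lib] = kept_by_lib.get(lib, 0) + 1
        for lib, total in n_in.items():
            rej = sum(1 for l, _, _ in rejections if l == lib)
            assert kept_by_lib.get(lib, 0) + rej == total, f"count leak in {lib}"
        log.append(
            {
                "stage": "preprocess",
                "reads_in": n_in,
                "inserts": len(inserts),
                "rejected": len(rejections),
            }
        )
        pd.DataFrame(rejections, columns=["library", "read_id", "reason"]).to_csv(
            os.path.join(config.out_dir, "rejections.tsv"), sep="\t", index=False
        )
        return inserts, index

    inserts, index = stage("preprocess")(_preprocess)

    def _tags():
        tags = preprocess.cluster_unique(inserts, len_sim=config.cluster_len_sim)
        ncrna_ref = _read_ncrna_ref(config.ncrna_ref) if config.ncrna_ref else []
        kept, removed = preprocess.filter_degradation(
            tags, ncrna_ref, config.degr_cov, config.degr_ident
        )
        mapped, unmapped = preprocess.map_to_genome(
            kept, index, max_mismatch=config.max_mismatch
        )
        log.append(
            {
                "stage": "tags",
                "unique_tags": len(tags),
                "degradation_removed": len(removed),
                "unmapped": len(unmapped),
                "mapped": len(mapped),
                "unique_fraction": {
                    lib: len([t for t in mapped if t.counts.get(lib)])
                    / max(1, sum(t.counts.get(lib, 0) for t in mapped))
                    for lib in {l for t in mapped for l in t.libraries()}
                },
            }
        )
        write_tag_table(mapped, os.path.join(config.out_dir, "tags.tsv"))
        return mapped

    tags = stage("tags")(_tags)
    results["tags"] = tags

    def _stats():
        len_df, nt_df = preprocess.tag_stats(tags)
        len_df.to_csv(os.path.join(config.out_dir, "length_distribution.tsv"), sep="\t")
        nt_df.to_csv(os.path.join(config.out_dir, "nt5_frequency.tsv"), sep="\t")
        return len_df, nt_df

    results["stats"] = stage("stats")(_stats)

    def _coverage():
        profiles = coverage.bin_alignments(tags, genome, bin_size=config.bin_size)
        coverage.export_profiles(profiles, os.path.join(config.out_dir, "coverage"))
        return profiles

    results["profiles"] = stage("coverage")(_coverage)

    def _mirna():
        engine = get_engine(config.fold_engine)
        calls = mirna.predict_mirnas(
            tags,
            genome,
            engine=engine,
            flank=config.flank,
            mfe_max=config.mfe_max,
            loop_min=config.loop_min,
            bulge_max=config.bulge_max,
            star_tol=config.star_tol,
        )
        if config.known_mirnas:
            known = read_fasta(config.known_mirnas)
            mirna.match_known_mirnas(
                calls, known, config.seed_len, config.seed_max_mismatch
            )
        log.append({"stage": "mirna", "candidates_called": len(calls)})
        _write_mirna_calls(calls, config.out_dir)
        return calls

    mirna_calls = stage("mirna")(_mirna)
    results["mirna_calls"] = mirna_calls

    def _sirna():
        mirna_seqs = {c.mature for c in mirna_calls} | {
            c.star_sequence for c in mirna_calls if c.star_sequence
        }
        rest = [t for t in tags if t.sequence not in mirna_seqs]
        ras_calls, fam_table = sirna.call_rasirna(rest, genome)
        ras_seqs = {c.tag.sequence for c in ras_calls}
        nat_input = [t for t in rest if t.sequence not in ras_seqs]
        nat_calls, nat_summary = sirna.classify_nat_sirna(nat_input, genome)
        fam_table.to_csv(os.path.join(config.out_dir, "family_table.tsv"), sep="\t")
        nat_summary.to_csv(
            os.path.join(config.out_dir, "nat_summary.tsv"), sep="\t"
        )
        for weighting in ("unique", "reads"):
            sirna.distribution_summary(
                tags, mirna_seqs, ras_calls, nat_calls, weighting=weighting
            ).to_csv(
                os.path.join(config.out_dir, f"distribution_{weighting}.tsv"),
                sep="\t",
            )
        libs = sorted({lib for t in tags for lib in t.libraries()})
        cross = []
        for la in libs:
            for lb in libs:
                if la == lb:
                    continue
                set_a = [c.tag for c in ras_calls if c.tag.counts.get(la)]
                set_b = [c.tag for c in ras_calls if c.tag.counts.get(lb)]
                frac = (
                    sirna.cross_library_match(set_a, set_b, config.evalue_max)
                    if set_a and set_b
                    else 0.0
                )
                cross.append((la, lb, len(set_a), len(set_b), frac))
        pd.DataFrame(
            cross, columns=["set_a", "set_b", "n_a", "n_b", "match_fraction"]
        ).to_csv(os.path.join(config.out_dir, "cross_match.tsv"), sep="\t", index=False)
        rows = [
            {
                "sequence": c.tag.sequence,
                "class": c.klass,
                "repeat_family": c.repeat_family or ".",
            }
            for c in ras_calls + nat_calls
        ]
        pd.DataFrame(rows).to_csv(
            os.path.join(config.out_dir, "sirna_calls.tsv"), sep="\t", index=False
        )
        log.append(
            {
                "stage": "sirna",
                "rasirna": len(ras_calls),
                "nat_classified": len(nat_calls),
            }
        )
        return ras_calls, nat_calls

    ras_calls, nat_calls = stage("sirna")(_sirna)
    results["rasirna_calls"] = ras_calls
    results["nat_calls"] = nat_calls

    def _targets():
        if not config.genes_gff:
            return None
        hits = []
        gene_by_id = {}
        searched = 0
        for gene in genome.annotations.genes:
            if not gene.has_utr_annotation:
                continue
            searched += 1
            gene_by_id[gene.gene_id] = gene
            tseq = gene.transcript_sequence(genome.chromosomes[gene.chrom])
            for call in mirna_calls:
                mid = call.mature
                for h in targets.scan_animal_sites(mid, mid, gene.gene_id, tseq):
                    h.region = targets.assign_region(h, gene)
                    hits.append(h)
                if len(mid) >= 18:
                    for h in targets.scan_plant_sites(
                        mid, mid, gene.gene_id, tseq, mfe_max=config.hybrid_mfe_max
                    ):
                        h.region = targets.assign_region(h, gene)
                        hits.append(h)
        pd.DataFrame([vars(h) for h in hits]).to_csv(
            os.path.join(config.out_dir, "targets.tsv"), sep="\t", index=False
        )
        summary = _target_summary(hits, searched)
        pd.DataFrame([summary]).to_csv(
            os.path.join(config.out_dir, "target_summary.tsv"), sep="\t", index=False
        )
        go_df = None
        if config.go_map:
            go_map = targets.read_go_map(config.go_map)
            target_genes = {h.transcript_id for h in hits}
            all_genes = {g.gene_id for g in genome.annotations.genes}
            go_df = targets.go_ratio(target_genes, go_map, all_genes)
            go_df.to_csv(os.path.join(config.out_dir, "go_ratio.tsv"), sep="\t")
        log.append(
            {
                "stage": "targets",
                "transcripts_searched": searched,
                "hits": len(hits),
            }
        )
        return {"hits": hits, "summary": summary, "go": go_df}

    results["targets"] = stage("targets")(_targets)

    if config.truth:
        truth = TruthManifest.read(config.truth)
        report = score_recovery(mirna_calls, ras_calls, nat_calls, truth)
        report.as_frame().to_csv(
            os.path.join(config.out_dir, "recovery.tsv"), sep="\t"
        )
        results["recovery"] = report

    with open(os.path.join(config.out_dir, "run_log.json"), "w") as fh:
        json.dump(log, fh, indent=2)
    return results


def _target_summary(hits, searched: int) -> dict:
    out = {"transcripts_searched": searched}
    for mode in ("plant", "animal"):
        sub = [h for h in hits if h.mode == mode]
        with_t = len({h.transcript_id for h in sub})
        out[f"{mode}_transcripts_with_targets_pct"] = (
            100.0 * with_t / searched if searched else 0.0
        )
        known = [h for h in sub if h.region != "unknown"]
        for region in ("cds", "three-utr", "five-utr"):
            out[f"{mode}_{region}_site_pct"] = (
                100.0 * sum(1 for h in known if h.region == region) / len(known)
                if known
                else 0.0
            )
    return out


def _write_mirna_calls(calls, out_dir) -> None:
    rows = []
    for c in calls:
        a = c.alignment
        rows.append(
            {
                "mature": c.mature,
                "length": len(c.mature),
                "mature_reads": c.tag.total_count,
                "star": c.star_sequence or ".",
                "star_libraries": ",".join(c.libraries_with_star) or ".",
                "locus": f"{a.chrom}:{a.start}-{a.end}",
                "orientation": a.strand,
                "structure": c.candidate.structure,
                "mfe": c.candidate.mfe,
                "loop_length": c.candidate.loop_length,
                "max_bulge": c.candidate.max_bulge,
                "precursor_length": len(c.candidate.precursor),
                "locus_class": c.locus_class,
                "libraries": ",".join(c.libraries_with_mature),
                "seed_hits": ";".join(
                    f"{n}@{o}mm{m}" for n, o, m in c.seed_hits
                )
                or ".",
            }
        )
    pd.DataFrame(rows).to_csv(
        os.path.join(out_dir, "mirna_calls.tsv"), sep="\t", index=False
    )
    with open(os.path.join(out_dir, "precursors.txt"), "w") as fh:
        for c in calls:
            fh.write(f">{c.mature}\n{c.candidate.precursor}\n{c.candidate.structure}\n")
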