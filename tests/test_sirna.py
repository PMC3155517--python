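import random

import numpy as np
import pytest

from srnapipe.genome import AnnotationSet, GeneModel, GenomeBundle, RepeatInterval
from srnapipe.sirna import (
    _best_ungapped_score,
    call_rasirna,
    classify_nat_sirna,
    cross_library_match,
    distribution_summary,
)
from srnapipe.tags import Alignment, TagRecord


def _bundle(repeats=(), genes=()):
    return GenomeBundle(
        chromosomes={"c": "A" * 10000},
        annotations=AnnotationSet(genes=list(genes), repeats=list(repeats)),
    )


def _tag(seq, start, end, strand="+", lib="EF", chrom="c"):
    return TagRecord(
        sequence=seq,
        counts={lib: 1},
        alignments=[Alignment(chrom, start, end, strand, 0)],
    )


COPIA = RepeatInterval("c", 1000, 1400, "+", "Copia", "LTR/Copia")
GYPSY = RepeatInterval("c", 2000, 2300, "+", "Gypsy", "LTR/Gypsy")
HARB = RepeatInterval("c", 3000, 3200, "+", "Harbinger", "DNA/Harbinger")


def test_tag_inside_repeat_is_rasirna():
    calls, _ = call_rasirna([_tag("A" * 22, 1100, 1122)], _bundle([COPIA]))
    assert len(calls) == 1
    assert calls[0].klass == "rasirna" and calls[0].repeat_family == "LTR/Copia"


def test_single_nucleotide_overlap_counts():
    calls, _ = call_rasirna([_tag("A" * 22, 978, 1001)], _bundle([COPIA]))
    assert len(calls) == 1
    calls, _ = call_rasirna([_tag("A" * 22, 978, 1000)], _bundle([COPIA]))
    assert calls == []  # abutting, zero overlap


def test_family_table_percentages():
    bundle = _bundle([COPIA, GYPSY, HARB])
    tags = [
        _tag("A" * 21, 1100, 1121),
        _tag("C" * 21, 1200, 1221),
        _tag("G" * 21, 2100, 2121),
        _tag("T" * 21, 3100, 3121),
    ]
    _, table = call_rasirna(tags, bundle)
    assert table["EF"].sum() == pytest.approx(100.0)
    assert table.loc["LTR/Copia", "EF"] == pytest.approx(50.0)
    assert table.loc["LTR/Gypsy", "EF"] == pytest.approx(25.0)
    assert table.loc["DNA/Harbinger", "EF"] == pytest.approx(25.0)


# ----------------------------------------------------------------------
# cross-library matching


def _tagset(seqs):
    return [TagRecord(sequence=s, counts={"x": 1}) for s in seqs]


def test_cross_match_reflexive():
    rng = random.Random(1)
    seqs = ["".join(rng.choice("ACGT") for _ in range(25)) for _ in range(10)]
    assert cross_library_match(_tagset(seqs), _tagset(seqs)) == 1.0


def test_cross_match_disjoint_random_sets():
    rng = random.Random(2)
    a = ["".join(rng.choice("ACGT") for _ in range(25)) for _ in range(15)]
    b = ["".join(rng.choice("ACGT") for _ in range(25)) for _ in range(15)]
    # verify no long shared words that could reach the score cutoff
    words = {s[i : i + 13] for s in a for i in range(13)}
    assert not any(w in s for w in words for s in b)
    assert cross_library_match(_tagset(a), _tagset(b)) == 0.0


def test_cross_match_single_shared_sequence():
    rng = random.Random(3)
    shared = "".join(rng.choice("ACGT") for _ in range(25))
    a = _tagset([shared] + ["".join(rng.choice("ACGT") for _ in range(25))])
    b = _tagset(["".join(rng.choice("ACGT") for _ in range(25)), shared])
    assert cross_library_match(a, b) == pytest.approx(0.5)


def test_empty_comparison_set_warns():
    with pytest.warns(UserWarning):
        assert cross_library_match(_tagset(["ACGT" * 6]), []) == 0.0


def test_ungapped_score_against_numpy_diagonal_oracle():
    """Kadane-by-diagonal scoring equals an independent numpy maximum
    over every diagonal's running score."""
    rng = random.Random(4)
    for _ in range(30):
        a = "".join(rng.choice("ACGT") for _ in range(rng.randint(10, 30)))
        b = "".join(rng.choice("ACGT") for _ in range(rng.randint(10, 30)))
        best = 0
        for off in range(-(len(a) - 1), len(b)):
            vals = [
                1 if a[i] == b[i + off] else -3
                for i in range(max(0, -off), min(len(a), len(b) - off))
            ]
            run = np.array(vals).cumsum()
            prefix_min = np.minimum.accumulate(np.concatenate([[0], run[:-1]]))
            if len(vals):
                best = max(best, int((run - prefix_min).max()))
        assert _best_ungapped_score(a, b) == best


# ----------------------------------------------------------------------
# nat-siRNA orientation


GENE = GeneModel("g1", "c", "+", exons=[(5000, 5300), (5400, 5700)])


def test_antisense_orientation():
    calls, _ = classify_nat_sirna([_tag("A" * 25, 5100, 5125, "-")], _bundle(genes=[GENE]))
    assert calls[0].klass == "nat-antisense"


def test_sense_orientation_and_intron_overlap():
    calls, _ = classify_nat_sirna([_tag("A" * 25, 5320, 5345, "+")], _bundle(genes=[GENE]))
    # intron overlap still counts: orientation is against the pre-mRNA
    assert calls[0].klass == "nat-sense"


def test_mixed_alignments():
    tag = TagRecord(
        sequence="A" * 25,
        counts={"EF": 1},
        alignments=[
            Alignment("c", 5100, 5125, "+", 0),
            Alignment("c", 9000, 9025, "+", 0),
        ],
    )
    calls, _ = classify_nat_sirna([tag], _bundle(genes=[GENE]))
    assert calls[0].klass == "mixed"
    assert sorted(calls[0].sub_labels) == ["intergenic", "nat-sense"]


def test_planted_antisense_loci_recovered(clean_run):
    truth = clean_run["truth_manifest"]
    nat = {c.tag.sequence for c in clean_run["nat_calls"] if c.klass == "nat-antisense"}
    for locus in truth.of_type("natsirna"):
        assert locus.mature in nat


def test_distribution_partitions_tags(clean_run):
    tags = clean_run["tags"]
    mirna_seqs = {c.mature for c in clean_run["mirna_calls"]} | {
        c.star_sequence for c in clean_run["mirna_calls"] if c.star_sequence
    }
    df = distribution_summary(
        tags, mirna_seqs, clean_run["rasirna_calls"], clean_run["nat_calls"]
    )
    for lib in df.columns:
        assert df[lib].sum() == pytest.approx(100.0)
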