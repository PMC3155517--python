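import itertools

import pytest

from srnapipe.fold import SimpleFoldEngine
from srnapipe.mirna import (
    assess_precursor,
    evaluate_hairpin,
    evidence_ok,
    match_known_mirnas,
    predict_mirnas,
)
from srnapipe.tags import Alignment, TagRecord


class StubEngine:
    """Fold engine returning a fixed structure/energy, for testing the
    threshold comparisons in isolation."""

    def __init__(self, structure, mfe):
        self.structure, self.mfe = structure, mfe

    def fold(self, seq):
        return self.structure, self.mfe


def hairpin(stem=21, loop=12):
    """Perfect G:C hairpin with the mature arm 5' of the loop."""
    seq = "G" * stem + "A" * loop + "C" * stem
    return seq, (0, stem)


def test_designed_hairpin_passes_all_filters():
    seq, span = hairpin()
    res = assess_precursor(seq, span)
    assert res["verdicts"] == {"mfe": True, "arm": True, "bulge": True, "loop": True}
    assert res["loop_length"] == 12
    assert res["max_bulge"] == 0
    assert res["mfe"] == 21 * -3.0 + 4.0


@pytest.mark.parametrize("loop,passes", [(9, False), (10, True)])
def test_loop_length_boundary(loop, passes):
    """Terminal loop must span at least 10 nt."""
    seq, span = hairpin(loop=loop)
    res = assess_precursor(seq, span)
    assert res["loop_length"] == loop
    assert res["verdicts"]["loop"] is passes


@pytest.mark.parametrize("bulge,passes", [(3, True), (4, False)])
def test_bulge_size_boundary(bulge, passes):
    """The mature arm tolerates unpaired runs up to 3 nt."""
    stem = 20
    mature = "G" * 8 + "A" * bulge + "G" * (stem - 8)
    # star pairs only the G positions; the A run bulges out unpaired
    seq = mature + "A" * 12 + "C" * stem
    res = assess_precursor(seq, (0, len(mature)))
    assert res["max_bulge"] == bulge
    assert res["verdicts"]["bulge"] is passes


def test_mfe_threshold_is_strict():
    seq, span = hairpin()
    db = "(" * 21 + "." * 12 + ")" * 21
    for mfe, passes in [(-19.9, False), (-20.0, False), (-20.1, True)]:
        res = assess_precursor(seq, span, engine=StubEngine(db, mfe))
        assert res["verdicts"]["mfe"] is passes, mfe


def test_mature_arm_must_not_span_loop():
    seq, _ = hairpin()
    # a "mature" window straddling the loop pairs on both sides
    res = assess_precursor(seq, (15, 36))
    assert res["verdicts"]["arm"] is False


def test_unpaired_mature_fails():
    res = assess_precursor("A" * 60, (20, 40))
    assert not res["verdicts"]["arm"]


def test_star_interval_has_two_nt_overhang():
    seq, span = hairpin()
    res = assess_precursor(seq, span)
    # star arm = the 21 C's at positions 33..54, extended 2 nt at its 3' end
    assert res["star_span"] == (33, 54)  # clipped at sequence end


def test_filter_monotonicity_in_thresholds():
    """Relaxing (mfe, loop, bulge) thresholds can only grow the set of
    passing precursors."""
    import random

    rng = random.Random(13)
    precursors = []
    for _ in range(30):
        stem = rng.randint(8, 18)
        loop = rng.randint(6, 14)
        mature = "".join(rng.choice("GA") for _ in range(stem))
        star = "".join(
            {"G": "C", "A": "T"}[b] if rng.random() > 0.2 else "A"
            for b in reversed(mature)
        )
        precursors.append((mature + "C" * loop + star, (0, stem)))
    grids = [(-30.0, 12, 2), (-20.0, 10, 3), (-10.0, 8, 4)]
    engine = SimpleFoldEngine()
    passing = []
    for mfe_max, loop_min, bulge_max in grids:
        passing.append(
            {
                i
                for i, (seq, span) in enumerate(precursors)
                if all(
                    assess_precursor(
                        seq, span, engine, mfe_max, loop_min, bulge_max
                    )["verdicts"].values()
                )
            }
        )
    assert passing[0] <= passing[1] <= passing[2]


def test_evidence_rule():
    assert evidence_ok(2, False)
    assert evidence_ok(1, True)
    assert not evidence_ok(1, False)
    assert evidence_ok(3, True)


def test_evaluate_hairpin_on_planted_locus(sim_genome):
    bundle, truth = sim_genome
    locus = truth.of_type("mirna")[0]
    tag = TagRecord(sequence=locus.mature, counts={"EF": 1})
    aln = Alignment(locus.chrom, locus.start, locus.end, locus.strand, 0)
    cand = evaluate_hairpin(tag, aln, bundle)
    assert cand.passed
    assert abs(cand.star_interval.start - locus.star_start) <= 3
    assert abs(cand.star_interval.end - locus.star_end) <= 3
    assert len(cand.precursor) <= tag.length + 2 * 100


def test_repeat_overlapping_tags_never_called(sim_genome):
    bundle, truth = sim_genome
    ras = truth.of_type("rasirna")[0]
    tag = TagRecord(
        sequence=ras.mature,
        counts={"EF": 2, "EC": 2},
        alignments=[Alignment(ras.chrom, ras.start, ras.end, ras.strand, 0)],
    )
    assert predict_mirnas([tag], bundle) == []


@pytest.mark.parametrize(
    "mismatches,expected_hit", [(0, True), (1, True), (2, False)]
)
def test_known_mirna_seed_match_threshold(mismatches, expected_hit):
    """A seed hit needs >= 9 of 10 identities over the known 5' end."""
    mature = "TGAGGTAGTAGGTTGTATAGTT"
    known_seed = list(mature[:10])
    for i in range(mismatches):
        pos = 2 + 3 * i
        known_seed[pos] = {"A": "C", "C": "A", "G": "T", "T": "G"}[known_seed[pos]]
    known = {"kn-mir": "".join(known_seed) + "ACGTACGTACG"}

    class Call:
        pass

    call = Call()
    call.mature = mature
    call.seed_hits = []
    match_known_mirnas([call], known)
    assert bool(call.seed_hits) is expected_hit


def test_empty_known_set_yields_no_hits():
    class Call:
        mature = "TGAGGTAGTAGGTTGTATAGTT"
        seed_hits = []

    call = Call()
    match_known_mirnas([call], {})
    assert call.seed_hits == []
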