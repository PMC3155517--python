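import random

import pytest

from srnapipe.genome import GeneModel, revcomp
from srnapipe.targets import (
    TargetHit,
    assign_region,
    duplex_energy,
    go_ratio,
    scan_animal_sites,
    scan_plant_sites,
)

from .oracles import animal_sites_by_scan, plant_sites_by_scan

LET7 = "UGAGGUAGUAGGUUGUAUAGUU"


def test_animal_seed_site_found_by_hand():
    # seed nt 2-7 of let-7 is GAGGUA; its reverse complement is UACCUC
    transcript = "AAAAAUACCUCAAAAA"
    hits = scan_animal_sites("let7", LET7, "t1", transcript)
    assert [(h.start, h.end) for h in hits] == [(5, 11)]


def test_animal_scan_no_site():
    assert scan_animal_sites("let7", LET7, "t1", "A" * 40) == []


def test_animal_scan_linearity_on_duplication():
    segment = "GGGUACCUCGGG"
    hits = scan_animal_sites("let7", LET7, "t1", segment * 2)
    assert len(hits) == 2
    assert hits[1].start - hits[0].start == len(segment)


def test_plant_site_perfect_complement_energy():
    """13 G:C plus 8 A:U pairs give -55 kcal/mol and zero defects."""
    rng = random.Random(8)
    bases = ["G"] * 13 + ["A"] * 8
    rng.shuffle(bases)
    mirna = "".join(bases)
    site = revcomp(mirna)
    transcript = "AAACCC" + site + "CCCAAA"
    hits = scan_plant_sites("m", mirna, "t1", transcript)
    assert len(hits) == 1
    h = hits[0]
    assert h.hybrid_mfe == pytest.approx(13 * -3.0 + 8 * -2.0)
    assert h.mismatches_in_seed == 0 and h.mismatches_outside == 0


def test_plant_seed_defect_budget():
    """Two defects in the 8-nt seed region disqualify a site."""
    mirna = "G" * 21
    site = list(revcomp(mirna))
    # defects opposite miRNA positions 2 and 5 (inside the seed)
    site[len(site) - 1 - 2] = "A"
    site[len(site) - 1 - 5] = "A"
    hits = scan_plant_sites("m", mirna, "t1", "".join(site))
    assert hits == []
    site[len(site) - 1 - 5] = "C"  # restore one -> 1 seed defect, allowed
    hits = scan_plant_sites("m", mirna, "t1", "".join(site))
    assert len(hits) == 1 and hits[0].mismatches_in_seed == 1


def test_plant_all_au_duplex():
    mirna = "A" * 18
    hits = scan_plant_sites("m", mirna, "t1", "CCC" + "T" * 18 + "CCC")
    assert len(hits) == 1
    assert hits[0].hybrid_mfe == pytest.approx(18 * -2.0)


def test_plant_mode_requires_long_mirna():
    with pytest.raises(ValueError):
        scan_plant_sites("m", "A" * 10, "t1", "T" * 40)


def test_wobble_counts_as_defect_but_scores_energy():
    # miRNA G opposite transcript T forms a wobble: -1 kcal/mol, 1 defect
    mirna = "G" * 21
    site = list(revcomp(mirna))
    site[0] = "T"  # opposite miRNA position 20 (outside the seed)
    hits = scan_plant_sites("m", mirna, "t1", "".join(site))
    assert len(hits) == 1
    assert hits[0].mismatches_outside == 1
    assert hits[0].hybrid_mfe == pytest.approx(20 * -3.0 + -1.0)


def test_scan_against_position_by_position_oracle():
    rng = random.Random(31)
    for _ in range(25):
        mirna = "".join(rng.choice("ACGT") for _ in range(rng.randint(18, 24)))
        transcript = "".join(rng.choice("ACGT") for _ in range(300))
        # plant sites themselves in half the trials
        if rng.random() < 0.5:
            pos = rng.randint(0, 300 - len(mirna))
            transcript = (
                transcript[:pos] + revcomp(mirna) + transcript[pos + len(mirna):]
            )
        got = scan_plant_sites("m", mirna, "t", transcript, resolve_overlaps=False)
        expect = plant_sites_by_scan(mirna, transcript)
        assert [(h.start, h.mismatches_in_seed, h.mismatches_outside) for h in got] == [
            (p, sd, rd) for p, sd, rd, _ in expect
        ]
        got_a = scan_animal_sites("m", mirna, "t", transcript)
        assert [h.start for h in got_a] == animal_sites_by_scan(mirna, transcript)


def test_site_coordinates_shift_with_prefix():
    mirna = "G" * 13 + "A" * 8
    transcript = "CCC" + revcomp(mirna) + "CCC"
    base = scan_plant_sites("m", mirna, "t", transcript)
    shifted = scan_plant_sites("m", mirna, "t", "ACGTACG" + transcript)
    assert shifted[0].start - base[0].start == 7


def test_overlap_resolution_keeps_lowest_energy():
    mirna = "G" * 21
    # tandem G-runs create many overlapping candidate placements
    transcript = "C" * 60
    hits = scan_plant_sites("m", mirna, "t", transcript)
    starts = [h.start for h in hits]
    for a, b in zip(hits, hits[1:]):
        assert a.end <= b.start  # non-overlapping after resolution


# ----------------------------------------------------------------------
# region assignment


GENE = GeneModel(
    "g1",
    "c",
    "+",
    exons=[(0, 300)],
    cds=[(100, 250)],
    five_utr=[(0, 100)],
    three_utr=[(250, 300)],
)


@pytest.mark.parametrize(
    "start,end,region",
    [(10, 30, "five-utr"), (120, 140, "cds"), (260, 280, "three-utr")],
)
def test_region_by_midpoint(start, end, region):
    hit = TargetHit("m", "g1", start, end, "plant")
    assert assign_region(hit, GENE) == region


def test_region_unknown_without_utr_annotation():
    gene = GeneModel("g2", "c", "+", exons=[(0, 300)])
    hit = TargetHit("m", "g2", 10, 30, "plant")
    assert assign_region(hit, gene) == "unknown"


# ----------------------------------------------------------------------
# GO ratio


def test_go_ratio_arithmetic():
    go_map = {f"g{i}": {"GO:1"} for i in range(10)}
    go_map.update({f"g{i}": {"GO:1", "GO:2"} for i in range(2)})
    all_genes = {f"g{i}" for i in range(40)}
    for g in all_genes - set(go_map):
        go_map[g] = {"GO:3"}
    targets = {f"g{i}" for i in range(10)}
    df = go_ratio(targets, go_map, all_genes)
    # GO:2 covers 20% of targets but 5% of the genome: ratio 4
    assert df.loc["GO:2", "ratio"] == pytest.approx(4.0)
    # GO:1 covers 100% of targets, 25% of genome
    assert df.loc["GO:1", "ratio"] == pytest.approx(4.0)
    assert df.index[0] in ("GO:1", "GO:2")


def test_go_ratio_empty_targets():
    assert go_ratio(set(), {"g1": {"GO:1"}}, {"g1"}).empty


def test_go_ratio_term_missing_from_genome_warns():
    with pytest.warns(UserWarning):
        df = go_ratio({"g1"}, {"g1": {"GO:9"}}, {"g2"})
    assert "GO:9" not in df.index


def test_duplex_energy_antiparallel():
    assert duplex_energy("GGG", "CCC") == pytest.approx(-9.0)
    assert duplex_energy("GAU", revcomp("GAT")) == pytest.approx(-3 - 2 - 2)
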