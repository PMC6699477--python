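"""Two-box σ32 scanning, Shine-Dalgarno scanning, operons and the regulon
screen, each checked against an independent exhaustive oracle."""

import itertools

import numpy as np
import pytest

from endofootprint.genome import revcomp
from endofootprint.motifs import (
    HEAT_SHOCK_REGULON,
    IUPAC,
    TwoBoxMotif,
    predict_operons,
    regulon_screen,
    scan_sd,
    scan_two_box,
    sigma32_sites,
    upstream_window,
)

from conftest import make_gene, make_genome


def _mm(window, pattern):
    return sum(
        1 for c, p in zip(window, pattern) if c not in IUPAC[p]
    )


def _oracle_two_box(seq, motif):
    """Exhaustive placement oracle on the forward strand of ``seq``."""
    out = []
    m35, m10 = len(motif.box35), len(motif.box10)
    for i in range(len(seq) - m35 + 1):
        mm35 = _mm(seq[i : i + m35], motif.box35)
        if mm35 > motif.max_mm35:
            continue
        for sp in range(motif.spacer_min, motif.spacer_max + 1):
            j = i + m35 + sp
            if j + m10 > len(seq):
                continue
            mm10 = _mm(seq[j : j + m10], motif.box10)
            if mm10 <= motif.max_mm10:
                out.append((i, j, sp, mm35, mm10))
    return out


def _rand_seq(rng, n, gc=0.26):
    p = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]
    return "".join(np.array(list("ACGT"))[rng.choice(4, size=n, p=p)])


def test_two_box_exact_hit_and_coordinates():
    seq = "T" * 30 + "CTTGAAA" + "A" * 13 + "CCCCATGT" + "T" * 30
    hits = scan_two_box(seq, strands="+")
    assert len(hits) == 1
    h = hits[0]
    assert h.box35_start == 30
    assert h.box10_start == 30 + 7 + 13
    assert (h.spacer_len, h.mm35, h.mm10) == (13, 0, 0)
    # pattern N matches any base at the penultimate box10 position
    assert scan_two_box(seq.replace("CCCCATGT", "CCCCATCT"), strands="+")


def test_two_box_budgets_and_spacer_bounds():
    mk = lambda sp, b35="CTTGAAA", b10="CCCCATGT": "T" * 10 + b35 + "A" * sp + b10 + "T" * 10
    assert scan_two_box(mk(11), strands="+")
    assert scan_two_box(mk(15), strands="+")
    assert not scan_two_box(mk(10), strands="+")
    assert not scan_two_box(mk(16), strands="+")
    assert scan_two_box(mk(13, b35="CTTGAAC"), strands="+")  # 1 mm in -35
    assert not scan_two_box(mk(13, b35="CTTGACC"), strands="+")  # 2 mm
    assert scan_two_box(mk(13, b10="CCCCGGGT"), strands="+")  # 2 mm in -10
    assert not scan_two_box(mk(13, b10="CCCGGGGT"), strands="+")  # 3 mm


def test_two_box_reverse_strand_coordinates():
    fwd = "T" * 25 + "CTTGAAA" + "A" * 12 + "CCCCATGT" + "T" * 25
    seq = revcomp(fwd)
    hits = scan_two_box(seq)
    minus = [h for h in hits if h.strand == "-"]
    assert len(minus) == 1
    h = minus[0]
    n = len(seq)
    # map back: the -35 box occupies fwd positions 25..32
    s, e = h.box35_interval()
    assert revcomp(seq[s:e]) == "CTTGAAA" or seq[s:e] == revcomp("CTTGAAA")
    assert (n - e, n - s) == (25, 32)


def test_two_box_matches_exhaustive_oracle_on_random_sequences(rng):
    motif = TwoBoxMotif()
    for _ in range(40):
        seq = _rand_seq(rng, 600)
        got = [
            (h.box35_start, h.box10_start, h.spacer_len, h.mm35, h.mm10)
            for h in scan_two_box(seq, motif, strands="+")
        ]
        assert sorted(got) == sorted(_oracle_two_box(seq, motif))


def test_two_box_strand_symmetry(rng):
    motif = TwoBoxMotif()
    for _ in range(10):
        seq = _rand_seq(rng, 400)
        plus = [(h.box35_start, h.spacer_len) for h in scan_two_box(seq, motif, "+")]
        n = len(seq)
        minus_rc = [
            (n - h.box35_interval()[1], h.spacer_len)
            for h in scan_two_box(revcomp(seq), motif)
            if h.strand == "-"
        ]
        assert sorted(plus) == sorted(minus_rc)


# ---------------------------------------------------------------------------
# upstream windows


def _toy_genome():
    seq = "".join(np.array(list("ACGT"))[np.random.default_rng(5).integers(0, 4, 1000)])
    genes = [
        make_gene("g1", 100, 220),
        make_gene("g2", 300, 420),
        make_gene("g3", 600, 720, strand="-"),
    ]
    return make_genome(seq, genes)


def test_upstream_window_plus_strand_truncation():
    g = _toy_genome()
    win, usable, trunc = upstream_window(g, g.gene("g2"), 200)
    assert trunc and usable == 80  # g1 ends at 220
    assert win == g.sequence[220:300]


def test_upstream_window_minus_strand_is_revcomp():
    g = _toy_genome()
    win, usable, trunc = upstream_window(g, g.gene("g3"), 200)
    assert win == revcomp(g.sequence[720:920])
    assert usable == 200 and not trunc


def test_upstream_window_wraps_circular_origin():
    seq = "A" * 50 + "C" * 950
    g = make_genome(seq, [make_gene("g1", 20, 120)])
    win, usable, trunc = upstream_window(g, g.gene("g1"), 100, truncate_at_gene=False)
    assert usable == 100
    assert win == (seq + seq)[920:1020]


def test_upstream_window_without_truncation():
    g = _toy_genome()
    win, usable, trunc = upstream_window(g, g.gene("g2"), 200, truncate_at_gene=False)
    assert win == g.sequence[100:300]
    assert usable == 200


# ---------------------------------------------------------------------------
# sigma32_sites


def test_sigma_site_recovery_at_known_distance():
    rng = np.random.default_rng(11)
    up = _rand_seq(rng, 200)
    site = "CTTGAAA" + "A" * 13 + "CCCCATGT"
    # place site so the -10 box ends 60 nt before the start codon
    up = up[: 200 - 60 - len(site)] + site + up[200 - 60 :]
    assert len(up) == 200
    seq = up + "ATG" + _rand_seq(rng, 97)
    g = make_genome(seq, [make_gene("g1", 200, 300)], topology="linear")
    sites = sigma32_sites(g, ["g1"], 200)
    assert len(sites) == 1
    s = sites[0]
    assert s.assigned_gene == "g1"
    assert s.distance_to_start == 60
    assert s.strand == "+"


def test_sigma_site_assigned_to_operon_head():
    rng = np.random.default_rng(12)
    up = _rand_seq(rng, 150)
    site = "CTTGAAA" + "A" * 12 + "CCCCATGT"
    up = up[: 150 - 40 - len(site)] + site + up[150 - 40 :]
    seq = up + "ATGAAA" * 20 + "T" * 10 + "ATGCCC" * 20 + _rand_seq(rng, 100)
    genes = [make_gene("head", 150, 270), make_gene("member", 280, 400)]
    g = make_genome(seq, genes, topology="linear")
    ops = predict_operons(g)
    assert any(op.genes == ("head", "member") for op in ops)
    # scanning the downstream member finds the promoter upstream of the head
    sites = sigma32_sites(g, ["member"], 200, operons=ops)
    assert len(sites) == 1
    assert sites[0].assigned_gene == "head"
    assert sites[0].operon_genes == ("head", "member")


def test_sigma_sites_deduplicated_across_operon_members():
    rng = np.random.default_rng(12)
    up = _rand_seq(rng, 150)
    site = "CTTGAAA" + "A" * 12 + "CCCCATGT"
    up = up[: 150 - 40 - len(site)] + site + up[150 - 40 :]
    seq = up + "ATGAAA" * 20 + "T" * 10 + "ATGCCC" * 20 + _rand_seq(rng, 100)
    genes = [make_gene("head", 150, 270), make_gene("member", 280, 400)]
    g = make_genome(seq, genes, topology="linear")
    ops = predict_operons(g)
    sites = sigma32_sites(g, ["head", "member"], 200, operons=ops)
    assert len(sites) == 1


def test_planted_sigma_sites_in_quartet(quartet):
    genomes, truth = quartet
    for g in genomes:
        sites = sigma32_sites(g, [x.id for x in g.genes], 200, operons=predict_operons(g))
        planted = truth.by_kind(g.id, "sigma")
        assert len(planted) == 2
        for rec in planted:
            assert any(
                s.box35[0] >= rec.start - 2 and s.box10[1] <= rec.end + 2 for s in sites
            ), f"planted site {rec} not recovered in {g.id}"


# ---------------------------------------------------------------------------
# SD scanning


def _oracle_sd(seq, consensus="AGGAG", max_mm=1):
    hits = []
    for i in range(len(seq) - 4):
        w = seq[i : i + 5]
        mm = sum(a != b for a, b in zip(w, consensus))
        if mm <= max_mm:
            hits.append((i, mm))
    return hits


def test_sd_hamming_ball_oracle(rng):
    for _ in range(40):
        seq = _rand_seq(rng, 300)
        got = [(h.start, h.mismatches) for h in scan_sd([("s", seq)], merge_within=0)]
        assert got == _oracle_sd(seq)


def test_sd_exact_only_mode():
    seq = "TTAGGAGTTAGGTGTT"
    assert [(h.start, h.mismatches) for h in scan_sd([("s", seq)], max_mm=0, merge_within=0)] == [(2, 0)]


def test_sd_merging_keeps_best_hit():
    # AGGAGG: exact hit at 0 and 1-mm hit at 1 -> merged to the exact one
    seq = "AGGAGG" + "T" * 20
    hits = scan_sd([("s", seq)])
    assert len(hits) == 1
    assert hits[0].start == 0 and hits[0].mismatches == 0


def test_sd_distance_to_start_annotation():
    seq = "T" * 10 + "AGGAG" + "T" * 7 + "ATGAAA"
    hits = scan_sd([("s", seq)], start_offsets={"s": 22})
    assert len(hits) == 1
    assert hits[0].distance_to_start == 7  # 3' end of SD to the ATG
    far = "AGGAG" + "T" * 30 + "ATG"
    h2 = scan_sd([("s", far)], start_offsets={"s": 35})
    assert h2[0].distance_to_start is None  # > 20 nt away


def test_planted_sd_sites_recovered_in_zero_mutation_quartet(quartet_zero):
    genomes, truth = quartet_zero
    g = genomes[0]
    planted = truth.by_kind(g.id, "sd")
    assert len(planted) == 20
    hits = scan_sd([(g.id, g.sequence)], merge_within=0)
    starts = {h.start for h in hits}
    for rec in planted:
        assert rec.start in starts


# ---------------------------------------------------------------------------
# operons


def test_operon_prediction_rules():
    genes = [
        make_gene("a", 0, 100),
        make_gene("b", 120, 200),          # gap 20 -> same operon
        make_gene("c", 300, 380),          # gap 100 -> new operon
        make_gene("d", 390, 450, strand="-"),  # strand switch -> new operon
    ]
    g = make_genome("A" * 1000, genes, topology="linear")
    ops = predict_operons(g)
    assert [op.genes for op in ops] == [("a", "b"), ("c",), ("d",)]
    assert ops[0].head == "a"
    assert ops[2].head == "d"  # 5'-most gene on the minus strand is rightmost...


def test_minus_strand_operon_head_is_rightmost_gene():
    genes = [make_gene("x", 100, 200, strand="-"), make_gene("y", 220, 320, strand="-")]
    g = make_genome("A" * 1000, genes, topology="linear")
    ops = predict_operons(g)
    assert len(ops) == 1
    assert ops[0].head == "y"


def test_operon_joins_across_circular_origin():
    genes = [make_gene("a", 10, 100), make_gene("b", 950, 995)]
    g = make_genome("A" * 1000, genes)
    ops = predict_operons(g)
    assert len(ops) == 1
    assert ops[0].genes == ("b", "a")


def test_simulated_operon_structure_matches_truth(quartet):
    genomes, truth = quartet
    g = genomes[0]
    ops = predict_operons(g)
    by_gene = {}
    for op in ops:
        for x in op.genes:
            by_gene[x] = op
    for op_indices in truth.operon_map:
        ids = [truth.ortholog_map[i][g.id] for i in op_indices]
        assert len({id(by_gene[x]) for x in ids}) == 1, f"operon {ids} split"
        assert by_gene[ids[0]].head == ids[0]


# ---------------------------------------------------------------------------
# regulon screen


def test_regulon_screen_finds_planted_names(quartet):
    genomes, _ = quartet
    df = regulon_screen(genomes)
    assert list(df.columns) == list(HEAT_SHOCK_REGULON)
    assert df.shape == (4, 15)
    assert df.notna().all().all()


def test_regulon_screen_absent_name_and_warning():
    g = make_genome("A" * 300, [make_gene("g1", 0, 100, gene_name="dnaK")], topology="linear")
    df = regulon_screen([g], regulon=["dnaK", "zzzZ"])
    assert df.loc[g.id, "dnaK"] == "g1"
    assert df.loc[g.id, "zzzZ"] is None
    with pytest.warns(UserWarning):
        regulon_screen([g], regulon=["zzzZ"])


def test_regulon_screen_propagates_through_orthologs():
    from endofootprint.orthology import find_orthologs

    prot = "M" + "ACDEFGHIKLMNPQRSTVWY" * 3
    ga = make_genome("A" * 300, [make_gene("a1", 0, 100, gene_name="dnaK", translation=prot)], gid="A", topology="linear")
    gb = make_genome("A" * 300, [make_gene("b1", 0, 100, translation=prot)], gid="B", topology="linear")
    table = find_orthologs([ga, gb])
    df = regulon_screen([ga, gb], regulon=["dnaK"], ortholog_table=table)
    assert df.loc["A", "dnaK"] == "a1"
    assert df.loc["B", "dnaK"] == "b1"
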