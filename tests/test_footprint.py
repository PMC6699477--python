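"""Orthologous-IGS pairing, center-star alignment, conserved loci and the
spacer-length association statistic."""

import numpy as np
import pytest

from endofootprint.footprint import (
    IGSAlignment,
    align_group,
    conserved_loci,
    length_association,
    pair_orthologous_igs,
)
from endofootprint.genome import IntergenicSpacer, extract_igs, revcomp
from endofootprint.orthology import OrthoGroup, OrthologTable, find_orthologs


def _spacer(gid, left, right, seq, start=0, lstrand="+", rstrand="+"):
    return IntergenicSpacer(
        genome_id=gid,
        start=start,
        end=start + len(seq),
        left_gene=left,
        right_gene=right,
        left_strand=lstrand,
        right_strand=rstrand,
        sequence=seq,
    )


def _table(genomes, mapping):
    """mapping: group id -> {genome: gene}."""
    groups = [OrthoGroup(group_id=k, members=dict(v)) for k, v in mapping.items()]
    return OrthologTable(genomes=list(genomes), groups=groups)


# ---------------------------------------------------------------------------
# pairing


def test_pairing_matches_flank_groups():
    table = _table(
        ["A", "B"],
        {"OG1": {"A": "a1", "B": "b1"}, "OG2": {"A": "a2", "B": "b2"}},
    )
    spacers = {
        "A": [_spacer("A", "a1", "a2", "ACGTACGT")],
        "B": [_spacer("B", "b1", "b2", "ACGAACGT")],
    }
    groups = pair_orthologous_igs(table, spacers)
    assert len(groups) == 1
    grp = groups[0]
    assert set(grp.members) == {"A", "B"}
    assert (grp.left_group, grp.right_group) == ("OG1", "OG2")
    assert not any(grp.flipped.values())


def test_pairing_normalizes_flipped_orientation():
    table = _table(
        ["A", "B"],
        {"OG1": {"A": "a1", "B": "b1"}, "OG2": {"A": "a2", "B": "b2"}},
    )
    seq = "ACGTTTTACG"
    spacers = {
        "A": [_spacer("A", "a1", "a2", seq)],
        # in B the locus is inverted: flank order reversed
        "B": [_spacer("B", "b2", "b1", revcomp(seq), lstrand="-", rstrand="-")],
    }
    groups = pair_orthologous_igs(table, spacers)
    assert len(groups) == 1
    grp = groups[0]
    flipped = [g for g, f in grp.flipped.items() if f]
    assert len(flipped) == 1
    # oriented sequences agree after normalization
    assert grp.oriented_sequence("A") == grp.oriented_sequence("B")


def test_pairing_skips_duplicated_flank_pairs():
    table = _table(
        ["A", "B"],
        {"OG1": {"A": "a1", "B": "b1"}, "OG2": {"A": "a2", "B": "b2"}},
    )
    spacers = {
        "A": [_spacer("A", "a1", "a2", "ACGT"), _spacer("A", "a1", "a2", "TTTT", start=500)],
        "B": [_spacer("B", "b1", "b2", "ACGT")],
    }
    assert pair_orthologous_igs(table, spacers) == []


def test_pairing_min_genomes_threshold():
    table = _table(
        ["A", "B", "C"],
        {"OG1": {"A": "a1", "B": "b1", "C": "c1"}, "OG2": {"A": "a2", "B": "b2", "C": "c2"}},
    )
    spacers = {
        "A": [_spacer("A", "a1", "a2", "ACGT")],
        "B": [_spacer("B", "b1", "b2", "ACGT")],
        "C": [],
    }
    assert pair_orthologous_igs(table, spacers) == []  # default: all genomes
    assert len(pair_orthologous_igs(table, spacers, min_genomes=2)) == 1


def test_quartet_pairing_is_complete_and_consistent(quartet):
    genomes, truth = quartet
    table = find_orthologs(genomes)
    spacers = {g.id: extract_igs(g, min_len=1) for g in genomes}
    groups = pair_orthologous_igs(table, spacers)
    # simulator never rearranges, so every spacer present in all four pairs up
    assert len(groups) == 60
    for grp in groups:
        assert set(grp.members) == {g.id for g in genomes}
        assert grp.orientation_consistent


# ---------------------------------------------------------------------------
# alignment + conserved loci


def _group(seqs):
    from endofootprint.footprint import OrthologousIGSGroup

    members = {gid: _spacer(gid, "l", "r", s) for gid, s in seqs.items()}
    return OrthologousIGSGroup(
        group_id="IG0001",
        members=members,
        left_group="OG1",
        right_group="OG2",
        flipped={gid: False for gid in seqs},
    )


def test_alignment_rows_degap_to_inputs():
    seqs = {
        "A": "ACGTACGTACGTAAATTT",
        "B": "ACGTACGACGTAAATTT",  # one deletion
        "C": "ACGTACGTACGTAAATTTG",  # one insertion
    }
    aln = align_group(_group(seqs))
    assert len({len(r) for r in aln.rows}) == 1
    for gid, row in zip(aln.genome_ids, aln.rows):
        assert row.replace("-", "") == seqs[gid]


def test_identical_members_align_without_gaps():
    seqs = {x: "ACGTGGTACCAT" * 3 for x in "ABCD"}
    aln = align_group(_group(seqs))
    assert all(r == "ACGTGGTACCAT" * 3 for r in aln.rows)
    loci = conserved_loci(aln, min_len=21)
    assert len(loci) == 1
    assert loci[0].consensus == "ACGTGGTACCAT" * 3


def _oracle_loci_columns(rows, min_len):
    """Per-column scan oracle: identical, gap-free column runs >= min_len."""
    n = len(rows[0])
    good = [
        len({r[c] for r in rows}) == 1 and rows[0][c] != "-" for c in range(n)
    ]
    runs, c = [], 0
    while c < n:
        if good[c]:
            s = c
            while c < n and good[c]:
                c += 1
            if c - s >= min_len:
                runs.append((s, c))
        else:
            c += 1
    return runs


def test_conserved_loci_match_column_oracle(rng):
    for _ in range(25):
        n = int(rng.integers(30, 120))
        base = "".join(np.array(list("ACGT"))[rng.integers(0, 4, n)])
        rows = []
        for _k in range(3):
            chars = list(base)
            for p in rng.integers(0, n, int(rng.integers(0, 6))):
                chars[p] = "ACGT"[int(rng.integers(0, 4))]
            rows.append("".join(chars))
        aln = IGSAlignment(group_id="IG", genome_ids=["A", "B", "C"], rows=rows)
        got = [(lc.col_start, lc.col_end) for lc in conserved_loci(aln, min_len=5)]
        assert got == _oracle_loci_columns(rows, 5)


def test_locus_run_shorter_than_threshold_excluded():
    rows = ["A" * 20 + "C" + "G" * 21, "A" * 20 + "T" + "G" * 21]
    aln = IGSAlignment(group_id="IG", genome_ids=["A", "B"], rows=rows)
    loci = conserved_loci(aln, min_len=21)
    assert [(lc.col_start, lc.col_end) for lc in loci] == [(21, 42)]
    # exactly-20-long run is excluded (strictly more than 20 nt required)
    assert conserved_loci(
        IGSAlignment(group_id="IG", genome_ids=["A", "B"], rows=["A" * 20, "A" * 20]),
        min_len=21,
    ) == []


def test_locus_coordinates_map_back_to_genomes():
    seqs = {"A": "TT" + "ACGTGGTACCATACGTGGTACCAT" + "GG",
            "B": "ACGTGGTACCATACGTGGTACCAT"}
    grp = _group(seqs)
    grp.members["A"] = _spacer("A", "l", "r", seqs["A"], start=100)
    grp.members["B"] = _spacer("B", "l", "r", seqs["B"], start=500)
    aln = align_group(grp)
    loci = conserved_loci(aln, grp, min_len=21)
    assert len(loci) == 1
    lc = loci[0]
    sa, ea, _ = lc.coords["A"]
    sb, eb, _ = lc.coords["B"]
    assert seqs["A"][sa - 100 : ea - 100] == lc.consensus
    assert seqs["B"][sb - 500 : eb - 500] == lc.consensus


def test_locus_coordinates_on_flipped_member():
    from endofootprint.footprint import OrthologousIGSGroup

    fwd = "ACGTGGTACCATACGTGGTACCAT"
    members = {
        "A": _spacer("A", "l", "r", fwd, start=10),
        "B": _spacer("B", "r", "l", revcomp(fwd), start=300),
    }
    grp = OrthologousIGSGroup(
        group_id="IG0001",
        members=members,
        left_group="OG1",
        right_group="OG2",
        flipped={"A": False, "B": True},
    )
    aln = align_group(grp)
    loci = conserved_loci(aln, grp, min_len=21)
    assert len(loci) == 1
    sb, eb, strand = loci[0].coords["B"]
    assert strand == "-"
    assert revcomp(members["B"].sequence[sb - 300 : eb - 300]) == loci[0].consensus


def test_quartet_loci_sit_on_planted_elements(quartet):
    genomes, truth = quartet
    table = find_orthologs(genomes)
    spacers = {g.id: extract_igs(g, min_len=1) for g in genomes}
    groups = pair_orthologous_igs(table, spacers)
    all_loci = []
    for grp in groups:
        aln = align_group(grp)
        all_loci.extend(conserved_loci(aln, grp))
    assert len(all_loci) > 20
    # every planted SD site in genome 1 should fall inside some conserved locus
    gid = genomes[0].id
    covered = []
    for rec in truth.by_kind(gid, "sd"):
        hit = any(
            gid in lc.coords
            and lc.coords[gid][0] <= rec.start
            and rec.end <= lc.coords[gid][1]
            for lc in all_loci
        )
        covered.append(hit)
    assert sum(covered) / len(covered) >= 0.9


# ---------------------------------------------------------------------------
# length association


def test_length_association_closed_form():
    groups = []
    la = [100, 120, 80, 150, 90]
    lb = [104, 118, 85, 149, 95]
    from endofootprint.footprint import OrthologousIGSGroup

    for i, (x, y) in enumerate(zip(la, lb)):
        groups.append(
            OrthologousIGSGroup(
                group_id=f"IG{i}",
                members={"A": _spacer("A", "l", "r", "A" * x), "B": _spacer("B", "l", "r", "A" * y)},
                left_group="OG1",
                right_group="OG2",
            )
        )
    res = length_association(groups, "A", "B")
    r = np.corrcoef(la, lb)[0, 1]
    assert res.r_squared == pytest.approx(r**2, abs=1e-9)
    assert res.lengths_a == la and res.lengths_b == lb


def test_length_association_identical_vectors_is_one():
    from endofootprint.footprint import OrthologousIGSGroup

    groups = [
        OrthologousIGSGroup(
            group_id=f"IG{i}",
            members={"A": _spacer("A", "l", "r", "A" * x), "B": _spacer("B", "l", "r", "A" * x)},
            left_group="OG1",
            right_group="OG2",
        )
        for i, x in enumerate([50, 50, 50])
    ]
    assert length_association(groups, "A", "B").r_squared == 1.0


def test_quartet_sisters_more_correlated_than_cross_pairs(quartet):
    genomes, _ = quartet
    table = find_orthologs(genomes)
    spacers = {g.id: extract_igs(g, min_len=1) for g in genomes}
    groups = pair_orthologous_igs(table, spacers)
    within = length_association(groups, "B", "Q").r_squared
    across = length_association(groups, "B", "Z1").r_squared
    assert within >= across
    assert within > 0.99
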