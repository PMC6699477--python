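"""Phylogenetic footprinting of orthologous intergenic spacers.

Spacers from different genomes are *orthologous* when they are flanked by the
same ordered pair of ortholog groups with conserved adjacency.  Each group is
aligned (center-star progressive alignment with affine-gap pairwise steps),
and maximal runs of identically aligned, gap-free columns longer than a
threshold (default >20 nt) are extracted as conserved loci — the candidate
functional elements.  Length association between genomes (r² of paired
spacer lengths) quantifies architectural stasis.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
from Bio.Align import PairwiseAligner
from scipy import stats

from .genome import AnnotatedGenome, IntergenicSpacer, revcomp
from .orthology import OrthologTable


@dataclass
class OrthologousIGSGroup:
    group_id: str
    members: dict[str, IntergenicSpacer]  # genome id -> spacer
    left_group: str  # flanking ortholog group ids, orientation-normalized
    right_group: str
    flipped: dict[str, bool] = field(default_factory=dict)  # member reported revcomp'd
    orientation_consistent: bool = True

    def oriented_sequence(self, genome_id: str) -> str:
        seq = self.members[genome_id].sequence
        return revcomp(seq) if self.flipped.get(genome_id, False) else seq


@dataclass
class IGSAlignment:
    group_id: str
    genome_ids: list[str]
    rows: list[str]  # gapped, equal length

    def __post_init__(self) -> None:
        if len({len(r) for r in self.rows}) > 1:
            raise ValueError("alignment rows differ in length")

    @property
    def n_columns(self) -> int:
        return len(self.rows[0]) if self.rows else 0

    def degapped(self, i: int) -> str:
        return self.rows[i].replace("-", "")


@dataclass
class ConservedLocus:
    group_id: str
    col_start: int  # alignment column interval, half-open
    col_end: int
    consensus: str
    coords: dict[str, tuple[int, int, str]]  # genome -> (start, end, strand)
    gc: float

    @property
    def length(self) -> int:
        return self.col_end - self.col_start


@dataclass
class LengthAssociation:
    genome_a: str
    genome_b: str
    lengths_a: list[int]
    lengths_b: list[int]
    r_squared: float


# ---------------------------------------------------------------------------
# pairing


def pair_orthologous_igs(
    ortholog_table: OrthologTable,
    spacers_by_genome: dict[str, Sequence[IntergenicSpacer]],
    min_genomes: int | None = None,
) -> list[OrthologousIGSGroup]:
    """Group spacers flanked by the same (orientation-normalized) ordered
    pair of ortholog groups.

    A group is emitted only when at least ``min_genomes`` genomes (default:
    all) contribute exactly one such spacer; a broken flank adjacency in a
    required genome, or an ambiguous duplicate, drops the group.  Member
    sequences are reported on the strand that puts the left ortholog group
    first.
    """
    genome_ids = list(spacers_by_genome)
    need = len(genome_ids) if min_genomes is None else min_genomes
    g2grp = ortholog_table.gene_to_group()

    keyed: dict[tuple[str, str], dict[str, list[tuple[IntergenicSpacer, bool]]]] = {}
    for gid, spacers in spacers_by_genome.items():
        for sp in spacers:
            lg = g2grp.get((gid, sp.left_gene))
            rg = g2grp.get((gid, sp.right_gene))
            if lg is None or rg is None:
                continue
            if lg <= rg:
                key, flip = (lg, rg), False
            else:
                key, flip = (rg, lg), True
            keyed.setdefault(key, {}).setdefault(gid, []).append((sp, flip))

    groups: list[OrthologousIGSGroup] = []
    for k, (key, per_genome) in enumerate(sorted(keyed.items())):
        ok = {g: v[0] for g, v in per_genome.items() if len(v) == 1}
        if len(ok) < need:
            continue
        strands = {
            (sp.left_strand, sp.right_strand) if not flip else (sp.right_strand, sp.left_strand)
            for sp, flip in ok.values()
        }
        groups.append(
            OrthologousIGSGroup(
                group_id=f"IGS{k:04d}",
                members={g: sp for g, (sp, _) in ok.items()},
                left_group=key[0],
                right_group=key[1],
                flipped={g: flip for g, (_, flip) in ok.items()},
                orientation_consistent=len(strands) == 1,
            )
        )
    return groups


# ---------------------------------------------------------------------------
# alignment


def nucleotide_aligner(match: float = 1.0, mismatch: float = -1.0, gap_open: float = -4.0, gap_extend: float = -1.0) -> PairwiseAligner:
    al = PairwiseAligner()
    al.match_score = match
    al.mismatch_score = mismatch
    al.open_gap_score = gap_open
    al.extend_gap_score = gap_extend
    al.mode = "global"
    return al


def _pairwise_rows(al: PairwiseAligner, a: str, b: str) -> tuple[str, str]:
    aln = al.align(a, b)[0]
    return str(aln[0]), str(aln[1])


def _merge_into_master(master: list[str], center_gapped: str, new_gapped: str) -> list[str]:
    """Insert the gap pattern of a new center/member pairwise alignment into
    an existing multiple alignment whose first row degaps to the center."""
    old_center = master[0]
    merged = ["" for _ in master] + [""]
    i = j = 0  # i over old alignment columns, j over new pairwise columns
    n_old, n_new = len(old_center), len(center_gapped)
    while i < n_old or j < n_new:
        oc = old_center[i] if i < n_old else None
        nc = center_gapped[j] if j < n_new else None
        if oc is not None and oc == "-":
            # column where earlier members inserted against the center
            for r in range(len(master)):
                merged[r] += master[r][i]
            merged[-1] += "-"
            i += 1
        elif nc is not None and nc == "-":
            # new member inserts against the center
            for r in range(len(master)):
                merged[r] += "-"
            merged[-1] += new_gapped[j]
            j += 1
        else:
            for r in range(len(master)):
                merged[r] += master[r][i]
            merged[-1] += new_gapped[j]
            i += 1
            j += 1
    return merged


def align_group(
    group: OrthologousIGSGroup,
    aligner: PairwiseAligner | None = None,
    genome_order: Sequence[str] | None = None,
) -> IGSAlignment:
    """Center-star progressive alignment of a group's oriented members.

    The center is the member maximizing summed pairwise identity (ties break
    by genome id order); every other member is aligned to the center with
    affine-gap global alignment and gaps are merged into the growing
    alignment.  Degapping any row returns that member's oriented sequence.
    """
    al = aligner or nucleotide_aligner()
    ids = sorted(group.members) if genome_order is None else [g for g in genome_order if g in group.members]
    seqs = {g: group.oriented_sequence(g) for g in ids}
    for g, s in seqs.items():
        if not s:
            raise ValueError(f"group {group.group_id}: empty member {g}")
    if len(ids) < 2:
        raise ValueError("need at least two members")

    def pid(a: str, b: str) -> float:
        ra, rb = _pairwise_rows(al, a, b)
        return sum(x == y and x != "-" for x, y in zip(ra, rb)) / len(ra)

    sums = {g: sum(pid(seqs[g], seqs[h]) for h in ids if h != g) for g in ids}
    center = max(ids, key=lambda g: (sums[g], -ids.index(g)))
    others = [g for g in ids if g != center]

    master = [seqs[center]]
    row_ids = [center]
    for g in others:
        cg, ng = _pairwise_rows(al, master[0].replace("-", ""), seqs[g])
        master = _merge_into_master(master, cg, ng)
        row_ids.append(g)
    # present rows in genome id order
    order = {g: k for k, g in enumerate(ids)}
    paired = sorted(zip(row_ids, master), key=lambda t: order[t[0]])
    return IGSAlignment(group_id=group.group_id, genome_ids=[g for g, _ in paired], rows=[r for _, r in paired])


# ---------------------------------------------------------------------------
# conserved loci


def _gc_of(seq: str) -> float:
    acgt = sum(seq.count(b) for b in "ACGT")
    return round(100.0 * (seq.count("G") + seq.count("C")) / acgt, 1) if acgt else 0.0


def conserved_loci(
    aln: IGSAlignment,
    group: OrthologousIGSGroup | None = None,
    min_len: int = 21,
) -> list[ConservedLocus]:
    """Maximal runs of identically aligned, gap-free columns of length >=
    ``min_len`` (default 21, i.e. strictly more than 20 nt).

    When the originating group is supplied, per-genome genomic coordinates
    are back-mapped through the gap structure (and through any orientation
    flip of a member).
    """
    rows = aln.rows
    ncol = aln.n_columns
    identical = [
        all(r[c] == rows[0][c] and r[c] != "-" for r in rows) for c in range(ncol)
    ]
    # per-row cumulative count of non-gap characters before each column
    offsets = []
    for r in rows:
        cum = np.cumsum([ch != "-" for ch in r])
        offsets.append(cum)

    loci: list[ConservedLocus] = []
    c = 0
    while c < ncol:
        if not identical[c]:
            c += 1
            continue
        d = c
        while d < ncol and identical[d]:
            d += 1
        if d - c >= min_len:
            consensus = rows[0][c:d]
            coords: dict[str, tuple[int, int, str]] = {}
            if group is not None:
                for k, gid in enumerate(aln.genome_ids):
                    # offset within the oriented member sequence
                    o_start = int(offsets[k][c - 1]) if c > 0 else 0
                    o_end = int(offsets[k][d - 1])
                    sp = group.members[gid]
                    if group.flipped.get(gid, False):
                        g_start = sp.end - o_end
                        g_end = sp.end - o_start
                        strand = "-"
                    else:
                        g_start = sp.start + o_start
                        g_end = sp.start + o_end
                        strand = "+"
                    coords[gid] = (g_start, g_end, strand)
            loci.append(
                ConservedLocus(
                    group_id=aln.group_id,
                    col_start=c,
                    col_end=d,
                    consensus=consensus,
                    coords=coords,
                    gc=_gc_of(consensus),
                )
            )
        c = d
    return loci


# ---------------------------------------------------------------------------
# length association


def length_association(
    groups: Sequence[OrthologousIGSGroup], genome_a: str, genome_b: str
) -> LengthAssociation:
    """Squared Pearson correlation of paired orthologous-spacer lengths."""
    la, lb = [], []
    for grp in groups:
        if genome_a in grp.members and genome_b in grp.members:
            la.append(grp.members[genome_a].length)
            lb.append(grp.members[genome_b].length)
    if len(la) < 3:
        raise ValueError("need at least three shared groups")
    if len(set(la)) == 1 or len(set(lb)) == 1:
        if la == lb:
            return LengthAssociation(genome_a, genome_b, la, lb, 1.0)
        raise ValueError("zero variance in spacer lengths")
    r, _ = stats.pearsonr(la, lb)
    return LengthAssociation(genome_a, genome_b, la, lb, float(r) ** 2)


# ---------------------------------------------------------------------------
# output helpers


def write_groups_tsv(groups: Sequence[OrthologousIGSGroup], path: str | Path) -> None:
    import pandas as pd

    rows = []
    for grp in groups:
        for gid, sp in grp.members.items():
            rows.append(
                dict(
                    group_id=grp.group_id,
                    genome=gid,
                    start=sp.start,
                    end=sp.end,
                    length=sp.length,
                    left_gene=sp.left_gene,
                    right_gene=sp.right_gene,
                    flipped=grp.flipped.get(gid, False),
                )
            )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_loci_tsv(loci: Sequence[ConservedLocus], path: str | Path) -> None:
    import pandas as pd

    rows = []
    for lc in loci:
        rows.append(
            dict(
                group_id=lc.group_id,
                col_start=lc.col_start,
                col_end=lc.col_end,
                length=lc.length,
                gc=lc.gc,
                consensus=lc.consensus,
            )
        )
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def write_alignment_fasta(aln: IGSAlignment, path: str | Path) -> None:
    with open(path, "w") as fh:
        for gid, row in zip(aln.genome_ids, aln.rows):
            fh.write(f">{aln.group_id}:{gid}\n{row}\n")
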