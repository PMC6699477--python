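"""Cross-genome orthology, core-gene similarity, distance trees and Ka/Ks.

Orthologs are identified by reciprocal best hit (RBH) over all-vs-all global
protein alignments, merged across genomes by single-linkage; this is a
deterministic stand-in for Markov-clustering orthology tools and is adequate
for near-collinear reduced genomes.  The tree is neighbor-joining on
``100 - percent identity`` distances.  Ka/Ks follows Nei & Gojobori (1986)
with Jukes–Cantor correction: fractional synonymous/nonsynonymous site counts
averaged over the two sequences, and substitution classification averaged
with equal weight over all mutational pathways for multi-hit codons.
Mutations creating stop codons count as nonsynonymous, which keeps
``N_sites + S_sites`` equal to the codon-aligned length in nucleotides.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from Bio.Align import PairwiseAligner, substitution_matrices
from Bio.Data import CodonTable

from .genome import AnnotatedGenome

# translation table 11 (bacterial); standard code for the 61 sense codons
_CODON_TABLE = CodonTable.unambiguous_dna_by_id[11]
CODON_TO_AA = dict(_CODON_TABLE.forward_table)
STOP_CODONS = set(_CODON_TABLE.stop_codons)
_BASES = "ACGT"


def translate_cds(nt: str) -> str:
    if len(nt) % 3:
        raise ValueError("CDS length not divisible by 3")
    aas = []
    for i in range(0, len(nt), 3):
        codon = nt[i : i + 3]
        if codon in STOP_CODONS:
            if i != len(nt) - 3:
                raise ValueError(f"internal stop codon at codon index {i // 3}")
            break
        aas.append(CODON_TO_AA.get(codon, "X"))
    return "".join(aas)


# ---------------------------------------------------------------------------
# protein alignment helpers


def protein_aligner() -> PairwiseAligner:
    al = PairwiseAligner()
    al.substitution_matrix = substitution_matrices.load("BLOSUM62")
    al.open_gap_score = -11.0
    al.extend_gap_score = -1.0
    al.mode = "global"
    return al


def _alignment_identity(row_a: str, row_b: str) -> tuple[int, int]:
    """(matches, columns) over the alignment excluding terminal gap columns."""
    lo, hi = 0, len(row_a)
    while lo < hi and (row_a[lo] == "-" or row_b[lo] == "-"):
        lo += 1
    while hi > lo and (row_a[hi - 1] == "-" or row_b[hi - 1] == "-"):
        hi -= 1
    matches = sum(a == b and a != "-" for a, b in zip(row_a[lo:hi], row_b[lo:hi]))
    return matches, hi - lo


def align_proteins(a: str, b: str, aligner: PairwiseAligner | None = None) -> tuple[str, str, float]:
    """Global alignment; returns the two gapped rows and the score."""
    al = aligner or protein_aligner()
    aln = al.align(a, b)[0]
    return str(aln[0]), str(aln[1]), aln.score


def protein_identity(a: str, b: str, aligner: PairwiseAligner | None = None) -> float:
    ra, rb, _ = align_proteins(a, b, aligner)
    m, c = _alignment_identity(ra, rb)
    return 100.0 * m / c if c else 0.0


# ---------------------------------------------------------------------------
# ortholog tables


@dataclass
class OrthoGroup:
    group_id: str
    members: dict[str, str]  # genome id -> gene id

    def is_core(self, genome_ids: Sequence[str]) -> bool:
        return all(g in self.members for g in genome_ids)


@dataclass
class OrthologTable:
    genomes: list[str]
    groups: list[OrthoGroup]

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for grp in self.groups:
            for gid, gene in grp.members.items():
                key = (gid, gene)
                if key in seen:
                    raise ValueError(f"gene {gene} of {gid} appears in two groups")
                seen.add(key)

    @property
    def core_groups(self) -> list[OrthoGroup]:
        return [g for g in self.groups if g.is_core(self.genomes)]

    def gene_to_group(self) -> dict[tuple[str, str], str]:
        return {
            (gid, gene): grp.group_id for grp in self.groups for gid, gene in grp.members.items()
        }

    def to_tsv(self, path: str | Path) -> None:
        rows = []
        for grp in self.groups:
            rows.append([grp.group_id] + [grp.members.get(g, "-") for g in self.genomes])
        pd.DataFrame(rows, columns=["group_id"] + self.genomes).to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path: str | Path) -> "OrthologTable":
        df = pd.read_csv(path, sep="\t", dtype=str)
        genomes = list(df.columns[1:])
        groups = [
            OrthoGroup(r.iloc[0], {g: r[g] for g in genomes if r[g] != "-"})
            for _, r in df.iterrows()
        ]
        return cls(genomes=genomes, groups=groups)


def _cds_proteins(genome: AnnotatedGenome) -> dict[str, str]:
    """gene id -> protein for every CDS with a usable translation."""
    import warnings

    out = {}
    for g in genome.genes:
        if g.kind != "CDS":
            continue
        prot = g.translation.rstrip("*")
        if not prot:  # derive from the nucleotide sequence when possible
            try:
                prot = translate_cds(_gene_nt(genome, g))
            except Exception:
                warnings.warn(f"{genome.id}:{g.id}: no translation and no derivable ORF; skipped")
                continue
        out[g.id] = prot
    return out


def _gene_nt(genome: AnnotatedGenome, g) -> str:
    from .genome import revcomp

    seq = genome.slice(g.start, g.end)
    return revcomp(seq) if g.strand == "-" else seq


def find_orthologs(
    genomes: Sequence[AnnotatedGenome],
    min_identity: float = 50.0,
    min_coverage: float = 0.5,
) -> OrthologTable:
    """Reciprocal-best-hit orthology over all genome pairs.

    Genes A and B are linked iff each is the other's highest-scoring global
    protein alignment in the opposite genome, with percent identity >=
    ``min_identity`` and aligned coverage >= ``min_coverage`` of both lengths.
    Links are merged into groups by single-linkage; if a merged component ever
    holds two genes of one genome, the lower-scoring gene is dropped.
    Output is deterministic for a given input (ties broken by gene id).
    """
    if len(genomes) < 2:
        raise ValueError("need at least two genomes")
    al = protein_aligner()
    prots = {g.id: _cds_proteins(g) for g in genomes}
    for g in genomes:
        if not prots[g.id]:
            raise ValueError(f"genome {g.id} has no CDS with translations")

    edges: dict[tuple[tuple[str, str], tuple[str, str]], float] = {}
    order = sorted(g.id for g in genomes)
    for ga, gb in itertools.combinations(order, 2):
        ids_a, ids_b = sorted(prots[ga]), sorted(prots[gb])
        score = np.empty((len(ids_a), len(ids_b)))
        for i, a in enumerate(ids_a):
            pa = prots[ga][a]
            for j, b in enumerate(ids_b):
                score[i, j] = al.score(pa, prots[gb][b])
        best_a = score.argmax(axis=1)  # ties -> lowest index = lexicographic id
        best_b = score.argmax(axis=0)
        for i, j in enumerate(best_a):
            if best_b[j] != i:
                continue
            pa, pb = prots[ga][ids_a[i]], prots[gb][ids_b[j]]
            ra, rb, sc = align_proteins(pa, pb, al)
            m, cols = _alignment_identity(ra, rb)
            if cols == 0:
                continue
            ident = 100.0 * m / cols
            if ident < min_identity:
                continue
            aligned = sum(a != "-" and b != "-" for a, b in zip(ra, rb))
            if aligned < min_coverage * len(pa) or aligned < min_coverage * len(pb):
                continue
            edges[((ga, ids_a[i]), (gb, ids_b[j]))] = sc

    # single-linkage over RBH edges (union-find)
    parent: dict[tuple[str, str], tuple[str, str]] = {}

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    nodes = sorted({n for e in edges for n in e})
    for node in nodes:
        parent[node] = node
    for (a, b), _ in sorted(edges.items()):
        ra, rb = find(a), find(b)
        if ra != rb:
            parent[max(ra, rb)] = min(ra, rb)

    comps: dict[tuple[str, str], list[tuple[str, str]]] = {}
    for node in nodes:
        comps.setdefault(find(node), []).append(node)

    node_score = {n: 0.0 for n in nodes}
    for (a, b), sc in edges.items():
        node_score[a] += sc
        node_score[b] += sc

    groups = []
    for k, comp in enumerate(sorted(comps.values())):
        members: dict[str, str] = {}
        for gid, gene in sorted(comp, key=lambda n: -node_score[n]):
            members.setdefault(gid, gene)  # keep best-scoring per genome
        groups.append(OrthoGroup(f"OG{k:04d}", members))
    return OrthologTable(genomes=order, groups=groups)


# ---------------------------------------------------------------------------
# core-gene similarity and trees


@dataclass
class SimilarityMatrix:
    ids: list[str]
    values: np.ndarray  # percent identity, symmetric, diag 100

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if not np.allclose(self.values, self.values.T):
            raise ValueError("similarity matrix is not symmetric")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.ids, columns=self.ids)

    def get(self, a: str, b: str) -> float:
        return float(self.values[self.ids.index(a), self.ids.index(b)])


def core_similarity(table: OrthologTable, genomes: Sequence[AnnotatedGenome]) -> SimilarityMatrix:
    """Pairwise percent amino-acid identity over concatenated core genes.

    Per genome pair the identity is alignment-column-weighted over all core
    groups (equivalent to identity of the concatenated alignment), rounded
    to 1 decimal.
    """
    core = table.core_groups
    if not core:
        raise ValueError("no core groups")
    al = protein_aligner()
    by_id = {g.id: g for g in genomes}
    prots = {gid: _cds_proteins(by_id[gid]) for gid in table.genomes}
    ids = list(table.genomes)
    n = len(ids)
    vals = np.full((n, n), 100.0)
    for i, j in itertools.combinations(range(n), 2):
        matches = cols = 0
        for grp in core:
            pa = prots[ids[i]][grp.members[ids[i]]]
            pb = prots[ids[j]][grp.members[ids[j]]]
            ra, rb, _ = align_proteins(pa, pb, al)
            m, c = _alignment_identity(ra, rb)
            matches += m
            cols += c
        vals[i, j] = vals[j, i] = round(100.0 * matches / cols, 1) if cols else 0.0
    return SimilarityMatrix(ids=ids, values=vals)


def nj_tree(matrix: SimilarityMatrix) -> str:
    """Neighbor-joining newick string on distance = 100 - similarity.

    Taxa are ordered lexicographically before joining so ties resolve
    deterministically; negative branch lengths are clamped to zero.
    """
    if len(matrix.ids) < 3:
        raise ValueError("need at least three genomes")
    from skbio import DistanceMatrix
    from skbio.tree import nj

    order = sorted(range(len(matrix.ids)), key=lambda i: matrix.ids[i])
    ids = [matrix.ids[i] for i in order]
    dist = 100.0 - matrix.values[np.ix_(order, order)]
    np.fill_diagonal(dist, 0.0)
    tree = nj(DistanceMatrix(dist, ids=ids), neg_as_zero=True)
    return str(tree).strip()


# ---------------------------------------------------------------------------
# Ka/Ks (Nei-Gojobori 1986, Jukes-Cantor corrected)


@dataclass
class KaKsResult:
    pair: tuple[str, str]
    Ka: float
    Ks: float
    ratio: float | None  # None when Ks == 0
    N_sites: float
    S_sites: float
    N_diff: float = 0.0
    S_diff: float = 0.0


def _syn_fraction(codon: str) -> tuple[float, float]:
    """(synonymous, nonsynonymous) site counts of one sense codon.

    Each of the 9 single-base changes contributes 1/3 of a site; changes to
    stop codons are nonsynonymous.
    """
    aa = CODON_TO_AA[codon]
    syn = 0.0
    for pos in range(3):
        for b in _BASES:
            if b == codon[pos]:
                continue
            mut = codon[:pos] + b + codon[pos + 1 :]
            if mut not in STOP_CODONS and CODON_TO_AA[mut] == aa:
                syn += 1.0 / 3.0
    return syn, 3.0 - syn


def _pathway_diffs(ca: str, cb: str) -> tuple[float, float]:
    """(syn, nonsyn) differences between two codons, averaged with equal
    weight over every mutational pathway (including those passing through
    stop codons, whose steps count as nonsynonymous)."""
    positions = [i for i in range(3) if ca[i] != cb[i]]
    if not positions:
        return 0.0, 0.0
    total_s = total_n = 0.0
    perms = list(itertools.permutations(positions))
    for order in perms:
        cur = ca
        for pos in order:
            nxt = cur[:pos] + cb[pos] + cur[pos + 1 :]
            if cur in STOP_CODONS or nxt in STOP_CODONS:
                total_n += 1
            elif CODON_TO_AA[cur] == CODON_TO_AA[nxt]:
                total_s += 1
            else:
                total_n += 1
            cur = nxt
    k = len(perms)
    return total_s / k, total_n / k


def _jukes_cantor(p: float) -> float:
    if p == 0:
        return 0.0
    if p >= 0.75:
        return float("nan")
    return -0.75 * math.log(1.0 - 4.0 * p / 3.0)


def codon_align(nt_a: str, nt_b: str) -> tuple[str, str]:
    """Codon-aware pairwise alignment: align the translations, project onto
    codons, and drop any codon column containing a gap."""
    pa, pb = translate_cds(nt_a), translate_cds(nt_b)
    ra, rb, _ = align_proteins(pa, pb)
    ia = ib = 0
    out_a: list[str] = []
    out_b: list[str] = []
    for a, b in zip(ra, rb):
        if a != "-" and b != "-":
            out_a.append(nt_a[3 * ia : 3 * ia + 3])
            out_b.append(nt_b[3 * ib : 3 * ib + 3])
        if a != "-":
            ia += 1
        if b != "-":
            ib += 1
    return "".join(out_a), "".join(out_b)


def kaks(cds_a: str, cds_b: str, ids: tuple[str, str] = ("a", "b")) -> KaKsResult:
    """Nei-Gojobori Ka/Ks with Jukes-Cantor correction.

    Inputs are coding sequences (stop codon optional); unequal lengths are
    codon-aligned first and gapped codons dropped.  ``ratio`` is None when
    Ks = 0.
    """
    a = cds_a.upper().replace("U", "T")
    b = cds_b.upper().replace("U", "T")
    for name, s in zip(ids, (a, b)):
        if len(s) % 3:
            raise ValueError(f"{name}: length {len(s)} not divisible by 3")
    # drop terminal stop codons
    if a[-3:] in STOP_CODONS:
        a = a[:-3]
    if b[-3:] in STOP_CODONS:
        b = b[:-3]
    for name, s in zip(ids, (a, b)):
        for i in range(0, len(s), 3):
            if s[i : i + 3] in STOP_CODONS:
                raise ValueError(f"{name}: internal stop at codon index {i // 3}")
    if len(a) != len(b):
        a, b = codon_align(a, b)
    S_a = S_b = 0.0
    Sd = Nd = 0.0
    for i in range(0, len(a), 3):
        ca, cb = a[i : i + 3], b[i : i + 3]
        sa, _ = _syn_fraction(ca)
        sb, _ = _syn_fraction(cb)
        S_a += sa
        S_b += sb
        ds, dn = _pathway_diffs(ca, cb)
        Sd += ds
        Nd += dn
    L = float(len(a))
    S = (S_a + S_b) / 2.0
    N = L - S
    ps = Sd / S if S else 0.0
    pn = Nd / N if N else 0.0
    Ks = _jukes_cantor(ps)
    Ka = _jukes_cantor(pn)
    ratio = None if Ks == 0 or math.isnan(Ks) else Ka / Ks
    return KaKsResult(pair=ids, Ka=Ka, Ks=Ks, ratio=ratio, N_sites=N, S_sites=S, N_diff=Nd, S_diff=Sd)
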