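"""Promoter and ribosome-binding-site scanning, operons, regulon screening.

The heat-shock promoter model is the two-box σ32 consensus of *E. coli* —
``CTTGAAA`` (−35 box) and ``CCCCATNT`` (−10 box) separated by an 11–15 nt
spacer — matched with independent per-box mismatch budgets.  Shine-Dalgarno
candidates are 5-mers within Hamming distance 1 of the ``AGGAG`` consensus.
Operons are maximal runs of same-strand adjacent genes with small gaps; a
σ32 site found upstream of an operon head is attributed to every member.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .genome import AnnotatedGenome, GeneFeature, revcomp

IUPAC = {
    "A": "A", "C": "C", "G": "G", "T": "T", "U": "T",
    "R": "AG", "Y": "CT", "S": "GC", "W": "AT", "K": "GT", "M": "AC",
    "B": "CGT", "D": "AGT", "H": "ACT", "V": "ACG", "N": "ACGT",
}

#: Table-2 heat-shock regulon of the reduced genome, after the E. coli regulon
HEAT_SHOCK_REGULON = [
    "groES", "dnaK", "ftsH", "dnaJ", "grpE", "hslV", "lon", "ybeY",
    "groEL", "ileS", "rpoH", "valS", "hslU", "rpoD", "glnS",
]


@dataclass
class TwoBoxMotif:
    box35: str = "CTTGAAA"
    box10: str = "CCCCATNT"
    spacer_min: int = 11
    spacer_max: int = 15
    max_mm35: int = 1
    max_mm10: int = 2

    def __post_init__(self) -> None:
        self.box35 = self.box35.upper()
        self.box10 = self.box10.upper()
        if self.spacer_min > self.spacer_max:
            raise ValueError("spacer_min > spacer_max")
        for pat in (self.box35, self.box10):
            if any(c not in IUPAC for c in pat):
                raise ValueError(f"non-IUPAC character in pattern {pat}")

    @property
    def span_min(self) -> int:
        return len(self.box35) + self.spacer_min + len(self.box10)


@dataclass
class TwoBoxHit:
    strand: str
    box35_start: int  # genomic / sequence coordinates, 0-based half-open
    box10_start: int
    spacer_len: int
    mm35: int
    mm10: int

    def box35_interval(self, len35: int = 7) -> tuple[int, int]:
        return self.box35_start, self.box35_start + len35

    def box10_interval(self, len10: int = 8) -> tuple[int, int]:
        return self.box10_start, self.box10_start + len10


@dataclass
class SigmaSite:
    genome_id: str
    strand: str
    box35: tuple[int, int]
    box10: tuple[int, int]
    spacer_len: int
    mm35: int
    mm10: int
    assigned_gene: str
    distance_to_start: int
    operon_genes: tuple[str, ...] = ()
    truncated_window: bool = False


@dataclass
class SDHit:
    seq_id: str
    start: int  # within the scanned sequence
    kmer: str
    mismatches: int
    distance_to_start: int | None = None  # nt to a downstream start, when known


@dataclass
class Operon:
    genes: tuple[str, ...]
    strand: str
    head: str  # 5'-most gene
    upstream_start: int = 0
    upstream_end: int = 0


# ---------------------------------------------------------------------------
# mismatch machinery

_ENC = {"A": 0, "C": 1, "G": 2, "T": 3, "U": 3, "N": 4}


def _encode(seq: str) -> np.ndarray:
    return np.fromiter((_ENC.get(c, 4) for c in seq.upper()), dtype=np.int8, count=len(seq))


def _mismatch_profile(enc: np.ndarray, pattern: str) -> np.ndarray:
    """Mismatch count of the pattern at every start position.

    Pattern N matches anything (0 mismatches); a sequence N mismatches any
    non-N pattern position.
    """
    m = len(pattern)
    n = len(enc)
    if n < m:
        return np.empty(0, dtype=np.int32)
    out = np.zeros(n - m + 1, dtype=np.int32)
    for k, pc in enumerate(pattern):
        allowed = IUPAC[pc]
        lut = np.ones(5, dtype=np.int32)
        for b in allowed:
            lut[_ENC[b]] = 0
        if allowed == "ACGT":
            lut[4] = 0  # pattern N tolerates sequence N
        out += lut[enc[k : k + n - m + 1]]
    return out


def scan_two_box(
    sequence: str,
    motif: TwoBoxMotif | None = None,
    strands: str = "both",
) -> list[TwoBoxHit]:
    """All placements of the two-box motif within per-box mismatch budgets
    and the allowed spacer range.  Overlapping hits are all reported, in
    deterministic (strand, position) order.
    """
    motif = motif or TwoBoxMotif()
    seq = sequence.upper()
    hits: list[TwoBoxHit] = []
    m35, m10 = len(motif.box35), len(motif.box10)

    def scan_forward(s: str) -> list[tuple[int, int, int, int]]:
        if len(s) < motif.span_min:
            return []
        enc = _encode(s)
        mm35 = _mismatch_profile(enc, motif.box35)
        mm10 = _mismatch_profile(enc, motif.box10)
        pos35 = np.nonzero(mm35 <= motif.max_mm35)[0]
        found = []
        for p35 in pos35:
            for spacer in range(motif.spacer_min, motif.spacer_max + 1):
                p10 = p35 + m35 + spacer
                if p10 < len(mm10) and mm10[p10] <= motif.max_mm10:
                    found.append((int(p35), int(p10), spacer, int(mm35[p35])))
        return [(p35, p10, sp, mm) for p35, p10, sp, mm in found]

    for p35, p10, spacer, mm in scan_forward(seq):
        hits.append(TwoBoxHit("+", p35, p10, spacer, mm, int(_hamming_iupac(seq[p10 : p10 + m10], motif.box10))))
    if strands == "both":
        rc = revcomp(seq)
        L = len(seq)
        for p35, p10, spacer, mm in scan_forward(rc):
            hits.append(
                TwoBoxHit("-", L - p35 - m35, L - p10 - m10, spacer, mm, int(_hamming_iupac(rc[p10 : p10 + m10], motif.box10)))
            )
    hits.sort(key=lambda h: (h.strand, h.box35_start, h.box10_start))
    return hits


def _hamming_iupac(window: str, pattern: str) -> int:
    mm = 0
    for c, p in zip(window.upper(), pattern):
        allowed = IUPAC[p]
        if allowed == "ACGT":
            continue
        if c not in allowed:
            mm += 1
    return mm


# ---------------------------------------------------------------------------
# upstream promoter scanning


def upstream_window(
    genome: AnnotatedGenome,
    gene: GeneFeature,
    window: int,
    truncate_at_gene: bool = True,
) -> tuple[str, int, bool]:
    """Sequence 5' of a gene's start on the gene's strand.

    Returns (sequence, usable length, truncated flag).  The window is
    truncated at the nearest upstream gene boundary by default, and at the
    sequence edge of a linear genome.
    """
    n = len(genome.sequence)
    truncated = False
    if gene.strand == "+":
        lo = gene.start - window
        if truncate_at_gene:
            bounds = [e for s, e in genome.gene_intervals() if e <= gene.start and e > lo]
            if bounds:
                lo = max(bounds)
                truncated = True
        if lo < 0:
            if genome.topology == "circular":
                seq = genome.slice((lo % n), (lo % n) + (gene.start - lo))
            else:
                seq = genome.sequence[0 : gene.start]
                truncated = True
        else:
            seq = genome.sequence[lo : gene.start]
        return seq, len(seq), truncated
    # '-' strand: upstream is to the right, reverse-complemented
    end = gene.end % n if gene.end > n else gene.end
    hi = end + window
    if truncate_at_gene:
        bounds = [s for s, e in genome.gene_intervals() if s >= end and s < hi]
        if bounds:
            hi = min(bounds)
            truncated = True
    if hi > n:
        if genome.topology == "circular":
            seq = genome.slice(end, hi)
        else:
            seq = genome.sequence[end:n]
            truncated = True
    else:
        seq = genome.sequence[end:hi]
    return revcomp(seq), len(seq), truncated


def sigma32_sites(
    genome: AnnotatedGenome,
    gene_ids: Sequence[str],
    upstream_window_len: int = 200,
    motif: TwoBoxMotif | None = None,
    operons: Sequence[Operon] | None = None,
    truncate_at_gene: bool = True,
) -> list[SigmaSite]:
    """Scan upstream windows of the given genes (or of their operon heads)
    for two-box σ32 sites; one site per distinct promoter placement."""
    motif = motif or TwoBoxMotif()
    head_of: dict[str, Operon] = {}
    if operons:
        for op in operons:
            for g in op.genes:
                head_of[g] = op

    seen: dict[tuple[str, int], SigmaSite] = {}
    for gene_id in gene_ids:
        gene = genome.gene(gene_id)
        op = head_of.get(gene_id)
        head = genome.gene(op.head) if op else gene
        seq, usable, truncated = upstream_window(genome, head, upstream_window_len, truncate_at_gene)
        for hit in scan_two_box(seq, motif, strands="forward"):
            m10 = len(motif.box10)
            dist = usable - (hit.box10_start + m10)
            # window coordinates -> genomic coordinates on the head's strand
            if head.strand == "+":
                base = head.start - usable
                b35 = (base + hit.box35_start, base + hit.box35_start + len(motif.box35))
                b10 = (base + hit.box10_start, base + hit.box10_start + m10)
            else:
                end = head.end
                b35 = (end + usable - hit.box35_start - len(motif.box35), end + usable - hit.box35_start)
                b10 = (end + usable - hit.box10_start - m10, end + usable - hit.box10_start)
            key = (head.strand, b35[0])
            if key in seen:
                continue
            seen[key] = SigmaSite(
                genome_id=genome.id,
                strand=head.strand,
                box35=b35,
                box10=b10,
                spacer_len=hit.spacer_len,
                mm35=hit.mm35,
                mm10=hit.mm10,
                assigned_gene=head.id,
                distance_to_start=dist,
                operon_genes=op.genes if op else (gene_id,),
                truncated_window=truncated,
            )
    return sorted(seen.values(), key=lambda s: (s.box35[0], s.strand))


# ---------------------------------------------------------------------------
# Shine-Dalgarno scanning


def scan_sd(
    sequences: Iterable[tuple[str, str]],
    consensus: str = "AGGAG",
    max_mm: int = 1,
    merge_within: int = 2,
    start_offsets: dict[str, int] | None = None,
) -> list[SDHit]:
    """5-mer consensus scan at Hamming distance <= ``max_mm`` (0 or 1).

    ``sequences`` is an iterable of (id, sequence).  Hits whose starts lie
    within ``merge_within`` nt of each other are merged to the best (fewest
    mismatches, then leftmost).  When ``start_offsets`` maps an id to the
    position of a downstream start codon, the distance is reported if <=20.
    """
    if len(consensus) != 5:
        raise ValueError("consensus must be 5 nt")
    if max_mm not in (0, 1):
        raise ValueError("max_mm must be 0 or 1")
    out: list[SDHit] = []
    for seq_id, seq in sequences:
        s = seq.upper().replace("U", "T")
        raw: list[SDHit] = []
        for i in range(len(s) - 4):
            window = s[i : i + 5]
            mm = sum(a != b for a, b in zip(window, consensus))
            if mm <= max_mm:
                raw.append(SDHit(seq_id, i, window, mm))
        merged: list[SDHit] = []
        for hit in raw:  # raw is left-to-right
            if merged and hit.start - merged[-1].start <= merge_within:
                if hit.mismatches < merged[-1].mismatches:
                    merged[-1] = hit
            else:
                merged.append(hit)
        if start_offsets and seq_id in start_offsets:
            start = start_offsets[seq_id]
            for hit in merged:
                d = start - (hit.start + 5)
                if 0 <= d <= 20:
                    hit.distance_to_start = d
        out.extend(merged)
    return out


# ---------------------------------------------------------------------------
# operons


def predict_operons(genome: AnnotatedGenome, max_gap: int = 50) -> list[Operon]:
    """Maximal runs of same-strand consecutive genes with inter-gene gaps
    <= ``max_gap``; singleton genes form 1-gene operons.  On a circular
    genome the run crossing the origin is joined."""
    genes = genome.genes
    if not genes:
        return []
    runs: list[list[GeneFeature]] = [[genes[0]]]
    for g in genes[1:]:
        prev = runs[-1][-1]
        if g.strand == prev.strand and g.start - prev.end <= max_gap:
            runs[-1].append(g)
        else:
            runs.append([g])
    n = len(genome.sequence)
    if genome.topology == "circular" and len(runs) > 1:
        last, first = runs[-1], runs[0]
        wrap_gap = (n + first[0].start) - last[-1].end
        if last[-1].strand == first[0].strand and 0 <= wrap_gap <= max_gap:
            runs[0] = last + first
            runs.pop()

    operons = []
    for run in runs:
        strand = run[0].strand
        head = run[0] if strand == "+" else run[-1]
        operons.append(
            Operon(genes=tuple(g.id for g in run), strand=strand, head=head.id)
        )
    return operons


# ---------------------------------------------------------------------------
# heat-shock regulon screen


def regulon_screen(
    genomes: Sequence[AnnotatedGenome],
    regulon: Sequence[str] | None = None,
    ortholog_table=None,
) -> pd.DataFrame:
    """Table of regulon gene names per genome: the matching gene id, or
    None when the name is absent.

    Matching is case-insensitive on ``gene_name`` with a substring fallback
    on ``product``.  With an ortholog table, a name found in one genome is
    propagated to the orthologs' genomes.
    """
    import warnings

    names = list(regulon or HEAT_SHOCK_REGULON)
    hits: dict[str, dict[str, str | None]] = {g.id: {n: None for n in names} for g in genomes}
    for g in genomes:
        for name in names:
            low = name.lower()
            for gene in g.genes:
                if gene.gene_name.lower() == low or (not gene.gene_name and low in gene.product.lower()):
                    hits[g.id][name] = gene.id
                    break
    if ortholog_table is not None:
        g2grp = ortholog_table.gene_to_group()
        grp_members: dict[str, list[tuple[str, str]]] = {}
        for grp in ortholog_table.groups:
            grp_members[grp.group_id] = list(grp.members.items())
        for name in names:
            found = [(gid, hits[gid][name]) for gid in hits if hits[gid][name]]
            for gid, gene in found:
                grp_id = g2grp.get((gid, gene))
                if grp_id is None:
                    continue
                for other_gid, other_gene in grp_members[grp_id]:
                    if hits.get(other_gid, {}).get(name) is None and other_gid in hits:
                        hits[other_gid][name] = other_gene
    for gid, row in hits.items():
        if all(v is None for v in row.values()):
            warnings.warn(f"genome {gid}: no regulon gene found; all-absent row")
    df = pd.DataFrame.from_dict(hits, orient="index")
    return df[names]
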