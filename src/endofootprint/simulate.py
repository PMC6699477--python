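"""Seed-reproducible synthetic endosymbiont micro-genomes with planted truth.

The generator emulates the architecture of a reduced, AT-rich obligate
symbiont genome: a circular chromosome of alternating ORFs and intergenic
spacers at ~26% GC with roughly 30% intergenic content, four related genomes
arranged as two sister pairs (within-pair nucleotide divergence small enough
for >99% protein identity), conserved gene order, and regulatory truth
planted into spacers:

* Shine-Dalgarno motifs (``AGGAG``) 5–10 nt upstream of start codons,
* two-box σ32 promoter sites upstream of the grpE- and groES-led operons,
* fold-back hairpin cassettes (sRNA stand-ins) mid-spacer,
* heat-shock regulon gene names on a subset of genes.

Descendants evolve along a user-supplied tree with HKY-like substitution
(transition bias κ=2), 10x rate reduction inside planted elements and their
immediate flanks (conservation as rate scaling, not hard freezing), and
spacer indels at a configurable rate.  Identical seeds give byte-identical
output.  Ct tables with planted ΔΔCt effects and Gaussian noise are
generated separately for the expression stage.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Sequence

import dendropy
import numpy as np
import pandas as pd

from .genome import AnnotatedGenome, GeneFeature, revcomp, write_fasta, write_genbank, write_gff3
from .motifs import HEAT_SHOCK_REGULON
from .orthology import STOP_CODONS, translate_cds

_BASES = np.array(list("ACGT"))
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}


def _sub_base(old: str, rng: np.random.Generator, gc: float) -> str:
    """HKY-like replacement: weight by stationary frequency (AT-rich) with a
    κ=2 transition bias, so base composition is approximately preserved."""
    freqs = {"A": (1 - gc) / 2, "C": gc / 2, "G": gc / 2, "T": (1 - gc) / 2}
    ts = _TRANSITION[old]
    bases = [b for b in "ACGT" if b != old]
    weights = [freqs[b] * (2.0 if b == ts else 1.0) for b in bases]
    r = rng.random() * sum(weights)
    acc = 0.0
    for b, w in zip(bases, weights):
        acc += w
        if r <= acc:
            return b
    return bases[-1]

DEFAULT_TREE = "((Z1:0.002,Z3:0.002):0.01,(B:0.002,Q:0.002):0.01);"


@dataclass
class SimConfig:
    seed: int = 0
    tree: str = DEFAULT_TREE
    n_genes: int = 60
    mean_gene_len: int = 100  # codons
    igs_mean_len: int = 130  # bp
    gc_target: float = 0.26
    igs_indel_rate: float = 0.05  # events/site per unit branch length
    n_sd: int = 20
    n_sigma: int = 2  # fixed placements: upstream of grpE and groES operon heads
    n_hairpins: int = 10
    element_rate_scale: float = 0.1  # substitution-rate multiplier in planted spans
    regulon_names: tuple[str, ...] = tuple(HEAT_SHOCK_REGULON)
    circular: bool = True
    rotate_origin: bool = True

    def __post_init__(self) -> None:
        if not (0.0 < self.gc_target < 1.0):
            raise ValueError("gc_target must be in (0, 1)")
        if min(self.igs_indel_rate, self.element_rate_scale) < 0:
            raise ValueError("rates must be >= 0")
        if self.n_genes < 45:
            raise ValueError("n_genes must be >= 45 to place the regulon layout")
        if self.igs_mean_len < 60:
            raise ValueError("igs_mean_len too small for planted elements")


@dataclass
class PlantedElement:
    kind: str  # 'sd' | 'sigma' | 'hairpin'
    igs_index: int
    core_off: int  # offset of the element within the spacer
    core_len: int
    cons_off: int  # offset of the conserved (rate-scaled) span
    cons_len: int
    gene_index: int | None = None  # downstream gene for sd/sigma


@dataclass
class TruthRecord:
    kind: str
    start: int
    end: int
    gene_id: str | None


@dataclass
class TruthSet:
    elements: dict[str, list[TruthRecord]]  # genome id -> planted coordinates
    ortholog_map: list[dict[str, str]]  # gene index -> {genome id: gene id}
    operon_map: list[tuple[int, ...]]  # gene-index runs forced into operons
    regulon_positions: dict[str, int]  # gene name -> gene index

    def by_kind(self, genome_id: str, kind: str) -> list[TruthRecord]:
        return [r for r in self.elements[genome_id] if r.kind == kind]

    def write_bed(self, path: str | Path) -> None:
        lines = []
        for gid in sorted(self.elements):
            for r in self.elements[gid]:
                lines.append(f"{gid}\t{r.start}\t{r.end}\t{r.kind}:{r.gene_id or '.'}\t0\t+")
        Path(path).write_text("\n".join(lines) + "\n")


# ---------------------------------------------------------------------------
# ancestral genome construction

_SIGMA_BOX35 = "CTTGAAA"
_SIGMA_BOX10 = "CCCCATAT"
_SD = "AGGAG"
_FLANK = 20  # conserved flank on each side of a planted element


def _rand_seq(rng: np.random.Generator, n: int, gc: float) -> str:
    p = np.array([(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2])
    return "".join(_BASES[rng.choice(4, size=n, p=p)])


import functools


@functools.lru_cache(maxsize=None)
def _codon_sampling_gc(target: float) -> float:
    """Per-base GC to use when sampling sense codons so that the accepted
    (stop-rejected) codons average the target GC; stops are AT-rich, so
    rejection inflates GC and the sampling composition must sit lower."""
    import itertools as it

    def expected(g: float) -> float:
        pb = {"A": (1 - g) / 2, "C": g / 2, "G": g / 2, "T": (1 - g) / 2}
        tot = gc_mass = 0.0
        for codon in it.product("ACGT", repeat=3):
            s = "".join(codon)
            if s in STOP_CODONS:
                continue
            p = pb[s[0]] * pb[s[1]] * pb[s[2]]
            tot += p
            gc_mass += p * (s.count("G") + s.count("C")) / 3.0
        return gc_mass / tot

    lo, hi = 0.01, 0.9
    for _ in range(40):
        mid = (lo + hi) / 2
        if expected(mid) < target:
            lo = mid
        else:
            hi = mid
    return (lo + hi) / 2


def _rand_codons(rng: np.random.Generator, n: int, gc: float) -> str:
    g = _codon_sampling_gc(gc)
    out = []
    while len(out) < n:
        codon = _rand_seq(rng, 3, g)
        if codon not in STOP_CODONS:
            out.append(codon)
    return "".join(out)


@dataclass
class _Part:
    kind: str  # 'gene' | 'igs'
    seq: str  # coding-oriented for genes, genome-forward for spacers
    index: int
    strand: str = "+"
    name: str = ""
    elements: list[PlantedElement] = field(default_factory=list)


def _regulon_layout(config: SimConfig) -> tuple[dict[str, int], list[tuple[int, ...]]]:
    """Place regulon names on gene indices; grpE-dnaK-dnaJ and groES-groEL
    are consecutive operons."""
    names = list(config.regulon_names)
    positions: dict[str, int] = {}
    operons: list[tuple[int, ...]] = []
    if {"grpE", "dnaK", "dnaJ"} <= set(names):
        positions.update({"grpE": 5, "dnaK": 6, "dnaJ": 7})
        operons.append((5, 6, 7))
    if {"groES", "groEL"} <= set(names):
        positions.update({"groES": 10, "groEL": 11})
        operons.append((10, 11))
    rest = [n for n in names if n not in positions]
    slot = 13
    for n in rest:
        positions[n] = slot
        slot += 3
    if positions and max(positions.values()) >= config.n_genes:
        raise ValueError("n_genes too small for the regulon layout")
    return positions, operons


def _build_ancestor(config: SimConfig, rng: np.random.Generator) -> list[_Part]:
    positions, operons = _regulon_layout(config)
    idx_to_name = {v: k for k, v in positions.items()}
    operon_members = {i for op in operons for i in op}
    operon_internal_igs = {op[k] for op in operons for k in range(len(op) - 1)}
    sigma_igs = {op[0] - 1 for op in operons[: config.n_sigma]}  # igs upstream of operon heads

    parts: list[_Part] = []
    for i in range(config.n_genes):
        n_codons = max(30, int(rng.normal(config.mean_gene_len, config.mean_gene_len * 0.2)))
        seq = "ATG" + _rand_codons(rng, n_codons - 2, config.gc_target) + "TAA"
        if i in operon_members or i in idx_to_name:
            strand = "+"
        else:
            strand = "+" if rng.random() < 0.5 else "-"
        parts.append(_Part("gene", seq, i, strand, idx_to_name.get(i, "")))

        if i in operon_internal_igs:
            igs_len = int(rng.integers(5, 21))
        elif i in sigma_igs:
            igs_len = max(140, int(rng.normal(config.igs_mean_len, 40)))
        else:
            igs_len = max(40, int(rng.normal(config.igs_mean_len, 50)))
        parts.append(_Part("igs", _rand_seq(rng, igs_len, config.gc_target), i))

    igs_parts = {p.index: p for p in parts if p.kind == "igs"}
    last_igs = config.n_genes - 1  # wraps the origin after rotation; keep unplanted

    def plant(igs_idx: int, offset: int, element: str, kind: str, gene_index: int | None) -> None:
        part = igs_parts[igs_idx]
        if offset < 0 or offset + len(element) > len(part.seq):
            raise ValueError(f"planted {kind} does not fit spacer {igs_idx}")
        part.seq = part.seq[:offset] + element + part.seq[offset + len(element) :]
        cons_off = max(0, offset - _FLANK)
        cons_end = min(len(part.seq), offset + len(element) + _FLANK)
        part.elements.append(
            PlantedElement(kind, igs_idx, offset, len(element), cons_off, cons_end - cons_off, gene_index)
        )

    # σ32 sites upstream of the operon heads
    for op in operons[: config.n_sigma]:
        igs_idx = op[0] - 1
        spacer = _rand_seq(rng, int(rng.integers(11, 16)), config.gc_target)
        site = _SIGMA_BOX35 + spacer + _SIGMA_BOX10
        dist = int(rng.integers(20, 61))  # box10 end -> gene start
        part = igs_parts[igs_idx]
        plant(igs_idx, len(part.seq) - dist - len(site), site, "sigma", op[0])

    # Shine-Dalgarno motifs upstream of '+'-strand genes
    sd_candidates = [
        i
        for i in range(config.n_genes)
        if parts[2 * i].strand == "+"
        and (i - 1) % config.n_genes not in sigma_igs
        and (i - 1) % config.n_genes != last_igs
        and len(igs_parts[(i - 1) % config.n_genes].seq) >= 45
        and not igs_parts[(i - 1) % config.n_genes].elements
    ]
    chosen = sorted(rng.choice(sd_candidates, size=min(config.n_sd, len(sd_candidates)), replace=False).tolist())
    for i in chosen:
        igs_idx = (i - 1) % config.n_genes
        d = int(rng.integers(5, 11))
        plant(igs_idx, len(igs_parts[igs_idx].seq) - d - len(_SD), _SD, "sd", i)

    # hairpin cassettes mid-spacer
    hp_candidates = [
        idx
        for idx, part in sorted(igs_parts.items())
        if idx != last_igs and len(part.seq) >= 90 and not any(e.kind == "sigma" for e in part.elements)
    ]
    chosen_hp = sorted(rng.choice(hp_candidates, size=min(config.n_hairpins, len(hp_candidates)), replace=False).tolist())
    for idx in chosen_hp:
        stem = _rand_seq(rng, 10, 0.6)
        cassette = stem + _rand_seq(rng, 4, config.gc_target) + revcomp(stem)
        part = igs_parts[idx]
        plant(idx, len(part.seq) // 2 - len(cassette) // 2, cassette, "hairpin", None)
    return parts


# ---------------------------------------------------------------------------
# evolution along the tree


def _mutate_gene(seq: str, d: float, rng: np.random.Generator, gc: float) -> str:
    if d <= 0:
        return seq
    chars = list(seq)
    n = len(chars)
    k = rng.binomial(n, d)
    if k == 0:
        return seq
    pos = rng.choice(n, size=k, replace=False)
    for p in sorted(int(x) for x in pos):
        old = chars[p]
        new = _sub_base(old, rng, gc)
        codon_i = p // 3
        codon = chars[3 * codon_i : 3 * codon_i + 3]
        codon[p % 3] = new
        codon_s = "".join(codon)
        if codon_i == 0:
            continue  # keep the start codon intact
        if codon_i == n // 3 - 1:
            if codon_s not in STOP_CODONS:
                continue  # terminal codon must stay a stop
        elif codon_s in STOP_CODONS:
            continue  # no internal stops
        chars[p] = new
    return "".join(chars)


def _mutate_igs(part: _Part, d: float, indel_rate: float, rng: np.random.Generator, gc: float) -> _Part:
    if d <= 0:
        return part
    seq = part.seq
    n = len(seq)
    scale = np.full(n, d)
    for el in part.elements:
        scale[el.cons_off : el.cons_off + el.cons_len] *= 0.1
    mask = rng.random(n) < scale
    chars = list(seq)
    for p in np.nonzero(mask)[0]:
        chars[p] = _sub_base(chars[p], rng, gc)
    elements = [replace(el) for el in part.elements]
    n_events = rng.poisson(indel_rate * n * d)
    for _ in range(n_events):
        for _try in range(10):
            size = int(rng.integers(1, 4))
            insert = rng.random() < 0.5
            pos = int(rng.integers(0, len(chars) + 1 if insert else max(len(chars) - size, 1)))
            span = (pos, pos) if insert else (pos, pos + size)
            clash = any(
                span[1] > el.cons_off and span[0] < el.cons_off + el.cons_len for el in elements
            )
            if clash:
                continue
            if insert:
                chars[pos:pos] = list(_rand_seq(rng, size, gc))
                delta, at = size, pos
            else:
                del chars[pos : pos + size]
                delta, at = -size, pos
            for el in elements:
                if el.cons_off >= at:
                    el.cons_off += delta
                    el.core_off += delta
            break
    return replace(part, seq="".join(chars), elements=elements)


def _evolve(parts: list[_Part], d: float, config: SimConfig, rng: np.random.Generator) -> list[_Part]:
    out = []
    for part in parts:
        if part.kind == "gene":
            out.append(replace(part, seq=_mutate_gene(part.seq, d, rng, config.gc_target)))
        else:
            out.append(_mutate_igs(part, d, config.igs_indel_rate, rng, config.gc_target))
    return out


# ---------------------------------------------------------------------------
# assembly


def _assemble(leaf_id: str, parts: list[_Part], config: SimConfig) -> tuple[AnnotatedGenome, list[TruthRecord]]:
    seq_chunks: list[str] = []
    genes: list[GeneFeature] = []
    truth: list[TruthRecord] = []
    cursor = 0
    gene_ids: dict[int, str] = {}
    for part in parts:
        if part.kind == "gene":
            gid = f"{leaf_id}_{part.index:03d}"
            gene_ids[part.index] = gid
            coding = part.seq
            genome_fwd = coding if part.strand == "+" else revcomp(coding)
            genes.append(
                GeneFeature(
                    id=gid,
                    start=cursor,
                    end=cursor + len(coding),
                    strand=part.strand,
                    kind="CDS",
                    gene_name=part.name,
                    product=f"{part.name} protein" if part.name else "hypothetical protein",
                    translation=translate_cds(coding),
                )
            )
            seq_chunks.append(genome_fwd)
            cursor += len(coding)
        else:
            for el in part.elements:
                truth.append(
                    TruthRecord(
                        kind=el.kind,
                        start=cursor + el.core_off,
                        end=cursor + el.core_off + el.core_len,
                        gene_id=None if el.gene_index is None else f"{leaf_id}_{el.gene_index:03d}",
                    )
                )
            seq_chunks.append(part.seq)
            cursor += len(part.seq)
    sequence = "".join(seq_chunks)
    L = len(sequence)
    if config.circular and config.rotate_origin:
        # rotate so the origin falls mid-way through the final spacer, which
        # then becomes the wrap-around spacer; no gene spans the origin
        shift = len(parts[-1].seq) // 2
        p0 = L - shift
        sequence = sequence[p0:] + sequence[:p0]
        for g in genes:
            length = g.end - g.start
            g.start = (g.start + shift) % L
            g.end = g.start + length
        for r in truth:
            length = r.end - r.start
            r.start = (r.start + shift) % L
            r.end = r.start + length
    genome = AnnotatedGenome(
        id=leaf_id,
        sequence=sequence,
        genes=genes,
        topology="circular" if config.circular else "linear",
        source_format="genbank",
    )
    return genome, truth


def simulate_genomes(
    config: SimConfig, outdir: str | Path | None = None
) -> tuple[list[AnnotatedGenome], TruthSet]:
    """Generate the genome set defined by ``config``.

    Returns the genomes (sorted by id) and the planted truth; when
    ``outdir`` is given, GenBank, GFF3, FASTA and truth BED files are
    written there.
    """
    rng = np.random.default_rng(config.seed)
    ancestor = _build_ancestor(config, rng)
    positions, operon_idx = _regulon_layout(config)

    tree = dendropy.Tree.get(data=config.tree, schema="newick")
    leaves: dict[str, list[_Part]] = {}

    def walk(node, parts):
        d = node.edge.length or 0.0
        evolved = _evolve(parts, d, config, rng) if node.parent_node is not None else parts
        if node.is_leaf():
            leaves[node.taxon.label] = evolved
        else:
            for child in node.child_nodes():
                walk(child, evolved)

    walk(tree.seed_node, ancestor)

    genomes: list[AnnotatedGenome] = []
    elements: dict[str, list[TruthRecord]] = {}
    for leaf_id in sorted(leaves):
        g, truth = _assemble(leaf_id, leaves[leaf_id], config)
        genomes.append(g)
        elements[leaf_id] = truth

    ortholog_map = [
        {g.id: f"{g.id}_{i:03d}" for g in genomes} for i in range(config.n_genes)
    ]
    truth_set = TruthSet(
        elements=elements,
        ortholog_map=ortholog_map,
        operon_map=operon_idx,
        regulon_positions=positions,
    )

    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for g in genomes:
            write_genbank(g, outdir / f"{g.id}.gb")
            write_gff3(g, outdir / f"{g.id}.gff3")
            write_fasta(g, outdir / f"{g.id}.fa")
        truth_set.write_bed(outdir / "truth.bed")
    return genomes, truth_set


# ---------------------------------------------------------------------------
# Ct tables


def simulate_ct(
    effects: dict[str, float],
    n_reps: int = 4,
    noise_sd: float = 0.2,
    seed: int = 0,
    assay: str = "cdna",
    reference: str = "RPL29",
    baseline_dct: float = 5.0,
) -> pd.DataFrame:
    """Ct table with planted ΔΔCt effects and Gaussian noise.

    Control ΔCt values sit at ``baseline_dct``; treatment ΔCt values are
    shifted by the per-target effect (negative effect = upregulation).
    """
    if n_reps < 2:
        raise ValueError("need at least two replicates")
    rng = np.random.default_rng(seed)
    rows = []
    for target in sorted(effects):
        for condition in ("control", "treatment"):
            shift = effects[target] if condition == "treatment" else 0.0
            for rep in range(1, n_reps + 1):
                ct_ref = 20.0 + rng.normal(0.0, 0.1) if noise_sd > 0 else 20.0
                dct = baseline_dct + shift + (rng.normal(0.0, noise_sd) if noise_sd > 0 else 0.0)
                rows.append(
                    dict(
                        sample=f"{condition[:1]}{rep}",
                        condition=condition,
                        replicate=rep,
                        target=target,
                        ct_target=round(ct_ref + dct, 4),
                        reference=reference,
                        ct_reference=round(ct_ref, 4),
                        assay=assay,
                    )
                )
    return pd.DataFrame(rows)
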