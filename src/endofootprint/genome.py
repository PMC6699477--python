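"""Annotated-genome I/O, coordinate handling and architecture statistics.

The unit of analysis throughout the package is an :class:`AnnotatedGenome`: a
(usually circular) DNA sequence plus an ordered, strand-aware list of gene
features.  Coordinates are 0-based half-open internally; GenBank's 1-based
inclusive convention and GFF3's 1-based inclusive convention are converted at
the I/O boundary.  The single feature of a circular genome that spans the
origin is kept as one feature whose ``end`` exceeds the sequence length
(interpreted modulo the length).

Reduced endosymbiont genomes such as *Candidatus* Portiera aleyrodidarum
(~350 kb, ~26% GC, >30% intergenic) are the motivating input, but nothing
here is specific to them.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

GENE_KINDS = ("CDS", "tRNA", "rRNA", "other")

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string (A/C/G/T/N)."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass
class GeneFeature:
    """A gene on the genome; ``[start, end)`` 0-based half-open.

    ``end`` may exceed the genome length only for the origin-spanning feature
    of a circular genome.
    """

    id: str
    start: int
    end: int
    strand: str  # '+' or '-'
    kind: str = "CDS"
    product: str = ""
    translation: str = ""
    gene_name: str = ""

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"feature {self.id}: start {self.start} >= end {self.end}")
        if self.strand not in "+-":
            raise ValueError(f"feature {self.id}: strand must be '+' or '-'")
        if self.kind not in GENE_KINDS:
            raise ValueError(f"feature {self.id}: kind {self.kind!r} not in {GENE_KINDS}")

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class AnnotatedGenome:
    id: str
    sequence: str
    genes: list[GeneFeature]
    accession: str = ""
    topology: str = "circular"  # or 'linear'
    source_format: str = "genbank"

    def __post_init__(self) -> None:
        self.sequence = self.sequence.upper()
        if not self.sequence:
            raise ValueError(f"genome {self.id}: zero-length sequence")
        bad = set(self.sequence) - set("ACGTN")
        if bad:
            raise ValueError(f"genome {self.id}: non-DNA characters {sorted(bad)}")
        self.genes.sort(key=lambda g: (g.start, g.end))
        n = len(self.sequence)
        ids = set()
        for g in self.genes:
            if g.id in ids:
                raise ValueError(f"genome {self.id}: duplicate gene id {g.id}")
            ids.add(g.id)
            if not (0 <= g.start < n):
                raise ValueError(f"genome {self.id}: {g.id} start outside sequence")
            if g.end > n and self.topology != "circular":
                raise ValueError(f"genome {self.id}: {g.id} wraps a linear genome")

    def __len__(self) -> int:
        return len(self.sequence)

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, AnnotatedGenome):
            return NotImplemented
        return (
            self.id == other.id
            and self.sequence == other.sequence
            and self.topology == other.topology
            and self.genes == other.genes
        )

    def gene(self, gene_id: str) -> GeneFeature:
        for g in self.genes:
            if g.id == gene_id:
                return g
        raise KeyError(gene_id)

    def slice(self, start: int, end: int) -> str:
        """Sequence of ``[start, end)``; wraps the origin when end > length."""
        n = len(self.sequence)
        if end <= n:
            return self.sequence[start:end]
        if self.topology != "circular":
            raise ValueError("interval wraps a linear genome")
        return self.sequence[start:] + self.sequence[: end % n]

    def gene_intervals(self) -> list[tuple[int, int]]:
        """Linearized gene intervals, origin-spanning features split in two."""
        n = len(self.sequence)
        out: list[tuple[int, int]] = []
        for g in self.genes:
            if g.end <= n:
                out.append((g.start, g.end))
            else:
                out.append((g.start, n))
                out.append((0, g.end % n))
        return sorted(out)


@dataclass
class GenomeStats:
    genome_id: str
    genome_size: int
    cds_count: int
    trna_count: int
    rrna_count: int
    igs_fraction: float  # percent of genome not covered by any gene feature
    gc_coding: float  # percent GC over the union of gene-covered positions
    gc_igs: float  # percent GC over intergenic positions


@dataclass
class IntergenicSpacer:
    """The gap between two consecutive genes; may wrap the origin."""

    genome_id: str
    start: int
    end: int  # > genome length when the spacer wraps the origin
    left_gene: str
    right_gene: str
    left_strand: str
    right_strand: str
    sequence: str

    @property
    def length(self) -> int:
        return self.end - self.start

    @property
    def name(self) -> str:
        return f"{self.left_gene}|{self.right_gene}"


# ---------------------------------------------------------------------------
# reading


def _features_from_genbank(rec: SeqRecord, length: int) -> list[GeneFeature]:
    kind_map = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}
    genes: list[GeneFeature] = []
    counter = 0
    for feat in rec.features:
        if feat.type not in ("CDS", "tRNA", "rRNA", "ncRNA", "misc_feature", "tmRNA"):
            continue
        kind = kind_map.get(feat.type, "other")
        loc = feat.location
        strand = "-" if loc.strand == -1 else "+"
        if isinstance(loc, CompoundLocation):
            parts = sorted(loc.parts, key=lambda p: int(p.start))
            # origin-spanning join(): last part ends at the sequence end and
            # the first part starts at 0
            if len(parts) == 2 and int(parts[1].end) == length and int(parts[0].start) == 0:
                start, end = int(parts[1].start), length + int(parts[0].end)
            else:
                start, end = int(loc.start), int(loc.end)
        else:
            start, end = int(loc.start), int(loc.end)
        quals = feat.qualifiers
        gid = quals.get("locus_tag", quals.get("gene", [f"feat{counter:04d}"]))[0]
        counter += 1
        genes.append(
            GeneFeature(
                id=gid,
                start=start,
                end=end,
                strand=strand,
                kind=kind,
                product=quals.get("product", [""])[0],
                translation=quals.get("translation", [""])[0],
                gene_name=quals.get("gene", [""])[0],
            )
        )
    return genes


def _read_gff3(gff_path: Path, length: int) -> list[GeneFeature]:
    """Minimal tabular GFF3 feature reading (CDS/tRNA/rRNA rows)."""
    kind_map = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA"}
    genes: list[GeneFeature] = []
    counter = 0
    for line in Path(gff_path).read_text().splitlines():
        if not line or line.startswith("#"):
            continue
        cols = line.split("\t")
        if len(cols) != 9:
            raise ValueError(f"malformed GFF3 line: {line[:80]!r}")
        _, _, ftype, start, end, _, strand, _, attrs = cols
        if ftype not in ("CDS", "tRNA", "rRNA", "ncRNA"):
            continue
        attr = dict(
            kv.split("=", 1) for kv in attrs.strip(";").split(";") if "=" in kv
        )
        gid = attr.get("ID", attr.get("locus_tag", f"feat{counter:04d}"))
        counter += 1
        genes.append(
            GeneFeature(
                id=gid,
                start=int(start) - 1,  # GFF3 is 1-based inclusive
                end=int(end),
                strand=strand if strand in "+-" else "+",
                kind=kind_map.get(ftype, "other"),
                product=attr.get("product", ""),
                translation=attr.get("translation", ""),
                gene_name=attr.get("gene", attr.get("Name", "")),
            )
        )
    return genes


def read_genome(path: str | Path, format: str = "genbank", gff_path: str | Path | None = None) -> AnnotatedGenome:
    """Read an annotated genome from a GenBank flat file or FASTA + GFF3 pair.

    For ``format='fasta+gff3'`` the annotation is taken from ``gff_path``,
    defaulting to the FASTA path with a ``.gff3`` suffix.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if format == "genbank":
        try:
            rec = SeqIO.read(str(path), "genbank")
        except Exception as exc:  # noqa: BLE001 - re-raise with file context
            raise ValueError(f"cannot parse GenBank file {path}: {exc}") from exc
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"{path}: zero-length sequence")
        topology = rec.annotations.get("topology", "linear")
        return AnnotatedGenome(
            id=rec.name or rec.id,
            accession=rec.id,
            sequence=seq,
            topology=topology if topology in ("circular", "linear") else "linear",
            genes=_features_from_genbank(rec, len(seq)),
            source_format="genbank",
        )
    if format == "fasta+gff3":
        rec = SeqIO.read(str(path), "fasta")
        seq = str(rec.seq).upper()
        if not seq:
            raise ValueError(f"{path}: zero-length sequence")
        gff = Path(gff_path) if gff_path else path.with_suffix(".gff3")
        topology = "circular" if "circular" in rec.description.lower() else "linear"
        return AnnotatedGenome(
            id=rec.id,
            accession=rec.id,
            sequence=seq,
            topology=topology,
            genes=_read_gff3(gff, len(seq)),
            source_format="fasta+gff3",
        )
    raise ValueError(f"unknown format {format!r}")


# ---------------------------------------------------------------------------
# writing


def write_genbank(genome: AnnotatedGenome, path: str | Path) -> None:
    n = len(genome.sequence)
    rec = SeqRecord(Seq(genome.sequence), id=genome.accession or genome.id, name=genome.id)
    rec.annotations["molecule_type"] = "DNA"
    rec.annotations["topology"] = genome.topology
    rec.annotations["date"] = "01-JAN-1980"  # fixed so output is byte-stable
    type_map = {"CDS": "CDS", "tRNA": "tRNA", "rRNA": "rRNA", "other": "misc_feature"}
    for g in genome.genes:
        strand = 1 if g.strand == "+" else -1
        if g.end <= n:
            loc = SimpleLocation(g.start, g.end, strand=strand)
        else:
            parts = [SimpleLocation(g.start, n, strand=strand), SimpleLocation(0, g.end % n, strand=strand)]
            if strand == -1:
                parts = parts[::-1]
            loc = CompoundLocation(parts)
        quals = {"locus_tag": [g.id]}
        if g.product:
            quals["product"] = [g.product]
        if g.gene_name:
            quals["gene"] = [g.gene_name]
        if g.translation:
            quals["translation"] = [g.translation]
        rec.features.append(SeqFeature(loc, type=type_map[g.kind], qualifiers=quals))
    SeqIO.write([rec], str(path), "genbank")


def write_gff3(genome: AnnotatedGenome, path: str | Path) -> None:
    n = len(genome.sequence)
    lines = ["##gff-version 3", f"##sequence-region {genome.id} 1 {n}"]
    for g in genome.genes:
        attrs = [f"ID={g.id}"]
        if g.gene_name:
            attrs.append(f"gene={g.gene_name}")
        if g.product:
            attrs.append(f"product={g.product}")
        if g.translation:
            attrs.append(f"translation={g.translation}")
        ftype = g.kind if g.kind != "other" else "ncRNA"
        lines.append(
            "\t".join(
                [genome.id, "endofootprint", ftype, str(g.start + 1), str(g.end), ".", g.strand, ".", ";".join(attrs)]
            )
        )
    Path(path).write_text("\n".join(lines) + "\n")


def write_fasta(genome: AnnotatedGenome, path: str | Path) -> None:
    desc = "circular" if genome.topology == "circular" else "linear"
    with open(path, "w") as fh:
        fh.write(f">{genome.id} {desc}\n")
        for i in range(0, len(genome.sequence), 70):
            fh.write(genome.sequence[i : i + 70] + "\n")


def write_spacers_bed(spacers: Sequence[IntergenicSpacer], path: str | Path) -> None:
    """BED6; wrap-around spacers are emitted as one record with end > size."""
    with open(path, "w") as fh:
        for sp in spacers:
            fh.write(f"{sp.genome_id}\t{sp.start}\t{sp.end}\t{sp.name}\t0\t+\n")


def write_spacers_fasta(spacers: Sequence[IntergenicSpacer], path: str | Path) -> None:
    with open(path, "w") as fh:
        for sp in spacers:
            fh.write(f">{sp.genome_id}:{sp.name}\n{sp.sequence}\n")


# ---------------------------------------------------------------------------
# statistics


def merge_intervals(intervals: Iterable[tuple[int, int]]) -> list[tuple[int, int]]:
    """Merge overlapping/abutting intervals into a disjoint sorted list."""
    merged: list[list[int]] = []
    for s, e in sorted(intervals):
        if merged and s <= merged[-1][1]:
            merged[-1][1] = max(merged[-1][1], e)
        else:
            merged.append([s, e])
    return [(s, e) for s, e in merged]


def _gc_percent(seq_parts: Iterable[str]) -> float:
    gc = at = 0
    for part in seq_parts:
        gc += part.count("G") + part.count("C")
        at += part.count("A") + part.count("T")
    total = gc + at  # N bases excluded from both numerator and denominator
    return 100.0 * gc / total if total else 0.0


def compute_stats(genome: AnnotatedGenome) -> GenomeStats:
    """Genome-architecture statistics: counts by kind, intergenic fraction,
    and GC content over the coding/intergenic partition.

    Overlapping gene features are merged first, so gene-covered bp plus
    intergenic bp always equals the genome size.  All gene kinds (including
    structural RNAs) count as genic for the partition.
    """
    if not genome.genes:
        raise ValueError("genome has no gene features")
    n = len(genome.sequence)
    merged = merge_intervals(genome.gene_intervals())
    covered = sum(e - s for s, e in merged)
    coding_parts = [genome.sequence[s:e] for s, e in merged]
    igs_parts = []
    prev = 0
    for s, e in merged:
        if s > prev:
            igs_parts.append(genome.sequence[prev:s])
        prev = max(prev, e)
    if prev < n:
        igs_parts.append(genome.sequence[prev:n])
    return GenomeStats(
        genome_id=genome.id,
        genome_size=n,
        cds_count=sum(g.kind == "CDS" for g in genome.genes),
        trna_count=sum(g.kind == "tRNA" for g in genome.genes),
        rrna_count=sum(g.kind == "rRNA" for g in genome.genes),
        igs_fraction=round(100.0 * (n - covered) / n, 1),
        gc_coding=round(_gc_percent(coding_parts), 1),
        gc_igs=round(_gc_percent(igs_parts), 1),
    )


def stats_table(stats: Sequence[GenomeStats]):
    import pandas as pd

    return pd.DataFrame([vars(s) for s in stats]).set_index("genome_id")


def write_stats(stats: Sequence[GenomeStats], tsv_path: str | Path | None = None, json_path: str | Path | None = None) -> None:
    df = stats_table(stats)
    if tsv_path:
        df.to_csv(tsv_path, sep="\t")
    if json_path:
        Path(json_path).write_text(json.dumps([vars(s) for s in stats], indent=1))


# ---------------------------------------------------------------------------
# intergenic spacers


def extract_igs(
    genome: AnnotatedGenome,
    min_len: int = 1,
    include_wraparound: bool = True,
) -> list[IntergenicSpacer]:
    """One spacer per consecutive gene pair with gap >= ``min_len``.

    Overlapping or nested genes yield no spacer between them; the flanking
    gene reported on the left is the one reaching furthest right.  For a
    circular genome the wrap-around gap between the last and first gene is
    included unless disabled.
    """
    if min_len < 0:
        raise ValueError("min_len must be >= 0")
    genes = genome.genes
    if not genes:
        return []
    n = len(genome.sequence)
    spacers: list[IntergenicSpacer] = []

    def emit(left: GeneFeature, right: GeneFeature, start: int, end: int) -> None:
        if end <= start or end - start < min_len:
            return
        spacers.append(
            IntergenicSpacer(
                genome_id=genome.id,
                start=start % n,
                end=end if end <= n else end,
                left_gene=left.id,
                right_gene=right.id,
                left_strand=left.strand,
                right_strand=right.strand,
                sequence=genome.slice(start % n, (start % n) + (end - start)),
            )
        )

    rightmost = genes[0]
    right_edge = genes[0].end
    for g in genes[1:]:
        if g.start > right_edge:
            emit(rightmost, g, right_edge, g.start)
        if g.end > right_edge:
            rightmost, right_edge = g, g.end
    if genome.topology == "circular" and include_wraparound:
        first = genes[0]
        # gap from the rightmost end around the origin to the first gene start
        if right_edge <= n:
            wrap_end = n + first.start
            if wrap_end > right_edge:
                emit(rightmost, first, right_edge, wrap_end)
        else:  # an origin-spanning gene already covers the junction
            eff = right_edge % n
            if first.start > eff:
                emit(rightmost, first, eff, first.start)
    return spacers
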