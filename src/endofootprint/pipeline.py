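"""End-to-end orchestration: stats → orthologs → footprint → scans → folds.

Every stage persists a plain-text intermediate (TSV/BED/FASTA/newick/JSON)
under the output directory, and the run ends with a machine-readable summary
whose counts equal the lengths of the corresponding stage outputs.  Reruns
with an identical configuration reproduce an identical summary.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Any, Sequence

from . import __version__
from .fold import srna_screen, write_dotbracket, write_folds_tsv
from .footprint import (
    align_group,
    conserved_loci,
    length_association,
    pair_orthologous_igs,
    write_alignment_fasta,
    write_groups_tsv,
    write_loci_tsv,
)
from .genome import (
    AnnotatedGenome,
    compute_stats,
    extract_igs,
    read_genome,
    write_spacers_bed,
    write_spacers_fasta,
    write_stats,
)
from .motifs import HEAT_SHOCK_REGULON, TwoBoxMotif, predict_operons, regulon_screen, scan_sd, sigma32_sites
from .orthology import core_similarity, find_orthologs, nj_tree
from .simulate import SimConfig, simulate_genomes

log = logging.getLogger("endofootprint")


class StageError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"stage {stage!r} failed: {cause}")
        self.stage = stage
        self.cause = cause


@dataclass
class RunConfig:
    genome_paths: list[str] = field(default_factory=list)
    genome_format: str = "genbank"
    outdir: str = "endofootprint_out"
    seed: int = 0
    simulate: bool = False  # generate a synthetic quartet instead of reading files
    min_identity: float = 50.0
    min_coverage: float = 0.5
    igs_min_len: int = 1
    min_locus_len: int = 21
    upstream_window: int = 200
    mm35: int = 1
    mm10: int = 2
    operon_max_gap: int = 50
    sd_max_mm: int = 1
    regulon: list[str] = field(default_factory=lambda: list(HEAT_SHOCK_REGULON))
    log_level: str = "INFO"

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        import yaml

        data = yaml.safe_load(Path(path).read_text()) or {}
        unknown = set(data) - set(cls.__dataclass_fields__)
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**data)

    def config_hash(self) -> str:
        blob = json.dumps(asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


@dataclass
class RunSummary:
    version: str
    config_hash: str
    genomes: list[str]
    stats: dict[str, dict[str, Any]]
    core_genes: int
    igs_groups: int
    conserved_loci: int
    conserved_nt: int
    conserved_fraction: float
    sd_hits: int
    sigma_sites: int
    srna_candidates: int
    length_r2: dict[str, float]

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(asdict(self), indent=1, sort_keys=True))


def _stage(name: str):
    def deco(fn):
        def wrapped(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                out = fn(*args, **kwargs)
            except Exception as exc:  # noqa: BLE001
                raise StageError(name, exc) from exc
            log.info("stage %-12s done in %.2fs", name, time.perf_counter() - t0)
            return out

        return wrapped

    return deco


def run_all(config: RunConfig) -> RunSummary:
    """Execute every stage in dependency order; see module docstring."""
    logging.basicConfig(level=getattr(logging, config.log_level.upper(), logging.INFO))
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)

    @_stage("load")
    def load() -> list[AnnotatedGenome]:
        if config.simulate or not config.genome_paths:
            genomes, truth = simulate_genomes(SimConfig(seed=config.seed), outdir / "sim")
            return genomes
        return [read_genome(p, config.genome_format) for p in config.genome_paths]

    genomes = load()
    if len(genomes) < 2:
        raise StageError("load", ValueError("need at least two genomes"))
    ids = [g.id for g in genomes]

    @_stage("stats")
    def stats_stage():
        st = [compute_stats(g) for g in genomes]
        write_stats(st, outdir / "stats.tsv", outdir / "stats.json")
        return {s.genome_id: asdict_stats(s) for s in st}

    def asdict_stats(s):
        return {k: v for k, v in vars(s).items() if k != "genome_id"}

    stats = stats_stage()

    @_stage("orthologs")
    def ortho_stage():
        table = find_orthologs(genomes, config.min_identity, config.min_coverage)
        table.to_tsv(outdir / "orthologs.tsv")
        sim = core_similarity(table, genomes)
        sim.to_frame().to_csv(outdir / "core_similarity.tsv", sep="\t")
        if len(ids) >= 3:
            (outdir / "tree.nwk").write_text(nj_tree(sim) + "\n")
        return table

    table = ortho_stage()

    @_stage("spacers")
    def spacer_stage():
        out = {}
        for g in genomes:
            sp = extract_igs(g, min_len=config.igs_min_len)
            write_spacers_bed(sp, outdir / f"igs_{g.id}.bed")
            write_spacers_fasta(sp, outdir / f"igs_{g.id}.fa")
            out[g.id] = sp
        return out

    spacers = spacer_stage()

    @_stage("footprint")
    def footprint_stage():
        groups = pair_orthologous_igs(table, spacers)
        write_groups_tsv(groups, outdir / "igs_groups.tsv")
        loci = []
        with open(outdir / "igs_alignments.fa", "w") as fh:
            for grp in groups:
                if min(sp.length for sp in grp.members.values()) <= 20:
                    continue  # too short for conserved-locus analysis
                aln = align_group(grp, genome_order=ids)
                for gid, row in zip(aln.genome_ids, aln.rows):
                    fh.write(f">{grp.group_id}:{gid}\n{row}\n")
                loci.extend(conserved_loci(aln, grp, config.min_locus_len))
        write_loci_tsv(loci, outdir / "conserved_loci.tsv")
        r2 = {}
        for i in range(len(ids)):
            for j in range(i + 1, len(ids)):
                try:
                    assoc = length_association(groups, ids[i], ids[j])
                    r2[f"{ids[i]}-{ids[j]}"] = round(assoc.r_squared, 4)
                except ValueError:
                    pass
        with open(outdir / "length_r2.tsv", "w") as fh:
            fh.write("pair\tr_squared\n")
            for k, v in r2.items():
                fh.write(f"{k}\t{v}\n")
        return groups, loci, r2

    groups, loci, r2 = footprint_stage()

    @_stage("sd_scan")
    def sd_stage():
        hits = scan_sd(
            ((f"{lc.group_id}:{lc.col_start}", lc.consensus) for lc in loci),
            max_mm=config.sd_max_mm,
        )
        with open(outdir / "sd_hits.tsv", "w") as fh:
            fh.write("locus\tstart\tkmer\tmismatches\n")
            for h in hits:
                fh.write(f"{h.seq_id}\t{h.start}\t{h.kmer}\t{h.mismatches}\n")
        return hits

    sd_hits = sd_stage()

    @_stage("sigma_scan")
    def sigma_stage():
        motif = TwoBoxMotif(max_mm35=config.mm35, max_mm10=config.mm10)
        regulon_df = regulon_screen(genomes, config.regulon, table)
        regulon_df.to_csv(outdir / "regulon.tsv", sep="\t")
        all_sites = []
        for g in genomes:
            operons = predict_operons(g, config.operon_max_gap)
            present = [
                gene.id
                for gene in g.genes
                if gene.gene_name and gene.gene_name in config.regulon
            ]
            sites = sigma32_sites(g, present, config.upstream_window, motif, operons)
            all_sites.append((g.id, sites))
        with open(outdir / "sigma_sites.tsv", "w") as fh:
            fh.write("genome\tstrand\tbox35_start\tbox10_start\tspacer\tmm35\tmm10\tgene\tdistance\n")
            for gid, sites in all_sites:
                for s in sites:
                    fh.write(
                        f"{gid}\t{s.strand}\t{s.box35[0]}\t{s.box10[0]}\t{s.spacer_len}\t{s.mm35}\t{s.mm10}\t{s.assigned_gene}\t{s.distance_to_start}\n"
                    )
        return all_sites

    sigma_sites_all = sigma_stage()

    @_stage("fold")
    def fold_stage():
        results = srna_screen(loci, min_len=config.min_locus_len)
        write_folds_tsv(results, outdir / "folds.tsv")
        write_dotbracket(results, outdir / "folds.dbn")
        return results

    folds = fold_stage()

    conserved_nt = sum(lc.length for lc in loci)
    total_igs_nt = sum(
        sum(sp.length for sp in grp.members.values()) / len(grp.members)
        for grp in groups
        if min(sp.length for sp in grp.members.values()) > 20
    )
    n_sigma = len({(gid, s.box35[0]) for gid, sites in sigma_sites_all for s in sites})

    summary = RunSummary(
        version=__version__,
        config_hash=config.config_hash(),
        genomes=ids,
        stats=stats,
        core_genes=len(table.core_groups),
        igs_groups=len(groups),
        conserved_loci=len(loci),
        conserved_nt=conserved_nt,
        conserved_fraction=round(conserved_nt / total_igs_nt, 4) if total_igs_nt else 0.0,
        sd_hits=len(sd_hits),
        sigma_sites=n_sigma,
        srna_candidates=sum(r.is_srna_candidate for r in folds),
        length_r2=r2,
    )
    summary.to_json(outdir / "summary.json")
    return summary
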