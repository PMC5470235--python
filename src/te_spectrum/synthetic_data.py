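"""Synthetic multi-condition ESC dataset with planted truth.

Generates a miniature genome, gene/TE/region annotations, spliced RNA-seq
alignments (SAM) and per-CpG bisulfite call reports, with every downstream
signal planted so each pipeline stage can be verified against known truth:

* condition-graded gene expression (a 1-D "spectrum" gradient) plus planted
  condition-specific differential genes, counts drawn NB;
* activated TE families, with a configurable fraction of multimapping reads
  written as primary + secondary records sharing a read name;
* TE-to-gene chimeric transcripts: a TE placed upstream of a gene's first
  exon, with junction-spanning reads splicing from inside the TE to an
  annotated acceptor — plus adversarial chimeras placed beyond the caller's
  window that must never be recovered;
* ordinary gene splice junctions as decoys;
* per-CpG binomial methylation calls with condition-graded global levels
  and distinct imprint-region behaviour (maintained / atrophied / erased).

Everything derives from a single seed; identical configs give
byte-identical files.
"""

from __future__ import annotations

import dataclasses
import os
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import pysam
import yaml

from .annotation_io import (
    DesignTable,
    GeneModel,
    Interval,
    RegionSet,
    TEInstance,
    write_design,
    write_tsv,
)

# condition panel emulating a naive-to-primed culture series; methylation
# defaults sit at the midpoints of the per-condition ranges the study
# design targets (hypomethylated 2i/L through hypermethylated S/L_KD)
DEFAULT_CONDITIONS = ("2i/L", "2i/L_K", "Pd/L", "Ch/L", "S/L", "S/L_KD")
DEFAULT_METHYLATION = (0.27, 0.30, 0.57, 0.72, 0.77, 0.80)
DEFAULT_IMPRINT = (0.25, 0.05, 0.50, 0.50, 0.50, 0.50)  # atrophied, erased, maintained...

TE_FAMILY_STEMS = (
    "MERVL-int", "MT2_Mm", "IAPEy-int", "IAPLTR3", "RLTR12C", "LTRIS2",
    "ETnERV2", "RMER16", "LTR9", "L1Md_T", "L1M3d", "B1_Mus", "MTA_Mm",
)


@dataclass
class SimulationConfig:
    n_chroms: int = 2
    chrom_length: int = 1_000_000
    conditions: tuple[str, ...] = DEFAULT_CONDITIONS
    replicates_per_condition: int = 3
    n_genes: int = 200
    n_te_instances: int = 300
    n_families: int = 50
    n_planted_chimeras: int = 30
    n_adversarial_chimeras: int = 5
    n_decoy_junctions: int = 300
    n_planted_de_genes: int = 40
    n_gradient_genes: int = 40
    de_log2fc: float = 3.0
    gradient_log2_step: float = 1.0
    nb_dispersion: float = 0.1
    library_size: int = 30_000
    read_length: int = 80
    chimera_support: int = 5
    decoy_support: int = 3
    te_multimap_fraction: float = 0.2
    chimera_window: int = 10_000
    adversarial_factor: float = 1.5  # adversarial TE distance = factor * window
    n_activated_families: int = 10
    te_activation_log2fc: float = 3.0
    methylation_levels: tuple[float, ...] = DEFAULT_METHYLATION
    imprint_levels: tuple[float, ...] = DEFAULT_IMPRINT
    n_imprints: int = 8
    n_te_origin_lncrnas: int = 10
    n_enhancers: int = 20
    cpg_coverage_mean: float = 2.0
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.methylation_levels) != len(self.conditions):
            raise ValueError("methylation_levels must match conditions")
        if len(self.imprint_levels) != len(self.conditions):
            raise ValueError("imprint_levels must match conditions")
        for v in (*self.methylation_levels, *self.imprint_levels, self.te_multimap_fraction):
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"fraction {v} outside [0,1]")
        if self.n_planted_chimeras + self.n_adversarial_chimeras > self.n_genes:
            raise ValueError("more planted chimeras than genes")
        if self.n_planted_de_genes + self.n_gradient_genes > self.n_genes:
            raise ValueError("more planted DE + gradient genes than genes")
        for name in ("n_genes", "n_te_instances", "n_families", "library_size"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be >= 0")

    @property
    def n_conditions(self) -> int:
        return len(self.conditions)

    @property
    def sample_ids(self) -> list[str]:
        out = []
        for cond in self.conditions:
            tag = cond.replace("/", "")
            for r in range(1, self.replicates_per_condition + 1):
                out.append(f"{tag}_r{r}")
        return out

    def design(self) -> DesignTable:
        rows = []
        for cond in self.conditions:
            tag = cond.replace("/", "")
            for r in range(1, self.replicates_per_condition + 1):
                rows.append(
                    {"sample_id": f"{tag}_r{r}", "condition": cond,
                     "background": "129", "replicate": r}
                )
        return DesignTable(pd.DataFrame(rows))

    def to_yaml(self, path: str) -> None:
        d = dataclasses.asdict(self)
        for k, v in d.items():
            if isinstance(v, tuple):
                d[k] = list(v)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str) -> "SimulationConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        for k in ("conditions", "methylation_levels", "imprint_levels"):
            if k in d:
                d[k] = tuple(d[k])
        return cls(**d)


@dataclass
class PlantedChimera:
    te_instance_id: str
    gene_id: str
    chrom: str
    intron: Interval
    donor_pos: int
    acceptor_pos: int
    active_conditions: tuple[str, ...]
    adversarial: bool = False


@dataclass
class SimulationTruth:
    """Ground truth for every planted signal."""

    gene_means: pd.DataFrame  # genes x conditions, expected counts
    family_means: pd.DataFrame  # families x conditions
    chimeras: list[PlantedChimera]
    de_genes: pd.DataFrame  # gene_id, condition, log2fc
    gradient_genes: list[str]
    te_origin_lncrnas: list[str]
    methylation_levels: dict[str, float]
    imprint_levels: dict[str, float]
    imprint_regions: RegionSet
    spectrum_order: list[str]

    @property
    def planted_chimeras(self) -> list[PlantedChimera]:
        return [c for c in self.chimeras if not c.adversarial]

    @property
    def adversarial_chimeras(self) -> list[PlantedChimera]:
        return [c for c in self.chimeras if c.adversarial]


@dataclass
class Annotations:
    genome: dict[str, np.ndarray]  # chrom -> uint8 array of ASCII bases
    genes: list[GeneModel]
    tes: list[TEInstance]
    regions: dict[str, RegionSet]

    def sequence(self, chrom: str, start: int, end: int) -> str:
        return self.genome[chrom][start:end].tobytes().decode()


# ---------------------------------------------------------------------------
# annotation generation


def _random_sequence(rng: np.random.Generator, length: int) -> np.ndarray:
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=length)


_EXON_LEN = 300
_INTRON_LEN = 700
_N_EXONS = 3
_TE_LEN_RANGE = (250, 600)
_CHIMERA_TE_LEN = 400
_GENE_SPAN = _N_EXONS * _EXON_LEN + (_N_EXONS - 1) * _INTRON_LEN


def _build_gene(gene_id: str, chrom: str, strand: str, start: int,
                biotype: str) -> GeneModel:
    exons = []
    pos = start
    for _ in range(_N_EXONS):
        exons.append(Interval(pos, pos + _EXON_LEN))
        pos += _EXON_LEN + _INTRON_LEN
    return GeneModel(gene_id, chrom, strand, exons, biotype=biotype)


def simulate_annotations(config: SimulationConfig) -> tuple[Annotations, SimulationTruth]:
    """Build the genome, gene models, TE instances and region sets, and the
    planted truth that the read/CpG simulators then realize."""
    root = np.random.SeedSequence(config.seed)
    rng_genome, rng_layout, rng_expr = (
        np.random.default_rng(s) for s in root.spawn(3)
    )

    chroms = [f"chr{i + 1}" for i in range(config.n_chroms)]
    genome = {c: _random_sequence(rng_genome, config.chrom_length) for c in chroms}

    # --- gene layout: sequential slots in the first 85% of each chromosome;
    # chimera target genes get a TE planted in their upstream reserve
    n_special = config.n_planted_chimeras + config.n_adversarial_chimeras
    genes: list[GeneModel] = []
    tes: list[TEInstance] = []
    chimeras: list[PlantedChimera] = []
    fam_counter: dict[str, int] = {}

    families = [
        TE_FAMILY_STEMS[i] if i < len(TE_FAMILY_STEMS) else f"SynTE{i}"
        for i in range(config.n_families)
    ]
    class_cycle = ["LTR", "LTR", "LTR", "LINE", "SINE", "DNA"]
    fam_class = {f: class_cycle[i % len(class_cycle)] for i, f in enumerate(families)}

    def add_te(family: str, chrom: str, start: int, end: int, strand: str) -> TEInstance:
        n = fam_counter.get(family, 0)
        fam_counter[family] = n + 1
        te = TEInstance(f"{family}.{n}", family, fam_class[family],
                        chrom, Interval(start, end), strand)
        tes.append(te)
        return te

    adv_dist = int(config.adversarial_factor * config.chimera_window)
    genes_per_chrom = [config.n_genes // config.n_chroms] * config.n_chroms
    genes_per_chrom[0] += config.n_genes % config.n_chroms
    gene_zone_end = int(config.chrom_length * 0.85)

    gi = 0
    for ci, chrom in enumerate(chroms):
        cursor = 1000
        for _ in range(genes_per_chrom[ci]):
            special = gi < n_special
            adversarial = config.n_planted_chimeras <= gi < n_special
            upstream = (adv_dist + _CHIMERA_TE_LEN + 500) if adversarial else 3500
            downstream = 600
            strand = "+" if rng_layout.random() < 0.5 else "-"
            slot = upstream + _GENE_SPAN + downstream
            if cursor + slot > gene_zone_end:
                raise ValueError("gene layout exceeds chromosome; enlarge chrom_length")
            if strand == "+":
                gstart = cursor + upstream
            else:
                gstart = cursor + downstream
            gene = _build_gene(f"gene{gi:04d}", chrom, strand, gstart,
                               biotype="lncRNA" if gi % 10 == 9 else "coding")
            genes.append(gene)

            if special:
                dist = adv_dist if adversarial else int(500 + rng_layout.integers(0, 2000))
                fam = families[gi % min(config.n_families, len(families))]
                if strand == "+":
                    te_end = gene.first_exon.start - dist
                    te = add_te(fam, chrom, te_end - _CHIMERA_TE_LEN, te_end, strand)
                    donor = te_end - 50
                    acceptor = sorted(gene.acceptor_sites)[0]  # exon 2 start
                    intron = Interval(donor + 1, acceptor)
                else:
                    te_start = gene.first_exon.end + dist
                    te = add_te(fam, chrom, te_start, te_start + _CHIMERA_TE_LEN, strand)
                    donor = te_start + 49
                    acceptor = sorted(gene.acceptor_sites)[-1]  # exon 2 end-1
                    intron = Interval(acceptor + 1, donor)
                pattern = gi % 3
                if pattern == 0:
                    active = config.conditions  # ubiquitous
                elif pattern == 1:
                    active = (config.conditions[gi % config.n_conditions],)
                else:
                    active = config.conditions[: max(2, config.n_conditions // 2)]
                chimeras.append(
                    PlantedChimera(te.instance_id, gene.gene_id, chrom, intron,
                                   donor, acceptor, tuple(active), adversarial)
                )
            cursor += slot
            gi += 1

    # --- remaining TEs, enhancers and imprints in the tail zone
    for ci, chrom in enumerate(chroms):
        cursor = gene_zone_end + 500
        n_tail_tes = (config.n_te_instances - len(tes)) // (config.n_chroms - ci)
        for k in range(n_tail_tes):
            length = int(rng_layout.integers(*_TE_LEN_RANGE))
            gap = int(rng_layout.integers(20, 120))
            if cursor + length + gap > config.chrom_length - 40_000:
                break
            fam = families[int(rng_layout.integers(0, config.n_families))]
            strand = "+" if rng_layout.random() < 0.5 else "-"
            add_te(fam, chrom, cursor, cursor + length, strand)
            cursor += length + gap

    # --- TE-origin lncRNAs: a TE overlapping the TSS of lncRNA genes that
    # are not chimera targets (transcripts originating inside a repeat)
    te_origin_lncrnas: list[str] = []
    n_wanted = config.n_te_origin_lncrnas
    for gidx, g in enumerate(genes):
        if len(te_origin_lncrnas) >= n_wanted:
            break
        if g.biotype != "lncRNA" or gidx < n_special:
            continue
        fam = families[gidx % config.n_families]
        if g.strand == "+":
            add_te(fam, g.chrom, g.first_exon.start - 300, g.first_exon.start + 20, g.strand)
        else:
            add_te(fam, g.chrom, g.first_exon.end - 20, g.first_exon.end + 300, g.strand)
        te_origin_lncrnas.append(g.gene_id)

    enhancers, imprints = [], []
    for ci, chrom in enumerate(chroms):
        cursor = config.chrom_length - 38_000
        for k in range(config.n_enhancers // config.n_chroms):
            enhancers.append((chrom, Interval(cursor, cursor + 500), f"enh_{chrom}_{k}"))
            cursor += 800
        for k in range(config.n_imprints // config.n_chroms):
            imprints.append((chrom, Interval(cursor, cursor + 1500), f"imprint_{chrom}_{k}"))
            cursor += 2000

    promoters = []
    for g in genes:
        if g.strand == "+":
            iv = Interval(max(g.first_exon.start - 500, 0), g.first_exon.start)
        else:
            iv = Interval(g.first_exon.end, g.first_exon.end + 500)
        promoters.append((g.chrom, iv, f"prom_{g.gene_id}"))

    regions = {
        "promoters": RegionSet("promoters", promoters),
        "enhancers": RegionSet("enhancers", enhancers),
        "imprints": RegionSet("imprints", imprints),
        "repeats": RegionSet(
            "repeats", [(t.chrom, t.interval, t.instance_id) for t in tes]
        ),
    }

    truth = _build_expression_truth(config, genes, families, chimeras, rng_expr,
                                    regions["imprints"])
    truth.te_origin_lncrnas = te_origin_lncrnas
    return Annotations(genome, genes, tes, regions), truth


def _build_expression_truth(
    config: SimulationConfig,
    genes: list[GeneModel],
    families: list[str],
    chimeras: list[PlantedChimera],
    rng: np.random.Generator,
    imprint_regions: RegionSet,
) -> SimulationTruth:
    conds = list(config.conditions)
    gene_ids = [g.gene_id for g in genes]

    # gradient and DE genes are drawn from genes without planted chimeras so
    # chimeric junction reads never confound the expression truth
    chimera_gene_ids = {c.gene_id for c in chimeras}
    free = [g for g in gene_ids if g not in chimera_gene_ids]
    gradient_genes = free[: config.n_gradient_genes]
    de_genes = free[config.n_gradient_genes:
                    config.n_gradient_genes + config.n_planted_de_genes]

    weights = rng.lognormal(mean=0.0, sigma=1.0, size=len(gene_ids))
    w = pd.Series(weights, index=gene_ids)
    w[gradient_genes] = 2.0
    w[de_genes] = 2.0

    base = np.tile(w.to_numpy()[:, None], (1, len(conds)))
    centered = np.arange(len(conds)) - (len(conds) - 1) / 2
    for i, gid in enumerate(gradient_genes):
        direction = 1.0 if i % 2 == 0 else -1.0
        base[gene_ids.index(gid)] *= 2.0 ** (direction * config.gradient_log2_step * centered)
    de_rows = []
    for i, gid in enumerate(de_genes):
        cond = conds[i % len(conds)]
        base[gene_ids.index(gid), conds.index(cond)] *= 2.0**config.de_log2fc
        de_rows.append({"gene_id": gid, "condition": cond, "log2fc": config.de_log2fc})

    gene_budget = 0.7 * config.library_size
    col_sums = base.sum(axis=0)
    gene_means = pd.DataFrame(
        base / col_sums * gene_budget if config.library_size > 0 else base * 0.0,
        index=gene_ids, columns=conds,
    )

    fam_w = rng.lognormal(mean=0.0, sigma=0.8, size=len(families))
    fam_base = np.tile(fam_w[:, None], (1, len(conds)))
    activated = families[: config.n_activated_families]
    # activated families fire in the naive (hypomethylated) half of the panel
    naive = conds[: max(1, len(conds) // 2)]
    for fam in activated:
        for c in naive:
            fam_base[families.index(fam), conds.index(c)] *= 2.0**config.te_activation_log2fc
    te_budget = 0.25 * config.library_size
    fam_sums = fam_base.sum(axis=0)
    family_means = pd.DataFrame(
        fam_base / fam_sums * te_budget if config.library_size > 0 else fam_base * 0.0,
        index=families, columns=conds,
    )

    meth = dict(zip(conds, config.methylation_levels))
    imprint = dict(zip(conds, config.imprint_levels))
    spectrum = [c for _, c in sorted(zip(config.methylation_levels, conds))]

    return SimulationTruth(
        gene_means=gene_means,
        family_means=family_means,
        chimeras=chimeras,
        de_genes=pd.DataFrame(de_rows, columns=["gene_id", "condition", "log2fc"]),
        gradient_genes=list(gradient_genes),
        te_origin_lncrnas=[],
        methylation_levels=meth,
        imprint_levels=imprint,
        imprint_regions=imprint_regions,
        spectrum_order=spectrum,
    )


# ---------------------------------------------------------------------------
# file writers


def write_genome_fasta(ann: Annotations, path: str, width: int = 70) -> None:
    with open(path, "w") as fh:
        for chrom, seq in ann.genome.items():
            fh.write(f">{chrom}\n")
            raw = seq.tobytes().decode()
            for i in range(0, len(raw), width):
                fh.write(raw[i : i + width] + "\n")


def write_gtf(ann: Annotations, path: str) -> None:
    with open(path, "w") as fh:
        for g in ann.genes:
            for n, e in enumerate(g.exons, start=1):
                attrs = (
                    f'gene_id "{g.gene_id}"; transcript_id "{g.gene_id}.t1"; '
                    f'exon_number "{n}"; gene_biotype "{g.biotype}";'
                )
                fh.write(
                    f"{g.chrom}\tsim\texon\t{e.start + 1}\t{e.end}\t.\t{g.strand}\t.\t{attrs}\n"
                )


def write_te_bed(ann: Annotations, path: str) -> None:
    with open(path, "w") as fh:
        for t in ann.tes:
            fh.write(
                f"{t.chrom}\t{t.interval.start}\t{t.interval.end}\t"
                f"{t.family}#{t.te_class}\t0\t{t.strand}\n"
            )


def write_region_beds(ann: Annotations, outdir: str) -> dict[str, str]:
    paths = {}
    for name, rs in ann.regions.items():
        path = os.path.join(outdir, f"{name}.bed")
        with open(path, "w") as fh:
            for chrom, iv, label in rs.regions:
                fh.write(f"{chrom}\t{iv.start}\t{iv.end}\t{label}\n")
        paths[name] = path
    return paths


# ---------------------------------------------------------------------------
# RNA-seq simulation


def _nb_counts(rng: np.random.Generator, mean: np.ndarray, dispersion: float) -> np.ndarray:
    mean = np.asarray(mean, dtype=float)
    if dispersion <= 0:
        return rng.poisson(mean)
    r = 1.0 / dispersion
    p = r / (r + np.maximum(mean, 1e-12))
    return np.where(mean > 0, rng.negative_binomial(r, p), 0)


def _header(config: SimulationConfig) -> dict:
    return {
        "HD": {"VN": "1.6", "SO": "unsorted"},
        "SQ": [
            {"SN": f"chr{i + 1}", "LN": config.chrom_length}
            for i in range(config.n_chroms)
        ],
    }


def _make_read(header, name, chrom, pos, cigar, seq, nh=1, xs=None, secondary=False):
    a = pysam.AlignedSegment(header=header)
    a.query_name = name
    a.reference_name = chrom
    a.reference_start = pos
    a.cigarstring = cigar
    a.mapping_quality = 255
    a.flag = 0
    if secondary:
        a.flag |= 256
        a.query_sequence = None
    else:
        a.query_sequence = seq
    tags = [("NH", nh)]
    if xs is not None:
        tags.append(("XS", xs))
    a.set_tags(tags)
    return a


def simulate_rnaseq(
    config: SimulationConfig,
    ann: Annotations,
    truth: SimulationTruth,
    outdir: str,
    dispersion_override: float | None = None,
) -> dict[str, str]:
    """Write one SAM file per sample; returns sample_id -> path.

    Per-gene and per-family counts are NB around the planted condition
    means (Poisson when dispersion is 0); chimeric and decoy junction reads
    are written at fixed support with M..N..M CIGARs spanning the planted
    introns exactly.
    """
    os.makedirs(outdir, exist_ok=True)
    design = config.design()
    dispersion = config.nb_dispersion if dispersion_override is None else dispersion_override
    rl = config.read_length
    header = pysam.AlignmentHeader.from_dict(_header(config))

    genes_by_id = {g.gene_id: g for g in ann.genes}
    fam_instances: dict[str, list[TEInstance]] = {}
    for t in ann.tes:
        fam_instances.setdefault(t.family, []).append(t)

    root = np.random.SeedSequence(config.seed).spawn(4)[3]
    sample_seeds = root.spawn(len(design.sample_ids))
    paths: dict[str, str] = {}

    for si, sample_id in enumerate(design.sample_ids):
        cond = design.condition_of(sample_id)
        rng = np.random.default_rng(sample_seeds[si])
        path = os.path.join(outdir, f"{sample_id}.sam")
        paths[sample_id] = path
        serial = 0
        with pysam.AlignmentFile(path, "w", header=header) as out:
            if config.library_size == 0:
                continue
            # exonic gene reads
            gene_counts = _nb_counts(rng, truth.gene_means[cond].to_numpy(), dispersion)
            for g, n in zip(ann.genes, gene_counts):
                big = [e for e in g.exons if len(e) >= rl]
                if not big or n == 0:
                    continue
                exon_idx = rng.integers(0, len(big), size=n)
                for ei in exon_idx:
                    e = big[ei]
                    start = int(rng.integers(e.start, e.end - rl + 1))
                    seq = ann.sequence(g.chrom, start, start + rl)
                    out.write(
                        _make_read(header, f"{sample_id}.g{serial}", g.chrom,
                                   start, f"{rl}M", seq)
                    )
                    serial += 1
            # TE family reads (with multimappers)
            fam_counts = _nb_counts(rng, truth.family_means[cond].to_numpy(), dispersion)
            for fam, n in zip(truth.family_means.index, fam_counts):
                insts = [t for t in fam_instances.get(fam, []) if len(t.interval) >= rl]
                if not insts or n == 0:
                    continue
                for _ in range(n):
                    t = insts[int(rng.integers(0, len(insts)))]
                    start = int(
                        rng.integers(t.interval.start, t.interval.end - rl + 1)
                    )
                    seq = ann.sequence(t.chrom, start, start + rl)
                    name = f"{sample_id}.t{serial}"
                    serial += 1
                    multimap = (
                        len(insts) >= 2 and rng.random() < config.te_multimap_fraction
                    )
                    if not multimap:
                        out.write(_make_read(header, name, t.chrom, start, f"{rl}M", seq))
                        continue
                    others = [o for o in insts if o.instance_id != t.instance_id]
                    o = others[int(rng.integers(0, len(others)))]
                    ostart = int(
                        rng.integers(o.interval.start, o.interval.end - rl + 1)
                    )
                    out.write(_make_read(header, name, t.chrom, start, f"{rl}M", seq, nh=2))
                    out.write(
                        _make_read(header, name, o.chrom, ostart, f"{rl}M", seq,
                                   nh=2, secondary=True)
                    )
            # chimeric junction reads (planted and adversarial)
            half = rl // 2
            for chi in truth.chimeras:
                if cond not in chi.active_conditions:
                    continue
                gene = genes_by_id[chi.gene_id]
                s, e = chi.intron.start, chi.intron.end
                left = ann.sequence(chi.chrom, s - half, s)
                right = ann.sequence(chi.chrom, e, e + (rl - half))
                cigar = f"{half}M{e - s}N{rl - half}M"
                for k in range(config.chimera_support):
                    out.write(
                        _make_read(header, f"{sample_id}.c{serial}", chi.chrom,
                                   s - half, cigar, left + right, xs=gene.strand)
                    )
                    serial += 1
            # decoy junctions: ordinary splicing across annotated gene introns
            decoys = _decoy_introns(ann, config.n_decoy_junctions)
            for chrom, s, e, strand in decoys:
                left = ann.sequence(chrom, s - half, s)
                right = ann.sequence(chrom, e, e + (rl - half))
                cigar = f"{half}M{e - s}N{rl - half}M"
                for k in range(config.decoy_support):
                    out.write(
                        _make_read(header, f"{sample_id}.d{serial}", chrom,
                                   s - half, cigar, left + right, xs=strand)
                    )
                    serial += 1
    return paths


def _decoy_introns(ann: Annotations, n: int) -> list[tuple[str, int, int, str]]:
    out = []
    for g in ann.genes:
        for a, b in zip(g.exons, g.exons[1:]):
            out.append((g.chrom, a.end, b.start, g.strand))
    return out[:n]


# ---------------------------------------------------------------------------
# WGBS simulation


def cpg_positions(ann: Annotations) -> dict[str, np.ndarray]:
    """0-based positions of the C of every CpG dinucleotide on the + strand."""
    out = {}
    for chrom, seq in ann.genome.items():
        is_c = seq[:-1] == ord("C")
        is_g = seq[1:] == ord("G")
        out[chrom] = np.nonzero(is_c & is_g)[0]
    return out


def simulate_wgbs(
    config: SimulationConfig,
    ann: Annotations,
    truth: SimulationTruth,
    outdir: str,
) -> dict[str, str]:
    """Write a per-sample CpG report (chrom, pos, meth_count, total_count).

    Coverage is Poisson around ``cpg_coverage_mean``; methylated calls are
    binomial at the condition's global level, overridden inside imprint
    regions by the condition's imprint level.
    """
    os.makedirs(outdir, exist_ok=True)
    design = config.design()
    positions = cpg_positions(ann)
    imprint_mask = {}
    for chrom, pos in positions.items():
        mask = np.zeros(len(pos), dtype=bool)
        for rchrom, iv, _ in truth.imprint_regions.regions:
            if rchrom == chrom:
                mask |= (pos >= iv.start) & (pos < iv.end)
        imprint_mask[chrom] = mask

    root = np.random.SeedSequence(config.seed).spawn(5)[4]
    sample_seeds = root.spawn(len(design.sample_ids))
    paths = {}
    for si, sample_id in enumerate(design.sample_ids):
        cond = design.condition_of(sample_id)
        rng = np.random.default_rng(sample_seeds[si])
        glevel = truth.methylation_levels[cond]
        ilevel = truth.imprint_levels[cond]
        path = os.path.join(outdir, f"{sample_id}.cpg.tsv")
        paths[sample_id] = path
        with open(path, "w") as fh:
            fh.write("#chrom\tpos\tmeth_count\ttotal_count\n")
            for chrom in sorted(positions):
                pos = positions[chrom]
                cov = rng.poisson(config.cpg_coverage_mean, size=len(pos))
                level = np.where(imprint_mask[chrom], ilevel, glevel)
                meth = rng.binomial(cov, level)
                frame = pd.DataFrame(
                    {"chrom": chrom, "pos": pos, "meth": meth, "total": cov}
                )
                frame.to_csv(fh, sep="\t", header=False, index=False)
    return paths


# ---------------------------------------------------------------------------
# one-stop generation


def write_truth_tables(truth: SimulationTruth, outdir: str) -> None:
    os.makedirs(outdir, exist_ok=True)
    write_tsv(truth.gene_means.reset_index(names="gene_id"),
              os.path.join(outdir, "truth.gene_means.tsv"))
    write_tsv(truth.family_means.reset_index(names="family"),
              os.path.join(outdir, "truth.family_means.tsv"))
    rows = [
        {
            "te_instance_id": c.te_instance_id, "gene_id": c.gene_id,
            "chrom": c.chrom, "intron_start": c.intron.start,
            "intron_end": c.intron.end, "donor_pos": c.donor_pos,
            "acceptor_pos": c.acceptor_pos,
            "active_conditions": ",".join(c.active_conditions),
            "adversarial": c.adversarial,
        }
        for c in truth.chimeras
    ]
    write_tsv(pd.DataFrame(rows), os.path.join(outdir, "truth.chimeras.tsv"))
    write_tsv(truth.de_genes, os.path.join(outdir, "truth.de_genes.tsv"))
    meth = pd.DataFrame(
        {
            "condition": list(truth.methylation_levels),
            "global_level": list(truth.methylation_levels.values()),
            "imprint_level": [truth.imprint_levels[c] for c in truth.methylation_levels],
        }
    )
    write_tsv(meth, os.path.join(outdir, "truth.methylation.tsv"))
    write_tsv(pd.DataFrame({"spectrum_order": truth.spectrum_order}),
              os.path.join(outdir, "truth.spectrum_order.tsv"))


def simulate_all(config: SimulationConfig, outdir: str) -> tuple[Annotations, SimulationTruth, dict]:
    """Generate the complete dataset under ``outdir``; returns annotations,
    truth, and a path manifest."""
    os.makedirs(outdir, exist_ok=True)
    ann, truth = simulate_annotations(config)
    paths: dict = {}
    paths["genome"] = os.path.join(outdir, "genome.fa")
    write_genome_fasta(ann, paths["genome"])
    paths["gtf"] = os.path.join(outdir, "genes.gtf")
    write_gtf(ann, paths["gtf"])
    paths["te_bed"] = os.path.join(outdir, "tes.bed")
    write_te_bed(ann, paths["te_bed"])
    paths["regions"] = write_region_beds(ann, outdir)
    paths["design"] = os.path.join(outdir, "design.tsv")
    write_design(config.design(), paths["design"])
    paths["sam"] = simulate_rnaseq(config, ann, truth, os.path.join(outdir, "rnaseq"))
    paths["cpg"] = simulate_wgbs(config, ann, truth, os.path.join(outdir, "wgbs"))
    write_truth_tables(truth, os.path.join(outdir, "truth"))
    config.to_yaml(os.path.join(outdir, "config.yaml"))
    return ann, truth, paths
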