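"""Splice-junction extraction and TE-to-gene chimeric transcript calling.

A chimeric transcript is an mRNA initiated inside a transposable element
that splices into the exons of a downstream annotated gene.  The observable
is a splice junction whose donor (the last exonic base 5' of the intron in
gene orientation) falls inside a TE instance lying upstream of the gene's
first annotated exon, and whose acceptor coincides with an annotated splice
acceptor of the gene.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import pandas as pd
import pysam

from .annotation_io import (
    DesignTable,
    GeneModel,
    GenomeIndex,
    Interval,
    TEInstance,
    build_interval_index,
    write_tsv,
)

log = logging.getLogger(__name__)

_CIGAR_N = 3
_REF_CONSUMING = {0, 2, 3, 7, 8}  # M, D, N, =, X


@dataclass
class SpliceJunction:
    """An intron inferred from spliced alignments.

    ``intron`` covers the skipped reference bases (0-based half-open).
    ``support`` maps sample_id to the number of primary alignments spanning
    the junction.
    """

    chrom: str
    intron: Interval
    strand: str = "?"
    support: dict[str, int] = field(default_factory=dict)

    @property
    def total_support(self) -> int:
        return sum(self.support.values())


@dataclass
class ChimericParams:
    """Tunable rule parameters for the chimeric caller.

    ``window`` bounds the distance (bp, gene orientation) from the TE's
    gene-proximal edge to the 5' edge of the gene's first exon.  TE strand
    matching is off by default because LTR promoters can fire antisense to
    the element.
    """

    window: int = 10_000
    min_support: int = 2
    min_samples: int = 1
    require_gene_strand_match: bool = True
    require_te_strand_match: bool = False
    acceptor_tolerance: int = 0


@dataclass
class ChimericCall:
    te_instance_id: str
    te_family: str
    gene_id: str
    junction: SpliceJunction
    donor_pos: int
    acceptor_pos: int
    te_gene_distance: int
    condition_support: dict[str, int]
    active_conditions: frozenset[str]
    specificity: str


def _read_introns(aln: pysam.AlignedSegment) -> list[tuple[int, int]] | None:
    """Introns of one alignment from its CIGAR; None flags an alignment whose
    aligned portion starts or ends with an N (malformed for junction use)."""
    cig = aln.cigartuples or []
    core = [(op, ln) for op, ln in cig if op not in (4, 5)]  # drop soft/hard clips
    if not core:
        return []
    if core[0][0] == _CIGAR_N or core[-1][0] == _CIGAR_N:
        return None
    introns = []
    pos = aln.reference_start
    for op, ln in core:
        if op == _CIGAR_N:
            introns.append((pos, pos + ln))
        if op in _REF_CONSUMING:
            pos += ln
    return introns


def extract_junctions(sam_paths: Mapping[str, str]) -> list[SpliceJunction]:
    """Extract splice junctions from SAM files, one file per sample.

    Only primary alignments contribute support (multimappers would otherwise
    be double counted).  A read whose CIGAR holds k N operations contributes
    to k junctions.  Strand is taken from the XS tag when present.
    """
    table: dict[tuple[str, int, int], SpliceJunction] = {}
    for sample_id, path in sam_paths.items():
        with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
            for aln in sam:
                if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                    continue
                introns = _read_introns(aln)
                if introns is None:
                    log.warning(
                        "read %s: N operation at alignment edge; skipped", aln.query_name
                    )
                    continue
                if not introns:
                    continue
                chrom = aln.reference_name
                strand = "?"
                if aln.has_tag("XS"):
                    strand = aln.get_tag("XS")
                for s, e in introns:
                    key = (chrom, s, e)
                    jx = table.get(key)
                    if jx is None:
                        jx = SpliceJunction(chrom, Interval(s, e), strand)
                        table[key] = jx
                    elif jx.strand == "?" and strand != "?":
                        jx.strand = strand
                    jx.support[sample_id] = jx.support.get(sample_id, 0) + 1
    return [table[k] for k in sorted(table)]


def _acceptor_index(genes: Iterable[GeneModel]) -> dict[tuple[str, int], list[GeneModel]]:
    idx: dict[tuple[str, int], list[GeneModel]] = {}
    for g in genes:
        for pos in g.acceptor_sites:
            idx.setdefault((g.chrom, pos), []).append(g)
    return idx


def _classify_specificity(active: frozenset[str], all_conditions: list[str]) -> str:
    if len(active) == len(all_conditions):
        return "ubiquitous"
    if len(active) == 1:
        return "single-condition"
    return "restricted"


def call_chimeric(
    junctions: Iterable[SpliceJunction],
    genes: list[GeneModel],
    tes: list[TEInstance],
    design: DesignTable,
    params: ChimericParams | None = None,
) -> tuple[list[ChimericCall], dict[str, int]]:
    """Call TE-to-gene chimeric transcripts from splice junctions.

    A junction yields a call iff

    a. its donor base lies inside a TE instance,
    b. the donor is strictly upstream (gene orientation) of the gene's
       first annotated exon,
    c. the TE's gene-proximal edge lies within ``params.window`` bp of the
       first exon's 5' edge,
    d. its acceptor matches an annotated acceptor site of the gene
       (within ``acceptor_tolerance``, default exact), and
    e. at least ``min_samples`` samples support it with at least
       ``min_support`` reads each.

    Per-condition activity applies the same support rule within each
    condition's replicates.  Returns the calls and a skip log.
    """
    params = params or ChimericParams()
    known_chroms = {g.chrom for g in genes} | {t.chrom for t in tes}
    te_index: GenomeIndex = build_interval_index(tes)
    acceptors = _acceptor_index(genes)
    conditions = design.conditions
    sample_condition = {s: design.condition_of(s) for s in design.sample_ids}

    skip_log = {"unknown_chrom": 0, "no_acceptor_match": 0, "failed_rule": 0, "low_support": 0}
    calls: list[ChimericCall] = []

    for jx in junctions:
        if jx.chrom not in known_chroms:
            skip_log["unknown_chrom"] += 1
            continue

        candidate_genes: list[tuple[GeneModel, int, int]] = []
        for tol in range(-params.acceptor_tolerance, params.acceptor_tolerance + 1):
            # + gene: acceptor is the first base after the intron; - gene: last before
            for pos, donor in (
                (jx.intron.end + tol, jx.intron.start - 1),
                (jx.intron.start - 1 + tol, jx.intron.end),
            ):
                for g in acceptors.get((jx.chrom, pos), []):
                    expected_donor = jx.intron.start - 1 if g.strand == "+" else jx.intron.end
                    if donor == expected_donor:
                        candidate_genes.append((g, pos, donor))
        if not candidate_genes:
            skip_log["no_acceptor_match"] += 1
            continue

        matched = False
        for gene, acceptor_pos, donor_pos in candidate_genes:
            if (
                params.require_gene_strand_match
                and jx.strand != "?"
                and jx.strand != gene.strand
            ):
                continue
            hit_tes = [
                t
                for t in te_index.query_point(jx.chrom, donor_pos)
                if not params.require_te_strand_match or t.strand == gene.strand
            ]
            if not hit_tes:
                continue
            if gene.strand == "+":
                if donor_pos >= gene.first_exon.start:
                    continue
                hit_tes = [
                    t
                    for t in hit_tes
                    if max(gene.first_exon.start - t.interval.end, 0) <= params.window
                ]
                key = lambda t: max(gene.first_exon.start - t.interval.end, 0)
            else:
                if donor_pos <= gene.first_exon.end - 1:
                    continue
                hit_tes = [
                    t
                    for t in hit_tes
                    if max(t.interval.start - gene.first_exon.end, 0) <= params.window
                ]
                key = lambda t: max(t.interval.start - gene.first_exon.end, 0)
            if not hit_tes:
                continue
            te = min(hit_tes, key=key)  # gene-proximal instance

            n_passing = sum(1 for v in jx.support.values() if v >= params.min_support)
            if n_passing < params.min_samples:
                skip_log["low_support"] += 1
                matched = True
                continue

            cond_support: dict[str, int] = {c: 0 for c in conditions}
            cond_passing: dict[str, int] = {c: 0 for c in conditions}
            for s, v in jx.support.items():
                c = sample_condition[s]
                cond_support[c] += v
                if v >= params.min_support:
                    cond_passing[c] += 1
            active = frozenset(
                c for c in conditions if cond_passing[c] >= params.min_samples
            )
            calls.append(
                ChimericCall(
                    te_instance_id=te.instance_id,
                    te_family=te.family,
                    gene_id=gene.gene_id,
                    junction=jx,
                    donor_pos=donor_pos,
                    acceptor_pos=acceptor_pos,
                    te_gene_distance=key(te),
                    condition_support=cond_support,
                    active_conditions=active,
                    specificity=_classify_specificity(active, conditions),
                )
            )
            matched = True
        if not matched:
            skip_log["failed_rule"] += 1

    return calls, skip_log


def calls_to_frame(calls: list[ChimericCall]) -> pd.DataFrame:
    rows = []
    for c in calls:
        rows.append(
            {
                "te_instance_id": c.te_instance_id,
                "te_family": c.te_family,
                "gene_id": c.gene_id,
                "chrom": c.junction.chrom,
                "intron_start": c.junction.intron.start,
                "intron_end": c.junction.intron.end,
                "donor_pos": c.donor_pos,
                "acceptor_pos": c.acceptor_pos,
                "te_gene_distance": c.te_gene_distance,
                "total_support": c.junction.total_support,
                "active_conditions": ",".join(sorted(c.active_conditions)),
                "specificity": c.specificity,
            }
        )
    cols = [
        "te_instance_id", "te_family", "gene_id", "chrom", "intron_start",
        "intron_end", "donor_pos", "acceptor_pos", "te_gene_distance",
        "total_support", "active_conditions", "specificity",
    ]
    return pd.DataFrame(rows, columns=cols)


def condition_restriction_table(
    calls: list[ChimericCall], design: DesignTable
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-call activity table plus counts of calls per specificity class."""
    per_call = calls_to_frame(calls)
    for cond in design.conditions:
        per_call[f"support_{cond}"] = [c.condition_support.get(cond, 0) for c in calls]
    counts = (
        per_call.groupby("specificity").size().rename("n_calls").reset_index()
        if len(per_call)
        else pd.DataFrame(columns=["specificity", "n_calls"])
    )
    return per_call, counts


def write_junction_bed(junctions: list[SpliceJunction], path: str) -> None:
    """Write junction introns as BED6; score = total read support."""
    with open(path, "w") as fh:
        for jx in junctions:
            strand = jx.strand if jx.strand in "+-" else "."
            fh.write(
                f"{jx.chrom}\t{jx.intron.start}\t{jx.intron.end}\t"
                f"junction\t{jx.total_support}\t{strand}\n"
            )


def write_calls(calls: list[ChimericCall], design: DesignTable, path: str) -> None:
    per_call, _ = condition_restriction_table(calls, design)
    write_tsv(per_call, path)
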