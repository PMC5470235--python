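"""TE-family expression quantification with an explicit multimapper policy.

Reads are assigned at the family level (the unit the field reports for
repeats).  Two modes:

``unique``
    only primary alignments of uniquely mapping reads (NH=1, or no NH tag)
    are counted; each read goes to the family of the instance it overlaps
    most, and cross-family ties are discarded as ambiguous.

``fractional``
    every reported alignment (primary and secondary) contributes ``1/NH``
    to its best-overlap family, spreading multimapping TE reads across
    their reported loci.
"""

from __future__ import annotations

import logging
from typing import Mapping

import pandas as pd
import pysam

from .annotation_io import DesignTable, GenomeIndex, TEInstance, build_interval_index
from . import de as _de

log = logging.getLogger(__name__)


def _alignment_blocks(aln: pysam.AlignedSegment) -> list[tuple[int, int]]:
    return aln.get_blocks()


def _best_family(
    aln: pysam.AlignedSegment, index: GenomeIndex
) -> str | None:
    """Family of the TE instance with the largest block overlap; None when
    no overlap or the best overlap is tied between families."""
    blocks = _alignment_blocks(aln)
    if not blocks:
        return None
    overlap: dict[str, tuple[int, str]] = {}
    chrom = aln.reference_name
    for bs, be in blocks:
        for te in index.query(chrom, bs, be):
            ov = min(be, te.interval.end) - max(bs, te.interval.start)
            if ov > 0:
                prev = overlap.get(te.instance_id, (0, te.family))
                overlap[te.instance_id] = (prev[0] + ov, te.family)
    if not overlap:
        return None
    best = max(v[0] for v in overlap.values())
    best_families = {fam for ov, fam in overlap.values() if ov == best}
    if len(best_families) > 1:
        return None  # ambiguous between families
    return next(iter(best_families))


def count_te_families(
    sam_paths: Mapping[str, str],
    tes: list[TEInstance],
    mode: str = "unique",
) -> pd.DataFrame:
    """Count reads per TE family per sample (families x samples).

    All annotated families appear as rows, zero-filled.  In unique mode
    counts are integers; in fractional mode they are reals.
    """
    if mode not in ("unique", "fractional"):
        raise ValueError(f"mode must be 'unique' or 'fractional', got {mode!r}")
    index = build_interval_index(tes)
    families = sorted({t.family for t in tes})
    counts = pd.DataFrame(0.0, index=families, columns=list(sam_paths))
    n_ambiguous = 0
    for sample_id, path in sam_paths.items():
        with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
            for aln in sam:
                if aln.is_unmapped or aln.is_supplementary:
                    continue
                nh = aln.get_tag("NH") if aln.has_tag("NH") else None
                if mode == "unique":
                    if aln.is_secondary or (nh is not None and nh != 1):
                        continue
                    weight = 1.0
                else:
                    if nh is None:
                        raise ValueError(
                            f"{path}: read {aln.query_name} lacks NH tag; "
                            "fractional mode needs NH — use unique mode"
                        )
                    weight = 1.0 / nh
                fam = _best_family(aln, index)
                if fam is None:
                    if _alignment_blocks(aln):
                        n_ambiguous += 1
                    continue
                counts.at[fam, sample_id] += weight
    if n_ambiguous:
        log.info("%d alignments discarded (no TE overlap or ambiguous family)", n_ambiguous)
    if mode == "unique":
        counts = counts.astype(int)
    return counts


def differential_te(
    matrix: pd.DataFrame,
    design: DesignTable,
    contrast: tuple[str, str],
    alpha: float = 0.01,
    lfc_threshold: float = 2.0,
    gene_counts: pd.DataFrame | None = None,
    **kwargs,
) -> pd.DataFrame:
    """Differential family activity for one contrast (NB Wald engine).

    When ``gene_counts`` is given, size factors come from genes so that TE
    activation itself cannot distort normalization.
    """
    sf = _de.size_factors(gene_counts) if gene_counts is not None else None
    return _de.differential_expression(
        matrix,
        design,
        contrast,
        alpha=alpha,
        lfc_threshold=lfc_threshold,
        size_factors_override=sf,
        **kwargs,
    )


def all_pairs_differential_te(
    matrix: pd.DataFrame,
    design: DesignTable,
    alpha: float = 0.01,
    lfc_threshold: float = 2.0,
    gene_counts: pd.DataFrame | None = None,
    **kwargs,
) -> tuple[pd.DataFrame, set[str]]:
    sf = _de.size_factors(gene_counts) if gene_counts is not None else None
    return _de.all_pairs_de(
        matrix,
        design,
        alpha=alpha,
        lfc_threshold=lfc_threshold,
        size_factors_override=sf,
        **kwargs,
    )


def class_breakdown(de_results: pd.DataFrame, tes: list[TEInstance]) -> pd.DataFrame:
    """Per-TE-class summary of differential activity.

    A family counts as significant when flagged in at least one contrast of
    ``de_results``.  Returns per class: n_tested, n_significant, proportion
    of all significant families belonging to the class (0 with an n=0 flag
    when nothing is significant).
    """
    fam_class = {}
    for t in tes:
        fam_class.setdefault(t.family, t.te_class)
    tested = de_results["feature_id"].unique()
    sig = set(de_results.loc[de_results["significant"], "feature_id"])
    rows = []
    n_sig_total = len(sig)
    classes = sorted({fam_class.get(f, "other") for f in tested})
    for klass in classes:
        fams = [f for f in tested if fam_class.get(f, "other") == klass]
        n_sig = sum(1 for f in fams if f in sig)
        rows.append(
            {
                "te_class": klass,
                "n_tested": len(fams),
                "n_significant": n_sig,
                "proportion_of_significant": (n_sig / n_sig_total) if n_sig_total else 0.0,
            }
        )
    out = pd.DataFrame(rows, columns=["te_class", "n_tested", "n_significant", "proportion_of_significant"])
    out.attrs["n_significant_total"] = n_sig_total
    return out
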