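"""Gene-level quantification, pairwise DE, correlation clustering and PCA
spectrum ordering.

The central output is a 1-D ordering of culture conditions along the first
principal component of the gene expression matrix — the "pluripotent
spectrum" — anchored so that a user-named reference condition (the most
naive state) sits at negative PC1.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Mapping

import numpy as np
import pandas as pd
import pysam
from scipy.cluster import hierarchy
from scipy.spatial.distance import squareform

from .annotation_io import DesignTable, GeneModel, GenomeIndex, TEInstance, build_interval_index
from . import de as _de

log = logging.getLogger(__name__)


def count_genes(sam_paths: Mapping[str, str], genes: list[GeneModel]) -> pd.DataFrame:
    """Exon-overlap gene counts (genes x samples), unique reads only.

    A primary NH=1 alignment is counted to a gene when one of its aligned
    blocks overlaps any exon of that gene; reads touching exons of more
    than one gene are discarded as ambiguous.
    """
    index = build_interval_index(genes, interval_of=lambda g: g.span)
    ids = [g.gene_id for g in genes]
    counts = pd.DataFrame(0, index=ids, columns=list(sam_paths), dtype=int)
    for sample_id, path in sam_paths.items():
        with pysam.AlignmentFile(path, "r", check_sq=False) as sam:
            for aln in sam:
                if aln.is_unmapped or aln.is_secondary or aln.is_supplementary:
                    continue
                if aln.has_tag("NH") and aln.get_tag("NH") != 1:
                    continue
                hits = set()
                blocks = aln.get_blocks()
                for bs, be in blocks:
                    for g in index.query(aln.reference_name, bs, be):
                        if any(e.overlaps(bs, be) for e in g.exons):
                            hits.add(g.gene_id)
                if len(hits) == 1:
                    counts.at[hits.pop(), sample_id] += 1
    return counts


def differential_genes(
    matrix: pd.DataFrame,
    design: DesignTable,
    alpha: float = 0.01,
    lfc_threshold: float = 2.0,
    **kwargs,
) -> tuple[pd.DataFrame, set[str]]:
    """Pairwise NB Wald DE across every condition pair.

    BH adjustment is applied within each contrast; the union set collects
    genes significant (|log2FC| > threshold, adjusted p < alpha) in at
    least one pair — the "robust differential expression" set.
    """
    return _de.all_pairs_de(matrix, design, alpha=alpha, lfc_threshold=lfc_threshold, **kwargs)


def log_cpm(matrix: pd.DataFrame, pseudocount: float = 1.0) -> pd.DataFrame:
    """log2(CPM + pseudocount); columns with zero library size are rejected."""
    libsize = matrix.sum(axis=0)
    if (libsize <= 0).any():
        bad = list(libsize.index[libsize <= 0])
        raise ValueError(f"zero library size for samples: {bad}")
    return np.log2(matrix.div(libsize, axis=1) * 1e6 + pseudocount)


def _top_variable(logmat: pd.DataFrame, k: int) -> pd.DataFrame:
    if k > logmat.shape[0]:
        log.warning("k_var_genes=%d > %d available genes; clamping", k, logmat.shape[0])
        k = logmat.shape[0]
    var = logmat.var(axis=1)
    keep = var.sort_values(ascending=False, kind="stable").index[:k]
    return logmat.loc[keep]


def correlation_clusters(
    matrix: pd.DataFrame, k_var_genes: int = 2000
) -> tuple[pd.DataFrame, list[str]]:
    """Sample-sample Pearson correlation on log2(CPM+1) of the top variable
    genes, plus an average-linkage dendrogram leaf order.

    Samples are pre-sorted by id so that tied merges resolve
    deterministically.
    """
    if matrix.shape[1] < 2:
        raise ValueError("correlation requires at least 2 samples")
    logmat = _top_variable(log_cpm(matrix), k_var_genes)
    logmat = logmat[sorted(logmat.columns)]
    sd = logmat.std(axis=0)
    if (sd == 0).any():
        bad = list(sd.index[sd == 0])
        raise ValueError(f"zero-variance sample(s), correlation undefined: {bad}")
    corr = logmat.corr(method="pearson")
    dist = squareform(np.clip(1.0 - corr.to_numpy(), 0.0, None), checks=False)
    linkage = hierarchy.linkage(dist, method="average")
    order = [corr.columns[i] for i in hierarchy.leaves_list(linkage)]
    return corr, order


@dataclass
class PCAResult:
    """SVD-based PCA of log-expression (samples scored, genes loaded).

    ``sample_scores``: samples x components; ``feature_loadings``: genes x
    components with unit-norm columns; scores @ loadings.T reconstructs the
    gene-centered matrix.  ``sign_anchored`` records that PC1's sign was
    fixed by the reference condition.
    """

    sample_scores: pd.DataFrame
    feature_loadings: pd.DataFrame
    explained_variance_fraction: np.ndarray
    sign_anchored: bool

    def top_loadings(self, component: str = "PC1", n: int = 20) -> pd.Series:
        lo = self.feature_loadings[component]
        idx = lo.abs().sort_values(ascending=False, kind="stable").index[:n]
        return lo.loc[idx]


@dataclass
class SpectrumOrder:
    """Conditions ordered along PC1 (ascending mean score)."""

    conditions: list[str]
    mean_scores: pd.Series


def pca_spectrum(
    matrix: pd.DataFrame,
    design: DesignTable,
    k_var_genes: int = 2000,
    reference_condition: str | None = None,
) -> tuple[PCAResult, SpectrumOrder]:
    """PCA of log2(CPM+1) on the top variable genes, and the condition
    ordering along PC1.

    PC1's arbitrary SVD sign is fixed so the reference condition has a
    negative mean score (naive states at negative PC1); other components
    are anchored by making each one's largest-magnitude loading positive.
    """
    if matrix.shape[1] < 3:
        raise ValueError("PCA spectrum requires at least 3 samples")
    if reference_condition is None:
        reference_condition = design.conditions[0]
    if reference_condition not in design.conditions:
        raise ValueError(f"reference condition {reference_condition!r} not in design")

    logmat = _top_variable(log_cpm(matrix), k_var_genes)
    samples = list(logmat.columns)
    x = logmat.to_numpy().T  # samples x genes
    x = x - x.mean(axis=0, keepdims=True)  # center each gene
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    n_comp = len(s)
    comp_names = [f"PC{i + 1}" for i in range(n_comp)]

    scores = u * s  # samples x comps
    loadings = vt.T  # genes x comps, unit columns

    # deterministic sign convention
    for j in range(n_comp):
        anchor = np.argmax(np.abs(loadings[:, j]))
        if loadings[anchor, j] < 0:
            loadings[:, j] *= -1
            scores[:, j] *= -1
    ref_samples = [samples.index(sid) for sid in design.samples_of(reference_condition)
                   if sid in samples]
    if ref_samples and scores[ref_samples, 0].mean() > 0:
        scores[:, 0] *= -1
        loadings[:, 0] *= -1

    total = float((s**2).sum())
    evf = (s**2) / total if total > 0 else np.zeros(n_comp)

    result = PCAResult(
        sample_scores=pd.DataFrame(scores, index=samples, columns=comp_names),
        feature_loadings=pd.DataFrame(loadings, index=logmat.index, columns=comp_names),
        explained_variance_fraction=evf,
        sign_anchored=True,
    )
    pc1 = result.sample_scores["PC1"]
    cond_means = pd.Series(
        {c: pc1.loc[[s_ for s_ in design.samples_of(c) if s_ in pc1.index]].mean()
         for c in design.conditions}
    )
    ordered = list(cond_means.sort_values(kind="stable").index)
    return result, SpectrumOrder(ordered, cond_means)


def classify_te_origin(
    features: list[GeneModel], tes: list[TEInstance], window: int = 0
) -> pd.DataFrame:
    """Flag features whose TSS lies inside a TE instance or within
    ``window`` bp downstream (gene orientation) of one.

    Captures transcripts — notably lncRNAs — that originate at TEs.
    """
    index = build_interval_index(tes)
    rows = []
    for f in features:
        tss = f.tss
        te_hit = None
        for te in index.query(f.chrom, tss - window - 1, tss + window + 2):
            if te.interval.contains(tss):
                te_hit = te
                break
            if f.strand == "+":
                dist = tss - te.interval.end
            else:
                dist = te.interval.start - 1 - tss
            if 0 <= dist < window:
                te_hit = te
                break
        rows.append(
            {
                "feature_id": f.gene_id,
                "biotype": f.biotype,
                "tss": tss,
                "te_origin": te_hit is not None,
                "te_instance_id": te_hit.instance_id if te_hit else "",
                "te_family": te_hit.family if te_hit else "",
            }
        )
    return pd.DataFrame(rows)
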