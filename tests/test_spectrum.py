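"""Gene counting, correlation clustering, PCA spectrum and TE-origin flags."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from te_spectrum.annotation_io import DesignTable, GeneModel, Interval, TEInstance
from te_spectrum.expression_spectrum import (
    classify_te_origin,
    correlation_clusters,
    count_genes,
    differential_genes,
    log_cpm,
    pca_spectrum,
)

from conftest import write_sam

CHROMS = {"chr1": 100_000}


def _gene(gid, start, strand="+"):
    return GeneModel(
        gid, "chr1", strand,
        [Interval(start, start + 200), Interval(start + 500, start + 700)],
    )


class TestCountGenes:
    def test_exonic_reads_counted(self, tmp_path):
        g = _gene("g1", 1000)
        recs = [
            {"qname": f"r{i}", "chrom": "chr1", "pos": 1001 + i, "cigar": "50M",
             "tags": ["NH:i:1"]}
            for i in range(10)
        ]
        sam = write_sam(tmp_path / "s.sam", recs, CHROMS)
        counts = count_genes({"s": sam}, [g])
        assert counts.at["g1", "s"] == 10

    def test_read_overlapping_two_genes_discarded(self, tmp_path):
        a = GeneModel("gA", "chr1", "+", [Interval(1000, 1200)])
        b = GeneModel("gB", "chr1", "-", [Interval(1150, 1400)])
        sam = write_sam(
            tmp_path / "s.sam",
            [{"qname": "r", "chrom": "chr1", "pos": 1101, "cigar": "80M",
              "tags": ["NH:i:1"]}],
            CHROMS,
        )
        counts = count_genes({"s": sam}, [a, b])
        assert counts["s"].sum() == 0

    def test_intronic_read_not_counted(self, tmp_path):
        g = _gene("g1", 1000)  # intron [1200, 1500)
        sam = write_sam(
            tmp_path / "s.sam",
            [{"qname": "r", "chrom": "chr1", "pos": 1251, "cigar": "50M",
              "tags": ["NH:i:1"]}],
            CHROMS,
        )
        assert count_genes({"s": sam}, [g])["s"].sum() == 0

    def test_matches_brute_force_oracle(self, tmp_path):
        rng = np.random.default_rng(17)
        genes = [_gene(f"g{i}", 1000 + 900 * i) for i in range(20)]
        recs, meta = [], []
        for i in range(300):
            pos = int(rng.integers(500, 20_000))
            length = int(rng.integers(30, 120))
            recs.append({"qname": f"r{i}", "chrom": "chr1", "pos": pos,
                         "cigar": f"{length}M", "tags": ["NH:i:1"]})
            meta.append((pos - 1, pos - 1 + length))
        sam = write_sam(tmp_path / "rand.sam", recs, CHROMS)
        got = count_genes({"s": sam}, genes)["s"]
        expected = pd.Series(0, index=[g.gene_id for g in genes])
        for s, e in meta:
            hits = {g.gene_id for g in genes if any(x.overlaps(s, e) for x in g.exons)}
            if len(hits) == 1:
                expected[hits.pop()] += 1
        pd.testing.assert_series_equal(got, expected, check_names=False)


class TestDifferentialGenes:
    def test_duplicated_condition_yields_no_significant(self):
        rng = np.random.default_rng(2)
        counts = pd.DataFrame(
            rng.poisson(100, size=(300, 4)),
            columns=["a1", "a2", "b1", "b2"],
            index=[f"g{i}" for i in range(300)],
        )
        # two "conditions" that are exchangeable replicates of the same state
        design = DesignTable(pd.DataFrame(
            {"sample_id": ["a1", "a2", "b1", "b2"],
             "condition": ["X", "X", "Y", "Y"], "replicate": [1, 2, 1, 2]}
        ))
        _, union = differential_genes(counts, design)
        assert union == set()


class TestCorrelation:
    def _counts(self, seed=0, m=300):
        rng = np.random.default_rng(seed)
        mu = rng.lognormal(np.log(50), 1.0, m)
        block = np.ones(m)
        block[: m // 3] = 8.0
        cols = {}
        for i in range(3):
            cols[f"x{i}"] = rng.poisson(mu)
        for i in range(3):
            cols[f"y{i}"] = rng.poisson(mu * block)
        return pd.DataFrame(cols, index=[f"g{i}" for i in range(m)])

    def test_duplicated_sample_perfectly_correlated(self):
        counts = self._counts()
        counts["x0b"] = counts["x0"]
        corr, _ = correlation_clusters(counts, k_var_genes=300)
        assert corr.at["x0", "x0b"] == pytest.approx(1.0)

    def test_planted_blocks_split_at_root(self):
        corr, order = correlation_clusters(self._counts(), k_var_genes=300)
        half = len(order) // 2
        sides = {tuple(sorted(order[:half])), tuple(sorted(order[half:]))}
        assert sides == {("x0", "x1", "x2"), ("y0", "y1", "y2")}

    def test_zero_variance_sample_raises(self):
        counts = self._counts()
        counts["flat"] = 7
        with pytest.raises(ValueError, match="flat"):
            correlation_clusters(counts, k_var_genes=300)


def _gradient_counts(seed=0, n_cond=6, reps=2, m=300, n_drivers=40):
    """Counts with a log-linear expression gradient in a known driver set."""
    rng = np.random.default_rng(seed)
    mu = rng.lognormal(np.log(100), 0.3, m)
    centered = np.arange(n_cond) - (n_cond - 1) / 2
    cols, names, conds = [], [], []
    for ci in range(n_cond):
        mult = np.ones(m)
        mult[:n_drivers] = 2.0 ** (
            np.where(np.arange(n_drivers) % 2 == 0, 1.0, -1.0) * 1.2 * centered[ci]
        )
        for r in range(reps):
            cols.append(rng.poisson(mu * mult))
            names.append(f"c{ci}_r{r}")
            conds.append(f"cond{ci}")
    counts = pd.DataFrame(
        np.column_stack(cols), columns=names, index=[f"g{i}" for i in range(m)]
    )
    design = DesignTable(pd.DataFrame(
        {"sample_id": names, "condition": conds,
         "replicate": [int(n.split("_r")[1]) for n in names]}
    ))
    drivers = [f"g{i}" for i in range(n_drivers)]
    return counts, design, drivers


class TestPCASpectrum:
    def test_constant_matrix_gives_zero_scores(self):
        counts = pd.DataFrame(7, index=[f"g{i}" for i in range(10)],
                              columns=["s1", "s2", "s3"])
        design = DesignTable(pd.DataFrame(
            {"sample_id": ["s1", "s2", "s3"], "condition": ["A", "B", "C"],
             "replicate": [1, 1, 1]}
        ))
        pca, _ = pca_spectrum(counts, design, k_var_genes=10, reference_condition="A")
        assert np.allclose(pca.sample_scores.to_numpy(), 0.0)

    def test_planted_gradient_recovered_exactly(self):
        counts, design, drivers = _gradient_counts()
        pca, order = pca_spectrum(counts, design, k_var_genes=200,
                                  reference_condition="cond0")
        truth_rank = {c: i for i, c in enumerate(f"cond{i}" for i in range(6))}
        rho = stats.spearmanr(
            [truth_rank[c] for c in order.conditions], range(6)
        ).statistic
        assert abs(rho) == pytest.approx(1.0)
        # sign convention: reference condition sits at negative PC1
        assert order.mean_scores["cond0"] < 0
        assert rho == pytest.approx(1.0)

    def test_top_loadings_are_planted_drivers(self):
        counts, design, drivers = _gradient_counts()
        pca, _ = pca_spectrum(counts, design, k_var_genes=200,
                              reference_condition="cond0")
        top20 = set(pca.top_loadings("PC1", 20).index)
        assert len(top20 & set(drivers)) >= 18

    def test_svd_reconstruction(self):
        counts, design, _ = _gradient_counts()
        pca, _ = pca_spectrum(counts, design, k_var_genes=150,
                              reference_condition="cond0")
        logmat = log_cpm(counts)
        var = logmat.var(axis=1).sort_values(ascending=False, kind="stable")
        x = logmat.loc[var.index[:150]].to_numpy().T
        x = x - x.mean(axis=0, keepdims=True)
        recon = pca.sample_scores.to_numpy() @ pca.feature_loadings.to_numpy().T
        assert np.abs(recon - x).max() < 1e-8

    def test_sample_order_invariance(self):
        counts, design, _ = _gradient_counts()
        pca1, order1 = pca_spectrum(counts, design, k_var_genes=200,
                                    reference_condition="cond0")
        shuffled = counts[list(reversed(counts.columns))]
        pca2, order2 = pca_spectrum(shuffled, design, k_var_genes=200,
                                    reference_condition="cond0")
        assert order1.conditions == order2.conditions
        for s in counts.columns:
            assert pca1.sample_scores.at[s, "PC1"] == pytest.approx(
                pca2.sample_scores.at[s, "PC1"], abs=1e-8
            )

    def test_explained_variance_non_increasing(self):
        counts, design, _ = _gradient_counts()
        pca, _ = pca_spectrum(counts, design, k_var_genes=200,
                              reference_condition="cond0")
        evf = pca.explained_variance_fraction
        assert np.all(np.diff(evf) <= 1e-12)
        assert evf.sum() <= 1.0 + 1e-9


class TestTEOrigin:
    TE = TEInstance("te0", "MT2_Mm", "LTR", "chr1", Interval(3000, 3400), "+")

    def _feature(self, tss_exon_start):
        return GeneModel(
            "lnc1", "chr1", "+",
            [Interval(tss_exon_start, tss_exon_start + 100),
             Interval(tss_exon_start + 300, tss_exon_start + 400)],
        )

    def test_tss_inside_te(self):
        table = classify_te_origin([self._feature(3350)], [self.TE], window=0)
        assert table.loc[0, "te_origin"]
        assert table.loc[0, "te_family"] == "MT2_Mm"

    def test_tss_just_past_half_open_end(self):
        table = classify_te_origin([self._feature(3400)], [self.TE], window=0)
        assert not table.loc[0, "te_origin"]

    def test_tss_within_downstream_window(self):
        table = classify_te_origin([self._feature(3450)], [self.TE], window=100)
        assert table.loc[0, "te_origin"]
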