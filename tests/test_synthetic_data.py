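"""Generator contracts: determinism, planted geometry, count moments,
SAM validity and methylation stratification."""

import filecmp

import numpy as np
import pysam
import pytest

from te_spectrum.annotation_io import build_interval_index
from te_spectrum.methylome import read_cpg_report
from te_spectrum.synthetic_data import (
    SimulationConfig,
    _nb_counts,
    cpg_positions,
    simulate_all,
    simulate_annotations,
    simulate_rnaseq,
    simulate_wgbs,
)

from conftest import MINI_SIM

TINY = SimulationConfig(
    seed=3,
    library_size=1500,
    replicates_per_condition=1,
    n_te_instances=120,
    n_decoy_junctions=40,
    cpg_coverage_mean=0.5,
)


class TestDeterminism:
    def test_same_seed_byte_identical_outputs(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        simulate_all(TINY, str(d1))
        simulate_all(TINY, str(d2))
        for rel in ["genes.gtf", "tes.bed", "genome.fa", "design.tsv",
                    "rnaseq/2iL_r1.sam", "rnaseq/SL_KD_r1.sam",
                    "wgbs/2iL_r1.cpg.tsv"]:
            assert filecmp.cmp(d1 / rel, d2 / rel, shallow=False), rel

    def test_different_seed_differs(self, tmp_path):
        d1, d2 = tmp_path / "a", tmp_path / "b"
        import dataclasses

        simulate_all(TINY, str(d1))
        simulate_all(dataclasses.replace(TINY, seed=4), str(d2))
        assert not filecmp.cmp(d1 / "rnaseq/2iL_r1.sam", d2 / "rnaseq/2iL_r1.sam",
                               shallow=False)


class TestPlantedGeometry:
    def test_chimeras_satisfy_caller_rule_by_construction(self):
        ann, truth = simulate_annotations(MINI_SIM)
        genes = {g.gene_id: g for g in ann.genes}
        tes = {t.instance_id: t for t in ann.tes}
        for chi in truth.planted_chimeras:
            te, gene = tes[chi.te_instance_id], genes[chi.gene_id]
            assert te.interval.contains(chi.donor_pos)
            assert chi.acceptor_pos in gene.acceptor_sites
            if gene.strand == "+":
                assert chi.donor_pos < gene.first_exon.start
                dist = gene.first_exon.start - te.interval.end
            else:
                assert chi.donor_pos > gene.first_exon.end - 1
                dist = te.interval.start - gene.first_exon.end
            assert 0 <= dist <= MINI_SIM.chimera_window

    def test_adversarial_chimeras_beyond_window(self):
        ann, truth = simulate_annotations(MINI_SIM)
        genes = {g.gene_id: g for g in ann.genes}
        tes = {t.instance_id: t for t in ann.tes}
        assert truth.adversarial_chimeras
        for chi in truth.adversarial_chimeras:
            te, gene = tes[chi.te_instance_id], genes[chi.gene_id]
            if gene.strand == "+":
                dist = gene.first_exon.start - te.interval.end
            else:
                dist = te.interval.start - gene.first_exon.end
            assert dist > MINI_SIM.chimera_window

    def test_te_instances_do_not_overlap_each_other(self):
        ann, _ = simulate_annotations(MINI_SIM)
        idx = build_interval_index(ann.tes)
        for te in ann.tes:
            hits = idx.query(te.chrom, te.interval.start, te.interval.end)
            assert hits == [te]

    def test_config_validation(self):
        with pytest.raises(ValueError, match="chimeras"):
            SimulationConfig(n_genes=10, n_planted_chimeras=20,
                             n_planted_de_genes=0, n_gradient_genes=0)


class TestCountModel:
    def test_poisson_limit_at_zero_dispersion(self):
        rng = np.random.default_rng(0)
        draws = np.array([_nb_counts(rng, np.full(1000, 50.0), 0.0) for _ in range(1)])
        # variance ~ mean within 5% over 1,000 draws
        assert draws.var() == pytest.approx(draws.mean(), rel=0.05)

    def test_nb_moments(self):
        rng = np.random.default_rng(1)
        mu, disp = 80.0, 0.2
        draws = _nb_counts(rng, np.full(20_000, mu), disp)
        assert draws.mean() == pytest.approx(mu, rel=0.02)
        assert draws.var() == pytest.approx(mu + disp * mu**2, rel=0.05)


class TestSamValidity:
    def test_cigar_consistent_and_junctions_exact(self, mini_dataset):
        truth = mini_dataset["truth"]
        planted = {(c.chrom, c.intron.start, c.intron.end) for c in truth.chimeras}
        decoy_or_planted = set(planted)
        for g in mini_dataset["ann"].genes:
            for a, b in zip(g.exons, g.exons[1:]):
                decoy_or_planted.add((g.chrom, a.end, b.start))
        path = next(iter(mini_dataset["paths"]["sam"].values()))
        n_junction_reads = 0
        with pysam.AlignmentFile(path, "r") as sam:
            for aln in sam:
                if not aln.is_secondary:
                    assert aln.infer_query_length() == len(aln.query_sequence)
                pos = aln.reference_start
                for op, ln in aln.cigartuples:
                    if op == 3:
                        assert (aln.reference_name, pos, pos + ln) in decoy_or_planted
                        n_junction_reads += 1
                    if op in (0, 2, 3, 7, 8):
                        pos += ln
        assert n_junction_reads > 0

    def test_multimappers_share_name_with_nh(self, mini_dataset):
        path = next(iter(mini_dataset["paths"]["sam"].values()))
        by_name: dict = {}
        with pysam.AlignmentFile(path, "r") as sam:
            for aln in sam:
                if aln.has_tag("NH") and aln.get_tag("NH") == 2:
                    by_name.setdefault(aln.query_name, []).append(aln.is_secondary)
        assert by_name, "expected some multimappers"
        for flags in by_name.values():
            assert sorted(flags) == [False, True]

    def test_zero_library_gives_header_only(self, tmp_path):
        import dataclasses

        cfg = dataclasses.replace(TINY, library_size=0)
        ann, truth = simulate_annotations(cfg)
        paths = simulate_rnaseq(cfg, ann, truth, str(tmp_path))
        path = next(iter(paths.values()))
        with pysam.AlignmentFile(path, "r") as sam:
            assert sam.header.nreferences == cfg.n_chroms
            assert list(sam) == []


class TestWgbs:
    def test_pooled_level_and_imprint_stratification(self, mini_dataset):
        truth = mini_dataset["truth"]
        cfg = mini_dataset["config"]
        imprint_idx = build_interval_index(
            [type("R", (), {"chrom": c, "interval": iv})()
             for c, iv, _ in truth.imprint_regions.regions]
        )
        for sample, path in list(mini_dataset["paths"]["cpg"].items())[:2]:
            cond = cfg.design().condition_of(sample)
            rec = read_cpg_report(path)
            in_imprint = np.array(
                [bool(imprint_idx.query_point(c, p))
                 for c, p in zip(rec["chrom"], rec["pos"])]
            )
            glob = rec[~in_imprint]
            level = glob["meth_count"].sum() / glob["total_count"].sum()
            assert level == pytest.approx(truth.methylation_levels[cond], abs=0.02)
            imp = rec[in_imprint]
            ilevel = imp["meth_count"].sum() / imp["total_count"].sum()
            assert ilevel == pytest.approx(truth.imprint_levels[cond], abs=0.05)

    def test_level_zero_gives_no_methylated_calls(self, tmp_path):
        import dataclasses

        cfg = dataclasses.replace(
            TINY,
            methylation_levels=(0.0,) * 6,
            imprint_levels=(0.0,) * 6,
        )
        ann, truth = simulate_annotations(cfg)
        paths = simulate_wgbs(cfg, ann, truth, str(tmp_path))
        rec = read_cpg_report(next(iter(paths.values())))
        assert (rec["meth_count"] == 0).all()

    def test_cpg_positions_match_sequence(self):
        ann, _ = simulate_annotations(TINY)
        pos = cpg_positions(ann)
        chrom = "chr1"
        seq = ann.genome[chrom]
        for p in pos[chrom][:50]:
            assert seq[p] == ord("C") and seq[p + 1] == ord("G")
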