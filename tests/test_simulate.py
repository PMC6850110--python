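"""Simulator: determinism, planted structure, serialization round trips."""

import dataclasses
import filecmp

import numpy as np
import pytest

from tests.conftest import small_config
from zeaqtl.annotation import read_gff3
from zeaqtl.config import ConfigError, SimConfig
from zeaqtl.eqtl import ld_r2
from zeaqtl.latent import genotype_pcs
from zeaqtl.simulate import (STAGES, SimulationError, generate_annotation,
                             generate_phenotype, generate_population,
                             read_dataset, simulate_dataset, write_dataset)


class TestConfigValidation:
    def test_inverse_cannot_exceed_shared(self):
        with pytest.raises(ConfigError):
            small_config(n_inverse=10, n_shared=9)

    def test_nonpositive_dimensions(self):
        with pytest.raises(ConfigError):
            small_config(n_lines=0)

    def test_fraction_ranges(self):
        with pytest.raises(ConfigError):
            small_config(motif_frac_target=1.2)

    def test_stage_partition_must_cover(self):
        with pytest.raises(ConfigError):
            small_config(n_stage1_only=99)


class TestDeterminism:
    def test_same_seed_identical(self):
        a = simulate_dataset(small_config(seed=42))
        b = simulate_dataset(small_config(seed=42))
        np.testing.assert_array_equal(a.genotypes.dosages,
                                      b.genotypes.dosages)
        for stage in STAGES:
            np.testing.assert_array_equal(a.expression[stage].fpkm,
                                          b.expression[stage].fpkm)
        assert a.transcripts == b.transcripts

    def test_byte_identical_files(self, tmp_path):
        d1 = write_dataset(simulate_dataset(small_config(seed=5)),
                           tmp_path / "a")
        d2 = write_dataset(simulate_dataset(small_config(seed=5)),
                           tmp_path / "b")
        for f in d1.iterdir():
            assert filecmp.cmp(f, d2 / f.name, shallow=False), f.name


class TestPopulation:
    def test_structure_separates_on_top_pc(self):
        cfg = small_config(n_lines=200, n_subpops=2, fst_divergence=0.3,
                           missing_rate=0.0, seed=9)
        G, subpop = generate_population(cfg)
        pcs = genotype_pcs(G.dosages, k=1)
        r = np.corrcoef(pcs[:, 0], subpop)[0, 1]
        assert abs(r) > 0.8

    def test_no_divergence_no_separation(self):
        cfg = small_config(n_lines=200, n_subpops=2, fst_divergence=0.0,
                           missing_rate=0.0, seed=9)
        G, subpop = generate_population(cfg)
        pcs = genotype_pcs(G.dosages, k=1)
        assert abs(np.corrcoef(pcs[:, 0], subpop)[0, 1]) < 0.3

    def test_snp_names_follow_coordinates(self, tiny_dataset):
        snps = tiny_dataset.genotypes.snps
        for r in snps.itertuples():
            assert r.snp_id == f"S{r.chrom}_{r.pos}"
        for chrom, grp in snps.groupby("chrom"):
            assert grp["pos"].is_monotonic_increasing

    def test_within_block_ld(self):
        cfg = small_config(missing_rate=0.0, seed=10)
        G, _ = generate_population(cfg)
        snps = G.snps.assign(block=G.snps["pos"] // cfg.ld_block_span)
        r2s = []
        for (_, _), grp in snps.groupby(["chrom", "block"]):
            idx = grp.index.to_numpy()
            if len(idx) >= 2:
                r2s.append(ld_r2(G.dosages[:, idx[0]], G.dosages[:, idx[1]]))
        assert np.mean(r2s) > 0.5

    def test_dosages_homozygous(self, tiny_dataset):
        D = tiny_dataset.genotypes.dosages
        vals = np.unique(D[~np.isnan(D)])
        assert set(vals) <= {0.0, 2.0}


class TestPlantedTruth:
    def test_cis_within_gene_trans_elsewhere(self, tiny_dataset):
        ds = tiny_dataset
        spans = ds.annotation.genes.set_index("gene_id")
        for e in ds.truth.planted_eqtls:
            chrom, pos = e.snp_id[1:].rsplit("_", 1)
            pos = int(pos)
            g = spans.loc[e.gene_id]
            if e.kind == "cis":
                assert str(g.chrom) == chrom
                assert abs(pos - g.start) <= 20_000 \
                    and abs(pos - g.end) <= 20_000
            else:
                assert str(g.chrom) != chrom

    def test_inverse_signs_opposite(self, tiny_dataset):
        inv = tiny_dataset.truth.inverse_pairs
        assert len(inv) == tiny_dataset.config.n_inverse
        for e in inv:
            s1, s2 = STAGES
            assert np.sign(e.effects[s1]) == -np.sign(e.effects[s2])

    def test_stage_assignment_counts(self, tiny_dataset):
        cfg = tiny_dataset.config
        planted = tiny_dataset.truth.planted_eqtls
        shared = sum(1 for e in planted if len(e.stages) == 2)
        s1 = sum(1 for e in planted if e.stages == [STAGES[0]])
        s2 = sum(1 for e in planted if e.stages == [STAGES[1]])
        assert (shared, s1, s2) == (cfg.n_shared, cfg.n_stage1_only,
                                    cfg.n_stage2_only)

    def test_planted_effect_contrast(self, tiny_dataset):
        """Expression contrast across homozygous classes matches the
        planted effect within three standard errors."""
        ds = tiny_dataset
        checked = 0
        for e in ds.truth.planted_eqtls:
            if STAGES[0] not in e.stages:
                continue
            dose = ds.genotypes.column(e.snp_id)
            expr = ds.expression[STAGES[0]].gene_row(e.gene_id, "fpkm")
            ok = ~np.isnan(dose)
            g0, g2 = expr[ok & (dose == 0)], expr[ok & (dose == 2)]
            diff = g2.mean() - g0.mean()
            se = np.sqrt(g0.var(ddof=1) / len(g0) + g2.var(ddof=1) / len(g2))
            assert abs(diff - e.effects[STAGES[0]]) < 3 * se + 0.2
            checked += 1
        assert checked > 0


class TestPhenotype:
    def test_single_gene_unit_weight_perfect_correlation(self, tiny_dataset):
        ds = tiny_dataset
        truth = dataclasses.replace(
            ds.truth, qtt_genes=[(ds.truth.gene_ids[0], 1.0)])
        kl = generate_phenotype(ds.expression[STAGES[0]], truth, 0.0,
                                np.random.default_rng(0))
        expr = ds.expression[STAGES[0]].fpkm[0]
        assert np.corrcoef(kl, expr)[0, 1] == pytest.approx(1.0)

    def test_noise_dominates(self, tiny_dataset):
        ds = tiny_dataset
        truth = dataclasses.replace(
            ds.truth, qtt_genes=[(ds.truth.gene_ids[0], 1.0)])
        kl = generate_phenotype(ds.expression[STAGES[0]], truth, 1e4,
                                np.random.default_rng(0))
        r = np.corrcoef(kl, ds.expression[STAGES[0]].fpkm[0])[0, 1]
        assert abs(r) < 0.2

    def test_degenerate_phenotype_errors(self, tiny_dataset):
        ds = tiny_dataset
        truth = dataclasses.replace(ds.truth, qtt_genes=[])
        with pytest.raises(SimulationError):
            generate_phenotype(ds.expression[STAGES[0]], truth, 0.0,
                               np.random.default_rng(0))

    def test_opposite_weights_opposite_partial_correlation(self, tiny_dataset):
        ds = tiny_dataset
        g1, g2 = ds.truth.gene_ids[:2]
        truth = dataclasses.replace(ds.truth,
                                    qtt_genes=[(g1, 1.0), (g2, -1.0)])
        kl = generate_phenotype(ds.expression[STAGES[0]], truth, 0.1,
                                np.random.default_rng(1))
        E = ds.expression[STAGES[0]]
        e1, e2 = E.fpkm[0], E.fpkm[1]
        # partial correlations: residualize each gene on the other
        for expr, other, sign in ((e1, e2, 1.0), (e2, e1, -1.0)):
            b = np.polyfit(other, expr, 1)
            r_expr = expr - np.polyval(b, other)
            b2 = np.polyfit(other, kl.values, 1)
            r_kl = kl.values - np.polyval(b2, other)
            assert np.sign(np.corrcoef(r_expr, r_kl)[0, 1]) == sign


class TestAnnotationAndSequences:
    def test_genes_do_not_overlap(self, tiny_dataset):
        genes = tiny_dataset.annotation.genes
        for _, grp in genes.groupby("chrom"):
            g = grp.sort_values("start")
            assert (g["start"].to_numpy()[1:] > g["end"].to_numpy()[:-1]).all()

    def test_gff3_round_trip(self, tiny_dataset, tmp_path):
        from zeaqtl.annotation import write_gff3
        ann = tiny_dataset.annotation
        write_gff3(ann, tmp_path / "a.gff3")
        back = read_gff3(tmp_path / "a.gff3")
        assert len(back.genes) == len(ann.genes)
        merged = back.genes.merge(ann.genes, on="gene_id",
                                  suffixes=("_r", ""))
        assert (merged["start_r"] == merged["start"]).all()
        assert (merged["tss_r"] == merged["tss"]).all()
        assert (back.transcripts.sort_values("transcript_id")["utr3_len"]
                .to_numpy()
                == ann.transcripts.sort_values("transcript_id")["utr3_len"]
                .to_numpy()).all()

    def test_all_targets_carry_motif_when_frac_one(self):
        from zeaqtl.motifs import scan_motif
        ds = simulate_dataset(small_config(motif_frac_target=1.0, seed=17))
        for g in ds.truth.motif_targets:
            seqs = list(ds.transcripts[g].values())
            assert any(scan_motif(s, "URUAY") for s in seqs)

    def test_transcript_length_matches_annotation(self, tiny_dataset):
        tx = tiny_dataset.annotation.transcripts.set_index("gene_id")
        for g, txd in tiny_dataset.transcripts.items():
            for seq in txd.values():
                assert len(seq) == int(tx.loc[g, "length"])


class TestRoundTrip:
    def test_dataset_round_trip_exact(self, tiny_dataset, tmp_path):
        out = write_dataset(tiny_dataset, tmp_path / "ds")
        back = read_dataset(out)
        np.testing.assert_array_equal(back.genotypes.dosages,
                                      tiny_dataset.genotypes.dosages)
        for stage in STAGES:
            np.testing.assert_array_equal(
                back.expression[stage].fpkm,
                tiny_dataset.expression[stage].fpkm)
            np.testing.assert_array_equal(
                back.expression[stage].counts,
                tiny_dataset.expression[stage].counts)
        np.testing.assert_allclose(back.phenotype.to_numpy(),
                                   tiny_dataset.phenotype.to_numpy())
        assert back.transcripts == tiny_dataset.transcripts
        assert [dataclasses.asdict(e) for e in back.truth.planted_eqtls] \
            == [dataclasses.asdict(e)
                for e in tiny_dataset.truth.planted_eqtls]
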