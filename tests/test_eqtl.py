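"""eQTL region calling: clustering, LD pruning, locality, categories."""

import numpy as np
import pandas as pd
import pytest

from zeaqtl.eqtl import (EQTLRegion, classify_local_distant,
                         cluster_candidates, eqtl_genomic_category,
                         interval_gap, joint_effect_r2, ld_r2,
                         prune_candidates)
from zeaqtl.simulate import generate_annotation
from zeaqtl.config import SimConfig


def sig_frame(positions, ps=None, chrom="1"):
    ps = ps if ps is not None else [1e-8] * len(positions)
    return pd.DataFrame({
        "snp_id": [f"S{chrom}_{p}" for p in positions],
        "chrom": chrom, "pos": positions, "p": ps,
    })


class TestCluster:
    def test_chained_cluster(self):
        out = cluster_candidates(sig_frame([100, 2000, 4500]))
        assert len(out) == 1
        e = out[0]
        assert (e.start, e.end, e.n_snps) == (100, 4500, 3)

    def test_gaps_break_chain(self):
        assert cluster_candidates(sig_frame([100, 6000, 11000])) == []

    def test_min_snps_enforced(self):
        assert cluster_candidates(sig_frame([100, 200])) == []

    def test_lead_is_min_p_leftmost_tie(self):
        out = cluster_candidates(
            sig_frame([100, 200, 300], ps=[1e-6, 1e-9, 1e-9]))
        assert out[0].lead_snp == "S1_200"

    def test_diameter_mode_splits_wide_chains(self):
        # consecutive gaps of 3 kb chain, but the span exceeds 5 kb
        pos = [0, 3000, 6000, 9000, 12000]
        chained = cluster_candidates(sig_frame(pos))
        assert len(chained) == 1 and chained[0].end == 12000
        diam = cluster_candidates(sig_frame(pos), diameter=True)
        assert all(e.end - e.start < 5000 for e in diam)

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            n = int(rng.integers(0, 25))
            pos = np.sort(rng.choice(30000, size=n, replace=False))
            out = cluster_candidates(sig_frame(list(pos)))
            # oracle: split wherever the gap between neighbours is >= 5 kb
            groups, cur = [], []
            for p in pos:
                if cur and p - cur[-1] >= 5000:
                    groups.append(cur)
                    cur = []
                cur.append(int(p))
            if cur:
                groups.append(cur)
            expected = [g for g in groups if len(g) >= 3]
            assert [(e.start, e.end, e.n_snps) for e in out] \
                == [(g[0], g[-1], len(g)) for g in expected]


class TestLdR2:
    def test_identical(self):
        assert ld_r2(np.array([0, 0, 2, 2.0]), np.array([0, 0, 2, 2.0])) == 1.0

    def test_orthogonal(self):
        assert ld_r2(np.array([0, 0, 2, 2.0]),
                     np.array([0, 2, 0, 2.0])) == pytest.approx(0.0, abs=1e-12)

    def test_one_third(self):
        assert ld_r2(np.array([0, 0, 2, 2.0]),
                     np.array([0, 0, 0, 2.0])) == pytest.approx(1 / 3)

    def test_zero_variance_warns(self):
        with pytest.warns(UserWarning):
            assert ld_r2(np.zeros(4), np.array([0, 2, 0, 2.0])) == 0.0


def region(positions, lead, lead_p, gene="G1", chrom="1"):
    ids = [f"S{chrom}_{p}" for p in positions]
    return EQTLRegion(chrom=chrom, start=min(positions), end=max(positions),
                      member_snps=ids, lead_snp=f"S{chrom}_{lead}",
                      gene_id=gene, lead_p=lead_p)


class TestPrune:
    def _setup(self, seed=1):
        rng = np.random.default_rng(seed)
        n = 60
        a = 2.0 * (rng.random(n) < 0.5)
        b = a.copy()
        flip = rng.random(n) < 0.05
        b[flip] = 2.0 - b[flip]          # r2 ~ 0.8 with a
        c = 2.0 * (rng.random(n) < 0.5)  # independent
        expr = 0.8 * a + rng.normal(size=n)
        dosages = {"S1_100": a, "S1_150": a, "S1_200": a,
                   "S1_5000": b, "S1_5050": b, "S1_5100": b,
                   "S1_9000": c, "S1_9050": c, "S1_9100": c}
        return dosages, expr

    def test_less_significant_in_ld_dropped(self):
        dosages, expr = self._setup()
        strong = region([100, 150, 200], 100, 1e-10)
        weak = region([5000, 5050, 5100], 5000, 1e-4)
        kept = prune_candidates([strong, weak], dosages.__getitem__, expr)
        assert [e.lead_snp for e in kept] == ["S1_100"]

    def test_equal_p_keeps_larger_joint_effect(self):
        dosages, expr = self._setup()
        a_cand = region([100, 150, 200], 100, 1e-8)
        b_cand = region([5000, 5050, 5100], 5000, 1e-8)
        kept = prune_candidates([a_cand, b_cand], dosages.__getitem__, expr)
        assert len(kept) == 1
        ja = joint_effect_r2(expr, np.column_stack(
            [dosages[s] for s in a_cand.member_snps]))
        jb = joint_effect_r2(expr, np.column_stack(
            [dosages[s] for s in b_cand.member_snps]))
        want = a_cand if ja >= jb else b_cand
        assert kept[0].lead_snp == want.lead_snp

    def test_below_threshold_both_survive(self):
        dosages, expr = self._setup()
        a_cand = region([100, 150, 200], 100, 1e-10)
        c_cand = region([9000, 9050, 9100], 9000, 1e-4)
        kept = prune_candidates([a_cand, c_cand], dosages.__getitem__, expr)
        assert len(kept) == 2

    def test_order_invariance(self):
        dosages, expr = self._setup()
        cands = [region([100, 150, 200], 100, 1e-10),
                 region([5000, 5050, 5100], 5000, 1e-4),
                 region([9000, 9050, 9100], 9000, 1e-6)]
        ref = [e.lead_snp for e in
               prune_candidates(list(cands), dosages.__getitem__, expr)]
        rev = [e.lead_snp for e in
               prune_candidates(cands[::-1], dosages.__getitem__, expr)]
        assert ref == rev


class TestLocality:
    def _eqtl(self, start, end, chrom="1"):
        return region(list(range(start, end + 1, (end - start) // 2 or 1)),
                      start, 1e-9, chrom=chrom)

    def test_inside_gene_local(self):
        e = self._eqtl(100_500, 101_000)
        assert classify_local_distant(e, "1", 100_000, 105_000) == "local"

    def test_gap_just_under_cutoff(self):
        # 1-based inclusive gap: 110000 - 105000 - 1 = 4999
        e = self._eqtl(110_000, 112_000)
        assert interval_gap(110_000, 112_000, 100_000, 105_000) == 4999
        assert classify_local_distant(e, "1", 100_000, 105_000) == "local"

    def test_cutoff_boundary(self):
        e = self._eqtl(125_001, 126_000)
        # gap = 125001 - 105000 - 1 = 20000 -> still local
        assert classify_local_distant(e, "1", 100_000, 105_000) == "local"
        e2 = self._eqtl(125_002, 126_000)
        assert classify_local_distant(e2, "1", 100_000, 105_000) == "distant"

    def test_other_chromosome_distant(self):
        e = self._eqtl(100_500, 101_000, chrom="2")
        assert classify_local_distant(e, "1", 100_000, 105_000) == "distant"


class TestGenomicCategory:
    @pytest.fixture(scope="class")
    def ann(self):
        return generate_annotation(
            SimConfig(n_genes=10, n_chroms=2, snps_per_chrom=10, seed=0),
            np.random.default_rng(0))

    def test_exon_beats_everything(self, ann):
        g = ann.genes.iloc[0]
        e = region([int(g.start) + 10, int(g.start) + 20, int(g.start) + 30],
                   int(g.start) + 10, 1e-9, chrom=str(g.chrom))
        assert eqtl_genomic_category(e, ann) == "exon"

    def test_upstream_window_is_utr1kb(self, ann):
        g = ann.genes.loc[ann.genes["strand"] == "+"].iloc[0]
        lo = int(g.start) - 600
        e = region([lo, lo + 50, lo + 100], lo, 1e-9, chrom=str(g.chrom))
        assert eqtl_genomic_category(e, ann) == "utr1kb"

    def test_far_from_genes_intergenic(self, ann):
        chrom = str(ann.genes["chrom"].iloc[0])
        far = int(ann.genes["end"].max()) + 60_000
        e = region([far, far + 10, far + 20], far, 1e-9, chrom=chrom)
        assert eqtl_genomic_category(e, ann) == "intergenic"

    def test_intron_between_exons(self, ann):
        g = ann.genes.iloc[0]
        exons = ann.exons.loc[ann.exons["gene_id"] == g.gene_id] \
            .sort_values("start")
        lo = int(exons.iloc[0]["end"]) + 50
        e = region([lo, lo + 20, lo + 40], lo, 1e-9, chrom=str(g.chrom))
        assert eqtl_genomic_category(e, ann) == "intron"
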