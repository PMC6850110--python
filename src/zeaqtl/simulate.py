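"""Synthetic two-stage eQTL panel with recorded ground truth.

The generator emulates the statistical design of a maize kernel eQTL
study: a few hundred fully homozygous inbred lines drawn from diverged
subpopulations, LD-blocked biallelic SNPs named ``S{chrom}_{pos}``,
two-stage expression with planted cis/trans effects (shared,
stage-specific and sign-inverted across stages), hidden expression
factors, a kernel-length phenotype driven by a subset of transcripts, and
transcript sequences with planted m6A-associated motifs.  Every random
draw flows from one seed, so a configuration reproduces its dataset
bit-identically.

Population structure follows a Balding-Nichols-style model: each LD block
has an ancestral allele frequency and per-subpopulation frequencies drawn
from a Beta distribution whose concentration is set by the divergence
parameter.  Linkage is simulated by a block-latent allele shared by all
SNPs of a 5-kb window, with a small per-SNP flip probability, which yields
average within-block r-squared well above 0.5 without a coalescent model.
"""

from __future__ import annotations

import dataclasses
import json
import re
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from zeaqtl.annotation import GeneAnnotation, read_gff3, write_gff3
from zeaqtl.config import ConfigError, SimConfig
from zeaqtl.expression import ExpressionMatrix, read_matrix_tsv, write_matrix_tsv
from zeaqtl.genotype import GenotypeMatrix, SNP_COLUMNS, read_vcf, snp_name, write_vcf
from zeaqtl.motifs import MOTIFS, scan_motif

STAGES = ("5DAP", "15DAP")

#: per-SNP probability of flipping away from the block-latent allele
_SNP_FLIP = 0.03

# gene model geometry (bp)
_U5, _EXON1, _INTRON, _EXON2, _U3 = 150, 600, 500, 900, 300
_GENE_LEN = _EXON1 + _INTRON + _EXON2
_GENE_PITCH = 6500
_BASES = "ACGT"


class SimulationError(RuntimeError):
    pass


@dataclass
class PlantedEQTL:
    """One planted SNP -> gene effect with its stage activity."""

    snp_id: str
    gene_id: str
    kind: str                 # "cis" | "trans"
    stages: list              # stages where the effect is active
    effects: dict             # stage -> signed effect (expression units)


@dataclass
class TruthTable:
    """Planted simulation ground truth for recovery tests."""

    planted_eqtls: list
    qtt_genes: list           # (gene_id, alpha_true) generative weights
    motif_targets: list       # designated target genes for enrichment
    motif_genes: dict         # motif -> {"mrna": [...], "3utr": [...]}
    hidden_loadings: np.ndarray   # genes x K
    hidden_values: np.ndarray     # lines x K
    baselines: np.ndarray         # per-gene baseline abundance
    subpop: np.ndarray            # per-line subpopulation label
    gene_ids: list
    line_ids: list

    def eqtl_genes(self, kind: str | None = None,
                   stage: str | None = None) -> set:
        out = set()
        for e in self.planted_eqtls:
            if kind is not None and e.kind != kind:
                continue
            if stage is not None and stage not in e.stages:
                continue
            out.add(e.gene_id)
        return out

    @property
    def inverse_pairs(self) -> list:
        return [
            e for e in self.planted_eqtls
            if len(e.stages) == 2
            and np.sign(e.effects[STAGES[0]]) == -np.sign(e.effects[STAGES[1]])
        ]

    def to_json(self, path: str | Path) -> None:
        data = {
            "planted_eqtls": [dataclasses.asdict(e) for e in self.planted_eqtls],
            "qtt_genes": [[g, w] for g, w in self.qtt_genes],
            "motif_targets": list(self.motif_targets),
            "motif_genes": {m: {r: sorted(v) for r, v in d.items()}
                            for m, d in self.motif_genes.items()},
            "hidden_loadings": np.asarray(self.hidden_loadings).tolist(),
            "hidden_values": np.asarray(self.hidden_values).tolist(),
            "baselines": np.asarray(self.baselines).tolist(),
            "subpop": np.asarray(self.subpop).tolist(),
            "gene_ids": list(self.gene_ids),
            "line_ids": list(self.line_ids),
        }
        with open(path, "w") as fh:
            json.dump(data, fh)

    @classmethod
    def from_json(cls, path: str | Path) -> "TruthTable":
        with open(path) as fh:
            data = json.load(fh)
        return cls(
            planted_eqtls=[PlantedEQTL(**e) for e in data["planted_eqtls"]],
            qtt_genes=[(g, w) for g, w in data["qtt_genes"]],
            motif_targets=data["motif_targets"],
            motif_genes={m: {r: set(v) for r, v in d.items()}
                         for m, d in data["motif_genes"].items()},
            hidden_loadings=np.array(data["hidden_loadings"]),
            hidden_values=np.array(data["hidden_values"]),
            baselines=np.array(data["baselines"]),
            subpop=np.array(data["subpop"]),
            gene_ids=data["gene_ids"],
            line_ids=data["line_ids"],
        )


@dataclass
class SimulatedDataset:
    """All emitted components of one simulated study."""

    config: SimConfig
    genotypes: GenotypeMatrix          # with missingness applied
    expression: dict                   # stage -> ExpressionMatrix
    phenotype: pd.Series               # kernel length per line
    annotation: GeneAnnotation
    transcripts: dict                  # gene_id -> {tx_id: sequence}
    truth: TruthTable


# ---------------------------------------------------------------------------
# annotation / gene layout

def generate_annotation(config: SimConfig, rng: np.random.Generator
                        ) -> GeneAnnotation:
    """Lay out non-overlapping two-exon gene models across chromosomes.

    Each gene has a 5'UTR at the transcription start, a CDS split over two
    exons, and a 3'UTR at the end; strands alternate randomly.
    """
    genes, exons, cds, utr5, utr3, txs = [], [], [], [], [], []
    per_chrom = int(np.ceil(config.n_genes / config.n_chroms))
    gi = 0
    for c in range(1, config.n_chroms + 1):
        for slot in range(per_chrom):
            if gi >= config.n_genes:
                break
            start = slot * _GENE_PITCH + 2001 + int(rng.integers(0, 1500))
            end = start + _GENE_LEN - 1
            strand = "+" if rng.random() < 0.5 else "-"
            gid = f"GENE{gi + 1:04d}"
            tid = f"{gid}_T01"
            tss = start if strand == "+" else end
            tes = end if strand == "+" else start
            genes.append((gid, str(c), start, end, strand, tss, tes))
            e1 = (start, start + _EXON1 - 1)
            e2 = (end - _EXON2 + 1, end)
            exons += [(gid, str(c), *e1), (gid, str(c), *e2)]
            if strand == "+":
                utr5.append((gid, str(c), e1[0], e1[0] + _U5 - 1))
                utr3.append((gid, str(c), e2[1] - _U3 + 1, e2[1]))
                cds += [(gid, str(c), e1[0] + _U5, e1[1]),
                        (gid, str(c), e2[0], e2[1] - _U3)]
            else:
                utr5.append((gid, str(c), e2[1] - _U5 + 1, e2[1]))
                utr3.append((gid, str(c), e1[0], e1[0] + _U3 - 1))
                cds += [(gid, str(c), e1[0] + _U3, e1[1]),
                        (gid, str(c), e2[0], e2[1] - _U5)]
            txs.append((tid, gid, _EXON1 + _EXON2, _U5, _U3))
            gi += 1

    cols = ["gene_id", "chrom", "start", "end"]
    return GeneAnnotation(
        genes=pd.DataFrame(genes, columns=["gene_id", "chrom", "start", "end",
                                           "strand", "tss", "tes"]),
        exons=pd.DataFrame(exons, columns=cols),
        cds=pd.DataFrame(cds, columns=cols),
        utr5=pd.DataFrame(utr5, columns=cols),
        utr3=pd.DataFrame(utr3, columns=cols),
        transcripts=pd.DataFrame(txs, columns=["transcript_id", "gene_id",
                                               "length", "utr5_len", "utr3_len"]),
    )


def _chrom_length(config: SimConfig) -> int:
    per_chrom = int(np.ceil(config.n_genes / config.n_chroms))
    return per_chrom * _GENE_PITCH + 5000


# ---------------------------------------------------------------------------
# genotypes

def generate_population(config: SimConfig,
                        rng: np.random.Generator | None = None
                        ) -> tuple[GenotypeMatrix, np.ndarray]:
    """Structured homozygous genotypes with LD blocks; no missingness yet.

    Returns the complete dosage matrix (values 0/2) and the per-line
    subpopulation labels.  SNPs in the same ``ld_block_span`` window share
    a block-latent allele, producing high within-block r-squared.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    n = config.n_lines
    subpop = np.arange(n) % config.n_subpops
    chrom_len = _chrom_length(config)
    rows = []
    cols = []
    for c in range(1, config.n_chroms + 1):
        pos = np.sort(rng.choice(np.arange(1, chrom_len + 1),
                                 size=config.snps_per_chrom, replace=False))
        block_of = pos // config.ld_block_span
        for block in np.unique(block_of):
            idx = np.nonzero(block_of == block)[0]
            p0 = rng.uniform(0.1, 0.9)
            F = config.fst_divergence
            if F <= 0:
                p_sub = np.full(config.n_subpops, p0)
            else:
                a = p0 * (1 - F) / F
                b = (1 - p0) * (1 - F) / F
                p_sub = rng.beta(a, b, size=config.n_subpops)
            latent = (rng.random(n) < p_sub[subpop]).astype(np.int8)
            for j in idx:
                flip = rng.random(n) < _SNP_FLIP
                allele = np.where(flip, 1 - latent, latent)
                ref, alt = rng.choice(4, size=2, replace=False)
                rows.append((snp_name(c, int(pos[j])), str(c), int(pos[j]),
                             _BASES[ref], _BASES[alt]))
                cols.append(allele.astype(float) * 2.0)
    snps = pd.DataFrame(rows, columns=SNP_COLUMNS)
    D = np.column_stack(cols)
    return GenotypeMatrix([f"L{i + 1:04d}" for i in range(n)], snps, D), subpop


def apply_missingness(G: GenotypeMatrix, rate: float,
                      rng: np.random.Generator) -> GenotypeMatrix:
    """Mask a random fraction of calls as missing."""
    D = G.dosages.copy()
    if rate > 0:
        D[rng.random(D.shape) < rate] = np.nan
    return GenotypeMatrix(list(G.line_ids), G.snps.copy(), D)


# ---------------------------------------------------------------------------
# truth planting

def _eligible_snps(G: GenotypeMatrix, maf_min: float = 0.2,
                   min_block: int = 3, block_span: int = 5000) -> pd.DataFrame:
    """SNPs with adequate MAF whose 5-kb window holds >= min_block SNPs."""
    snps = G.snps.copy()
    p = G.dosages.mean(axis=0) / 2.0
    snps["maf"] = np.minimum(p, 1 - p)
    snps["block"] = snps["pos"] // block_span
    sizes = snps.groupby(["chrom", "block"])["snp_id"].transform("size")
    return snps.loc[(snps["maf"] >= maf_min) & (sizes >= min_block)]


def plant_truth(config: SimConfig, annotation: GeneAnnotation,
                G: GenotypeMatrix, rng: np.random.Generator) -> TruthTable:
    """Choose planted eQTLs, QTT genes, hidden factors and motif targets.

    Cis SNPs are planted inside their gene's span (always within the 20-kb
    local window); trans SNPs sit on a different chromosome than their
    gene.  Each gene carries at most one planted eQTL.  QTT genes are
    drawn from the cis-planted genes so genotype, expression and phenotype
    evidence chains are all realizable.
    """
    elig = _eligible_snps(G, block_span=config.ld_block_span)
    genes = annotation.genes

    # genes with an eligible SNP inside their span
    cis_pool = []
    for _, g in genes.iterrows():
        hit = elig.loc[(elig["chrom"] == g.chrom) & (elig["pos"] >= g.start)
                       & (elig["pos"] <= g.end)]
        if len(hit):
            cis_pool.append((g.gene_id, hit))
    rng.shuffle(cis_pool)
    if len(cis_pool) < config.n_cis_eqtl:
        raise SimulationError(
            f"only {len(cis_pool)} genes have an eligible in-span SNP; "
            f"cannot plant {config.n_cis_eqtl} cis eQTLs"
        )

    planted: list[PlantedEQTL] = []
    used_genes: set = set()
    for gene_id, hit in cis_pool[:config.n_cis_eqtl]:
        snp = hit.iloc[int(rng.integers(0, len(hit)))]
        planted.append(PlantedEQTL(snp_id=snp.snp_id, gene_id=gene_id,
                                   kind="cis", stages=[], effects={}))
        used_genes.add(gene_id)

    free_genes = [g for g in genes["gene_id"] if g not in used_genes]
    rng.shuffle(free_genes)
    if len(free_genes) < config.n_trans_eqtl:
        raise SimulationError("not enough genes left for trans planting")
    gene_chrom = dict(zip(genes["gene_id"], genes["chrom"].astype(str)))
    for gene_id in free_genes[:config.n_trans_eqtl]:
        pool = elig.loc[elig["chrom"].astype(str) != gene_chrom[gene_id]]
        if pool.empty:
            raise SimulationError("no off-chromosome SNP available for trans eQTL")
        snp = pool.iloc[int(rng.integers(0, len(pool)))]
        planted.append(PlantedEQTL(snp_id=snp.snp_id, gene_id=gene_id,
                                   kind="trans", stages=[], effects={}))
        used_genes.add(gene_id)

    # stage assignment: shared (with sign-inverted subset), then specific
    order = rng.permutation(len(planted))
    magnitude = config.eqtl_effect_sd
    s1, s2 = STAGES
    for rank, idx in enumerate(order):
        e = planted[idx]
        sign = 1.0 if rng.random() < 0.5 else -1.0
        if rank < config.n_shared:
            e.stages = [s1, s2]
            if rank < config.n_inverse:
                e.effects = {s1: sign * magnitude, s2: -sign * magnitude}
            else:
                e.effects = {s1: sign * magnitude, s2: sign * magnitude}
        elif rank < config.n_shared + config.n_stage1_only:
            e.stages, e.effects = [s1], {s1: sign * magnitude}
        else:
            e.stages, e.effects = [s2], {s2: sign * magnitude}

    cis_genes = [e.gene_id for e in planted if e.kind == "cis"]
    n_qtt = min(config.n_qtt_genes, len(cis_genes))
    qtt_pick = list(rng.choice(cis_genes, size=n_qtt, replace=False))
    qtt_genes = [(g, float(rng.choice([-1.0, 1.0]))) for g in qtt_pick]

    gene_ids = list(genes["gene_id"])
    K = config.n_hidden_factors
    loadings = rng.normal(0.0, 0.6, size=(len(gene_ids), K))
    values = rng.normal(0.0, 1.0, size=(config.n_lines, K))
    # baselines well above zero so the non-negativity clip of the FPKM
    # representation almost never distorts a planted (possibly negative)
    # allelic shift
    baselines = rng.uniform(5.0, 15.0, size=len(gene_ids))

    n_targets = max(1, config.n_genes // 10)
    targets = list(rng.choice(gene_ids, size=n_targets, replace=False))

    subpop = np.arange(config.n_lines) % config.n_subpops
    return TruthTable(
        planted_eqtls=planted,
        qtt_genes=qtt_genes,
        motif_targets=targets,
        motif_genes={},
        hidden_loadings=loadings,
        hidden_values=values,
        baselines=baselines,
        subpop=subpop,
        gene_ids=gene_ids,
        line_ids=list(G.line_ids),
    )


# ---------------------------------------------------------------------------
# expression / phenotype

def generate_expression(
    G: GenotypeMatrix,
    truth: TruthTable,
    stage: str,
    annotation: GeneAnnotation,
    rng: np.random.Generator,
    noise_sd: float = 1.0,
) -> ExpressionMatrix:
    """Abundance = baseline + planted effects + hidden factors + noise.

    Planted effects active at this stage add ``effect * dosage / 2`` (so
    homozygous-alternate lines shift by the full effect).  The abundance
    matrix clips at zero for the FPKM representation; counts are a Poisson
    thinning of abundance at a per-line sequencing depth.
    """
    if stage not in STAGES:
        raise ValueError(f"unknown stage {stage!r}; know {STAGES}")
    genes = truth.gene_ids
    gidx = {g: i for i, g in enumerate(genes)}
    n_genes, n_lines = len(genes), G.n_lines
    E = np.tile(truth.baselines[:, None], (1, n_lines)).astype(float)
    E += truth.hidden_loadings @ truth.hidden_values.T
    for e in truth.planted_eqtls:
        if stage in e.stages:
            dose = np.nan_to_num(G.column(e.snp_id), nan=0.0)
            E[gidx[e.gene_id]] += e.effects[stage] * dose / 2.0
    E += rng.normal(0.0, noise_sd, size=E.shape)

    lengths = (annotation.transcripts.set_index("gene_id")["length"]
               .reindex(genes).to_numpy(dtype=float))
    abundance = np.clip(E, 0.0, None)
    depth = rng.uniform(1.5e6, 2.5e6, size=n_lines)
    lam = abundance * lengths[:, None] / 1000.0 * depth[None, :] / 1e6
    counts = rng.poisson(lam).astype(float)
    return ExpressionMatrix(
        gene_ids=list(genes), line_ids=list(G.line_ids),
        counts=counts, fpkm=abundance, gene_lengths=lengths,
    )


def generate_phenotype(E: ExpressionMatrix, truth: TruthTable,
                       noise_sd: float, rng: np.random.Generator) -> pd.Series:
    """Kernel length: weighted sum of QTT-gene abundances plus noise."""
    if not truth.qtt_genes and noise_sd == 0:
        raise SimulationError("no QTT genes and zero noise: phenotype degenerate")
    kl = np.zeros(E.n_lines)
    for gene_id, w in truth.qtt_genes:
        kl += w * E.gene_row(gene_id, "fpkm")
    kl += rng.normal(0.0, noise_sd, size=E.n_lines)
    return pd.Series(kl, index=E.line_ids, name="kernel_length")


# ---------------------------------------------------------------------------
# transcript sequences and motif planting

_ANY_MOTIF = re.compile("(?=(" + "|".join(MOTIFS.values()) + "))")

_PLANT_INSTANCE = {"RRACH": "GGACT", "URUAY": "TGTAT"}


def _scrub(seq: list, rng: np.random.Generator) -> None:
    """Mutate a base in every motif window until no pattern matches."""
    for _ in range(1000):
        text = "".join(seq)
        starts = [m.start() for m in _ANY_MOTIF.finditer(text)]
        if not starts:
            return
        for i in starts:
            seq[i + 2] = "C" if rng.random() < 0.5 else "G"
    raise SimulationError("motif scrubbing failed to converge")


def generate_sequences(
    config: SimConfig,
    annotation: GeneAnnotation,
    truth: TruthTable,
    rng: np.random.Generator,
) -> dict:
    """Transcript cDNA sequences with motif-free backbones and planted motifs.

    Backbones are scrubbed of both motif patterns; designated target genes
    carry a planted instance of each motif in their 3'UTR with probability
    ``motif_frac_target``, background genes with ``motif_frac_background``
    (independent draws per motif).  The realized presence sets, recounted
    with the scanner after planting, are recorded in
    ``truth.motif_genes``.
    """
    tx = annotation.transcripts.set_index("gene_id")
    targets = set(truth.motif_targets)
    transcripts: dict = {}
    carriers = {m: set() for m in MOTIFS}
    for gene_id in truth.gene_ids:
        row = tx.loc[gene_id]
        length, u3 = int(row["length"]), int(row["utr3_len"])
        seq = list(rng.choice(list(_BASES), size=length))
        _scrub(seq, rng)
        frac = config.motif_frac_target if gene_id in targets \
            else config.motif_frac_background
        offset = length - u3
        for k, (motif, instance) in enumerate(sorted(_PLANT_INSTANCE.items())):
            if rng.random() < frac:
                at = offset + 5 + 10 * k
                seq[at:at + len(instance)] = list(instance)
                carriers[motif].add(gene_id)
        transcripts[gene_id] = {str(row["transcript_id"]): "".join(seq)}

    truth.motif_genes = {
        m: {"mrna": set(), "3utr": set()} for m in MOTIFS
    }
    for gene_id, txd in transcripts.items():
        u3 = int(tx.loc[gene_id, "utr3_len"])
        for m in MOTIFS:
            for seq in txd.values():
                if scan_motif(seq, m):
                    truth.motif_genes[m]["mrna"].add(gene_id)
                if scan_motif(seq[-u3:], m):
                    truth.motif_genes[m]["3utr"].add(gene_id)
    return transcripts


# ---------------------------------------------------------------------------
# orchestration and serialization

def simulate_dataset(config: SimConfig) -> SimulatedDataset:
    """Generate one complete, internally consistent synthetic study."""
    rng = np.random.default_rng(config.seed)
    annotation = generate_annotation(config, rng)
    G_full, _ = generate_population(config, rng)
    truth = plant_truth(config, annotation, G_full, rng)
    expression = {
        stage: generate_expression(G_full, truth, stage, annotation, rng)
        for stage in STAGES
    }
    phenotype = generate_phenotype(expression[STAGES[0]], truth,
                                   config.phenotype_noise_sd, rng)
    transcripts = generate_sequences(config, annotation, truth, rng)
    G = apply_missingness(G_full, config.missing_rate, rng)
    return SimulatedDataset(
        config=config, genotypes=G, expression=expression,
        phenotype=phenotype, annotation=annotation,
        transcripts=transcripts, truth=truth,
    )


def write_dataset(ds: SimulatedDataset, outdir: str | Path) -> Path:
    """Write VCF, GFF3, FASTA, expression/phenotype TSVs and the truth JSON."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    write_vcf(ds.genotypes, out / "genotypes.vcf")
    write_gff3(ds.annotation, out / "annotation.gff3")
    records = [
        SeqRecord(Seq(seq), id=tx_id, description=f"gene={gene_id}")
        for gene_id, txd in ds.transcripts.items()
        for tx_id, seq in txd.items()
    ]
    SeqIO.write(records, out / "transcripts.fa", "fasta")
    for stage, E in ds.expression.items():
        write_matrix_tsv(E.fpkm, E.gene_ids, E.line_ids,
                         out / f"expression_{stage}.fpkm.tsv")
        write_matrix_tsv(E.counts, E.gene_ids, E.line_ids,
                         out / f"expression_{stage}.counts.tsv")
    ds.phenotype.rename_axis("line_id").to_csv(out / "phenotype.tsv",
                                               sep="\t", float_format="%.17g")
    ds.truth.to_json(out / "truth.json")
    with open(out / "sim_config.json", "w") as fh:
        json.dump(dataclasses.asdict(ds.config), fh, indent=1)
    return out


def read_dataset(outdir: str | Path) -> SimulatedDataset:
    """Load a dataset written by :func:`write_dataset`."""
    out = Path(outdir)
    with open(out / "sim_config.json") as fh:
        config = SimConfig(**json.load(fh))
    G = read_vcf(out / "genotypes.vcf")
    annotation = read_gff3(out / "annotation.gff3")
    truth = TruthTable.from_json(out / "truth.json")
    tx2gene = dict(zip(annotation.transcripts["transcript_id"],
                       annotation.transcripts["gene_id"]))
    transcripts: dict = {}
    for rec in SeqIO.parse(str(out / "transcripts.fa"), "fasta"):
        gene_id = tx2gene[rec.id]
        transcripts.setdefault(gene_id, {})[rec.id] = str(rec.seq)
    lengths = annotation.transcripts.set_index("gene_id")["length"]
    expression = {}
    for stage in STAGES:
        fpkm = read_matrix_tsv(out / f"expression_{stage}.fpkm.tsv")
        counts = read_matrix_tsv(out / f"expression_{stage}.counts.tsv")
        expression[stage] = ExpressionMatrix(
            gene_ids=list(fpkm.index), line_ids=list(fpkm.columns),
            counts=counts.to_numpy(dtype=float), fpkm=fpkm.to_numpy(dtype=float),
            gene_lengths=lengths.reindex(fpkm.index).to_numpy(dtype=float),
        )
    pheno = pd.read_csv(out / "phenotype.tsv", sep="\t", index_col=0,
                        float_precision="round_trip")
    phenotype = pheno.iloc[:, 0].rename("kernel_length")
    return SimulatedDataset(
        config=config, genotypes=G, expression=expression,
        phenotype=phenotype, annotation=annotation,
        transcripts=transcripts, truth=truth,
    )
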