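"""Synthetic F2 cross, phenotype and pooled-sequencing generator.

The generator emulates the cross design behind bulked-segregant mapping of a
semi-dominant dwarf locus in an oilseed-rape-like genome:

* two fully homozygous (doubled-haploid) parents that differ at genome-wide
  marker SNPs plus mutagenesis-induced variants, one of which is a planted
  causal missense SNP inside the degron (GWPPV) codon block of a gene;
* an F2 population produced by meiosis with Poisson crossover counts
  (Haldane model, no interference) and uniform crossover placement;
* trimodal plant heights under a one-locus semi-dominant model;
* phenotype-extreme bulks and clonal parental pools;
* Poisson per-site sequencing depth with binomial allele sampling and a
  per-read miscall rate.

The reference sequence is defined as the wild-type parent genome, so the alt
allele of every segregating variant is the mutant-parent allele and the
Δ(SNP-index) scan is positively polarized at the causal locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .genome import GeneModel, revcomp, write_fasta, write_gff3

SAMPLES = ("wt_parent", "mut_parent", "wt_bulk", "df_bulk")
GENOTYPE_CLASSES = ("hom_wt", "het", "hom_mut")

# degron codon block planted into the causal gene: G W P P V
DEGRON_CODONS = ("GGA", "TGG", "CCA", "CCA", "GTC")

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)
_STOPS = {"TAA", "TAG", "TGA"}
_SAFE_CODONS = [a + b + c for a in "ACGT" for b in "ACGT" for c in "ACGT"
                if a + b + c not in _STOPS]

# gene architecture used by the generator (transcript-orientation lengths)
_UTR5_LEN = 120
_UTR3_LEN = 150
_INTRON_LEN = 250
_CDS_PIECES = (150, 300, 750)  # total 1200 bp = 400 codons


@dataclass
class CrossConfig:
    """Full parameterization of the simulated cross and sequencing.

    Phenotype defaults are the observed parental heights of the study system
    (dwarf homozygote 86.8 +/- 4.9 cm, tall homozygote 198.7 +/- 15.9 cm) and
    the F1 mean of 152.1 cm; the heterozygote SD of 12 cm is a range/4
    heuristic from the reported F1 range 121-167 cm.
    """

    n_chromosomes: int = 3
    chrom_length_bp: int = 10_000_000
    cm_per_mb: float = 2.0
    n_marker_snps: int = 600
    n_induced_mutations: int = 60
    n_artifact_sites: int = 30
    genes_per_chromosome: int = 12
    causal_chrom_index: int = 2
    causal_gene_index: int = 4
    causal_codon: int = 84
    f2_size: int = 300
    bulk_size: int = 30
    parent_pool_size: int = 20
    depth_lambda: float = 50.0
    error_rate: float = 1e-3
    indel_fraction: float = 0.15
    phenotype_model: dict[str, tuple[float, float]] = field(
        default_factory=lambda: {
            "hom_wt": (198.7, 15.9),
            "het": (152.1, 12.0),
            "hom_mut": (86.8, 4.9),
        }
    )
    seed: int = 0

    @property
    def chrom_names(self) -> list[str]:
        return [f"A{i + 1:02d}" for i in range(self.n_chromosomes)]

    @property
    def causal_chrom(self) -> str:
        return self.chrom_names[self.causal_chrom_index]

    def validate(self) -> None:
        counts = dict(
            n_chromosomes=self.n_chromosomes,
            chrom_length_bp=self.chrom_length_bp,
            n_marker_snps=self.n_marker_snps,
            genes_per_chromosome=self.genes_per_chromosome,
            f2_size=self.f2_size,
            bulk_size=self.bulk_size,
            parent_pool_size=self.parent_pool_size,
        )
        for name, v in counts.items():
            if v <= 0:
                raise ValueError(f"{name} must be positive (got {v})")
        if self.n_induced_mutations < 0 or self.n_artifact_sites < 0:
            raise ValueError("variant counts must be non-negative")
        if self.bulk_size > self.f2_size:
            raise ValueError("bulk_size must not exceed f2_size")
        if not 0 <= self.error_rate < 0.5:
            raise ValueError("error_rate must lie in [0, 0.5)")
        if self.depth_lambda <= 0:
            raise ValueError("depth_lambda must be positive")
        if self.cm_per_mb < 0:
            raise ValueError("cm_per_mb must be non-negative")
        means = {k: self.phenotype_model[k][0] for k in GENOTYPE_CLASSES}
        if not means["hom_mut"] <= means["het"] <= means["hom_wt"]:
            raise ValueError(
                "semi-dominance requires mutant mean <= het mean <= wild-type mean"
            )
        if not 0 <= self.causal_chrom_index < self.n_chromosomes:
            raise ValueError("causal chromosome index out of range")
        if not 0 <= self.causal_gene_index < self.genes_per_chromosome:
            raise ValueError("causal gene index out of range")
        n_codons = sum(_CDS_PIECES) // 3
        # codon must be a real, non-initiator, non-stop codon of the CDS
        if not 1 < self.causal_codon < n_codons:
            raise ValueError(
                f"causal codon {self.causal_codon} does not fall inside the "
                f"simulated CDS ({n_codons} codons)"
            )
        gene_footprint = (
            _UTR5_LEN + _UTR3_LEN + 2 * _INTRON_LEN + sum(_CDS_PIECES)
        )
        if self.chrom_length_bp // self.genes_per_chromosome < gene_footprint + 200:
            raise ValueError("chromosome too short for the requested gene count")


@dataclass
class SimulatedPlant:
    """One F2 individual: phased parental-origin alleles, height and class."""

    plant_id: str
    gametes: np.ndarray  # (2, n_meiotic_sites) uint8, 1 = mutant-parent origin
    height_cm: float
    causal_genotype_class: str

    @property
    def dosage(self) -> np.ndarray:
        """Mutant-allele dosage (0/1/2) per meiotic variant site."""
        return self.gametes.sum(axis=0)


@dataclass
class Simulation:
    """Everything produced by :func:`simulate_cross`."""

    config: CrossConfig
    genome: dict[str, np.ndarray]
    genes: list[GeneModel]
    variants: pd.DataFrame  # chrom,pos,ref,alt,vtype,origin (sorted)
    causal_index: int  # row of the causal variant in `variants`
    f2: list[SimulatedPlant]
    f1_het_fraction: float
    rng: np.random.Generator

    @property
    def causal(self) -> pd.Series:
        return self.variants.iloc[self.causal_index]

    @property
    def causal_gene(self) -> GeneModel:
        row = self.causal
        for g in self.genes:
            if g.chrom == row.chrom and g.cds_offset_of(int(row.pos)) is not None:
                return g
        raise RuntimeError("causal variant not inside any CDS")

    def dosage_matrix(self) -> np.ndarray:
        """(n_plants, n_meiotic_sites) mutant-allele dosages."""
        return np.stack([p.dosage for p in self.f2])

    def meiotic_rows(self) -> np.ndarray:
        return (self.variants["origin"] != "artifact").to_numpy()


@dataclass
class Bulks:
    """Phenotype-extreme bulks plus clonal parental pools.

    Frequencies are mutant-allele (alt) frequencies per meiotic variant site.
    """

    df_plants: list[str]
    wt_plants: list[str]
    freqs: dict[str, np.ndarray]  # sample -> per-site alt frequency


# --------------------------------------------------------------------------
# gene and genome construction
# --------------------------------------------------------------------------

def _gene_segments() -> list[tuple[str, int]]:
    return [
        ("utr5", _UTR5_LEN),
        ("cds", _CDS_PIECES[0]),
        ("intron", _INTRON_LEN),
        ("cds", _CDS_PIECES[1]),
        ("intron", _INTRON_LEN),
        ("cds", _CDS_PIECES[2]),
        ("utr3", _UTR3_LEN),
    ]


def _random_seq(rng: np.random.Generator, n: int) -> str:
    return _BASES[rng.integers(0, 4, n)].tobytes().decode()


def _build_gene(
    gene_id: str,
    chrom: str,
    strand: str,
    start0: int,
    rng: np.random.Generator,
    causal_codon: int | None = None,
) -> tuple[GeneModel, str]:
    """Construct one gene and its transcript-orientation genomic sequence.

    When ``causal_codon`` is given, the degron codon block GWPPV is planted
    starting at that codon, so a G->A substitution at the codon's middle base
    yields Gly->Glu (GGA>GAA) and an EWPPV motif.
    """
    n_codons = sum(_CDS_PIECES) // 3
    codons = [_SAFE_CODONS[i] for i in rng.integers(0, len(_SAFE_CODONS), n_codons)]
    codons[0] = "ATG"
    codons[-1] = "TAA"
    if causal_codon is not None:
        block = DEGRON_CODONS
        codons[causal_codon - 1 : causal_codon - 1 + len(block)] = list(block)
    cds_seq = "".join(codons)

    parts: list[str] = []
    cds_used = 0
    for kind, ln in _gene_segments():
        if kind == "cds":
            parts.append(cds_seq[cds_used : cds_used + ln])
            cds_used += ln
        elif kind == "intron":
            inner = _random_seq(rng, ln - 4)
            parts.append("GT" + inner + "AG")
        else:
            parts.append(_random_seq(rng, ln))
    transcript = "".join(parts)
    total = len(transcript)

    # map transcript-orientation segments to genomic intervals
    intervals: list[tuple[str, int, int]] = []  # (kind, start1, end1) transcript order
    off = 0
    for kind, ln in _gene_segments():
        if strand == "+":
            s0 = start0 + off
            intervals.append((kind, s0 + 1, s0 + ln))
        else:
            e0 = start0 + total - off  # exclusive genomic end
            intervals.append((kind, e0 - ln + 1, e0))
        off += ln

    model = GeneModel(gene_id=gene_id, chrom=chrom, strand=strand)
    for kind, s, e in intervals:
        if kind == "cds":
            model.cds.append((s, e))
        elif kind == "utr5":
            model.utr5.append((s, e))
        elif kind == "utr3":
            model.utr3.append((s, e))
    # exons: merge consecutive non-intron segments
    exon: list[tuple[int, int]] = []
    for kind, s, e in intervals:
        if kind == "intron":
            if exon:
                model.exons.append((min(x[0] for x in exon), max(x[1] for x in exon)))
                exon = []
        else:
            exon.append((s, e))
    if exon:
        model.exons.append((min(x[0] for x in exon), max(x[1] for x in exon)))
    model.validate()
    genomic_seq = transcript if strand == "+" else revcomp(transcript)
    return model, genomic_seq


def _place_genes(config: CrossConfig, genome: dict[str, np.ndarray],
                 rng: np.random.Generator) -> list[GeneModel]:
    footprint = _UTR5_LEN + _UTR3_LEN + 2 * _INTRON_LEN + sum(_CDS_PIECES)
    genes: list[GeneModel] = []
    for ci, chrom in enumerate(config.chrom_names):
        slot = config.chrom_length_bp // config.genes_per_chromosome
        for gi in range(config.genes_per_chromosome):
            margin = 100
            lo = gi * slot + margin
            hi = (gi + 1) * slot - footprint - margin
            start0 = int(rng.integers(lo, hi))
            strand = "+" if gi % 2 == 0 else "-"
            causal = (
                ci == config.causal_chrom_index and gi == config.causal_gene_index
            )
            model, seq = _build_gene(
                f"gene_{chrom}_{gi:03d}", chrom, strand, start0, rng,
                causal_codon=config.causal_codon if causal else None,
            )
            genome[chrom][start0 : start0 + footprint] = np.frombuffer(
                seq.encode(), dtype=np.uint8
            )
            genes.append(model)
    return genes


def _causal_site(config: CrossConfig, genes: Sequence[GeneModel]) -> tuple[str, int, str, str]:
    """Genomic (chrom, pos, ref, alt) of the planted causal SNP.

    The SNP hits the middle base of the degron's Gly codon (GGA -> GAA).
    """
    idx = config.causal_chrom_index * config.genes_per_chromosome + config.causal_gene_index
    gene = genes[idx]
    cds_off = (config.causal_codon - 1) * 3 + 1  # middle base, 0-based CDS offset
    pos = gene.genomic_of_cds_offset(cds_off)
    if gene.strand == "+":
        return gene.chrom, pos, "G", "A"
    return gene.chrom, pos, "C", "T"


# --------------------------------------------------------------------------
# variants
# --------------------------------------------------------------------------

def _draw_variants(config: CrossConfig, genome: dict[str, np.ndarray],
                   genes: Sequence[GeneModel], rng: np.random.Generator
                   ) -> tuple[pd.DataFrame, int]:
    chroms = config.chrom_names
    L = config.chrom_length_bp
    causal_chrom, causal_pos, causal_ref, causal_alt = _causal_site(config, genes)

    rows = []
    used: set[tuple[str, int]] = {(causal_chrom, causal_pos)}
    rows.append(dict(chrom=causal_chrom, pos=causal_pos, ref=causal_ref,
                     alt=causal_alt, vtype="SNP", origin="causal"))

    def draw_position() -> tuple[str, int]:
        while True:
            chrom = chroms[int(rng.integers(0, len(chroms)))]
            pos = int(rng.integers(10, L - 10)) + 1
            if (chrom, pos) not in used:
                used.add((chrom, pos))
                return chrom, pos

    def snv(chrom: str, pos: int) -> tuple[str, str]:
        ref = chr(genome[chrom][pos - 1])
        alt = "ACGT"[int(rng.integers(0, 4))]
        while alt == ref:
            alt = "ACGT"[int(rng.integers(0, 4))]
        return ref, alt

    for _ in range(config.n_marker_snps):
        chrom, pos = draw_position()
        ref, alt = snv(chrom, pos)
        rows.append(dict(chrom=chrom, pos=pos, ref=ref, alt=alt,
                         vtype="SNP", origin="marker"))

    n_indels = int(round(config.n_induced_mutations * config.indel_fraction))
    for i in range(config.n_induced_mutations):
        chrom, pos = draw_position()
        if i < n_indels:
            k = int(rng.integers(1, 4))  # deletion of 1-3 bp
            ref = "".join(chr(b) for b in genome[chrom][pos - 1 : pos + k])
            rows.append(dict(chrom=chrom, pos=pos, ref=ref, alt=ref[0],
                             vtype="InDel", origin="induced"))
        else:
            ref, alt = snv(chrom, pos)
            rows.append(dict(chrom=chrom, pos=pos, ref=ref, alt=alt,
                             vtype="SNP", origin="induced"))

    for _ in range(config.n_artifact_sites):
        chrom, pos = draw_position()
        ref, alt = snv(chrom, pos)
        rows.append(dict(chrom=chrom, pos=pos, ref=ref, alt=alt,
                         vtype="SNP", origin="artifact"))

    df = pd.DataFrame(rows).sort_values(["chrom", "pos"]).reset_index(drop=True)
    causal_index = int(df.index[(df["origin"] == "causal")][0])
    return df, causal_index


# --------------------------------------------------------------------------
# meiosis, phenotypes, bulks, sequencing
# --------------------------------------------------------------------------

def _gamete_origins(rng: np.random.Generator, positions: np.ndarray,
                    chrom_len: int, morgans: float) -> np.ndarray:
    """Parental-origin vector for one gamete along one chromosome."""
    k = rng.poisson(morgans)
    start = int(rng.integers(0, 2))
    if k == 0:
        return np.full(positions.shape, start, dtype=np.uint8)
    breaks = np.sort(rng.uniform(0, chrom_len, k))
    return ((start + np.searchsorted(breaks, positions)) % 2).astype(np.uint8)


def simulate_cross(config: CrossConfig, rng: np.random.Generator | None = None) -> Simulation:
    """Simulate parents, F2 meiosis and phenotypes.

    Both parents are fully homozygous; every F1 is heterozygous at every
    segregating site.  F2 gametes carry Poisson(genetic length in Morgans)
    crossovers placed uniformly, without interference.
    """
    config.validate()
    if rng is None:
        rng = np.random.default_rng(config.seed)

    genome = {
        chrom: _BASES[rng.integers(0, 4, config.chrom_length_bp)].copy()
        for chrom in config.chrom_names
    }
    genes = _place_genes(config, genome, rng)
    variants, causal_index = _draw_variants(config, genome, genes, rng)

    meiotic = variants[variants["origin"] != "artifact"]
    # parents: wild type carries ref (origin 0) everywhere, mutant carries alt
    wt_allele = np.zeros(len(meiotic), dtype=np.uint8)
    mut_allele = np.ones(len(meiotic), dtype=np.uint8)
    f1_het_fraction = float(np.mean(wt_allele != mut_allele)) if len(meiotic) else 1.0

    # per-chromosome site slices (meiotic variants are sorted by chrom,pos)
    morgans = config.chrom_length_bp / 1e6 * config.cm_per_mb / 100.0
    chrom_slices: list[tuple[np.ndarray, slice]] = []
    offset = 0
    for chrom in config.chrom_names:
        pos = meiotic.loc[meiotic["chrom"] == chrom, "pos"].to_numpy()
        chrom_slices.append((pos, slice(offset, offset + len(pos))))
        offset += len(pos)

    causal_meiotic_idx = int(np.searchsorted(
        np.flatnonzero((variants["origin"] != "artifact").to_numpy()),
        causal_index,
    ))

    model = config.phenotype_model
    plants: list[SimulatedPlant] = []
    n_sites = len(meiotic)
    for i in range(config.f2_size):
        gametes = np.empty((2, n_sites), dtype=np.uint8)
        for gi in range(2):
            for pos, sl in chrom_slices:
                gametes[gi, sl] = _gamete_origins(
                    rng, pos, config.chrom_length_bp, morgans
                )
        dose = int(gametes[:, causal_meiotic_idx].sum())
        cls = GENOTYPE_CLASSES[dose]
        mean, sd = model[cls]
        height = float(rng.normal(mean, sd))
        plants.append(SimulatedPlant(
            plant_id=f"F2_{i + 1:04d}", gametes=gametes,
            height_cm=height, causal_genotype_class=cls,
        ))

    return Simulation(
        config=config, genome=genome, genes=genes, variants=variants,
        causal_index=causal_index, f2=plants,
        f1_het_fraction=f1_het_fraction, rng=rng,
    )


def assign_bulks(f2: Sequence[SimulatedPlant], config: CrossConfig) -> Bulks:
    """Select phenotype-extreme bulks by height rank (ties broken by id).

    Df-pool = the ``bulk_size`` shortest plants, WT-pool = the tallest;
    parental pools are clonal, so their allele frequencies are 0 and 1.
    """
    if not f2:
        raise ValueError("empty F2 population")
    if config.bulk_size > len(f2):
        raise ValueError("bulk_size exceeds population size")
    by_height = sorted(f2, key=lambda p: (p.height_cm, p.plant_id))
    dwarf = by_height[: config.bulk_size]
    by_height_desc = sorted(f2, key=lambda p: (-p.height_cm, p.plant_id))
    tall = by_height_desc[: config.bulk_size]

    def pool_freq(plants: Sequence[SimulatedPlant]) -> np.ndarray:
        return np.stack([p.dosage for p in plants]).mean(axis=0) / 2.0

    n_sites = f2[0].gametes.shape[1]
    freqs = {
        "df_bulk": pool_freq(dwarf),
        "wt_bulk": pool_freq(tall),
        "wt_parent": np.zeros(n_sites),
        "mut_parent": np.ones(n_sites),
    }
    return Bulks(
        df_plants=[p.plant_id for p in dwarf],
        wt_plants=[p.plant_id for p in tall],
        freqs=freqs,
    )


def sample_pool_depths(
    freqs: np.ndarray,
    depth_lambda: float,
    error_rate: float,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray]:
    """Sequence one pool: Poisson depth, binomial allele sampling with error.

    Per site, depth ~ Poisson(depth_lambda) and alt reads ~ Binomial(depth,
    f(1-e) + (1-f)e) with f the pool alt frequency and e the miscall rate.
    Zero-depth sites are returned as (0, 0).
    """
    freqs = np.asarray(freqs, dtype=float)
    depth = rng.poisson(depth_lambda, size=freqs.shape)
    p = freqs * (1 - error_rate) + (1 - freqs) * error_rate
    alt = rng.binomial(depth, p)
    return depth - alt, alt


# artifact sites emulate residual parental heterozygosity: the affected
# parent pool sequences at allele frequency 1/2 and the segregating bulks
# at roughly 1/4 (one F1 in two carries the allele).
_ARTIFACT_FREQS = {
    "wt_het": {"wt_parent": 0.5, "mut_parent": 0.0, "wt_bulk": 0.25, "df_bulk": 0.25},
    "mut_het": {"wt_parent": 0.0, "mut_parent": 0.5, "wt_bulk": 0.25, "df_bulk": 0.25},
}


def build_variant_table(sim: Simulation, bulks: Bulks,
                        rng: np.random.Generator | None = None) -> pd.DataFrame:
    """Attach per-sample (ref, alt) read depths to every variant row."""
    if rng is None:
        rng = sim.rng
    cfg = sim.config
    table = sim.variants.copy()
    meiotic_mask = sim.meiotic_rows()
    n = len(table)

    artifact_rows = np.flatnonzero(~meiotic_mask)
    artifact_kind = ["wt_het" if i % 2 == 0 else "mut_het"
                     for i in range(len(artifact_rows))]

    for sample in SAMPLES:
        freqs = np.zeros(n)
        freqs[meiotic_mask] = bulks.freqs[sample]
        for row, kind in zip(artifact_rows, artifact_kind):
            freqs[row] = _ARTIFACT_FREQS[kind][sample]
        ref_d, alt_d = sample_pool_depths(
            freqs, cfg.depth_lambda, cfg.error_rate, rng
        )
        table[f"{sample}_ref"] = ref_d
        table[f"{sample}_alt"] = alt_d
    return table


def simulate_backcross_heights(
    config: CrossConfig,
    recurrent_parent: str,
    n: int,
    rng: np.random.Generator,
) -> tuple[str, np.ndarray]:
    """Heights of an F1 x parent backcross at the causal locus.

    ``recurrent_parent`` is "wt" (heterozygote/tall 1:1) or "mut"
    (heterozygote/dwarf 1:1).  Both directions are exposed and labelled
    explicitly as (F1 x wild-type) and (F1 x mutant).
    """
    if recurrent_parent not in ("wt", "mut"):
        raise ValueError("recurrent_parent must be 'wt' or 'mut'")
    f1_allele = rng.integers(0, 2, n)  # mutant-allele dose from the F1 gamete
    parent_allele = 0 if recurrent_parent == "wt" else 1
    dose = f1_allele + parent_allele
    classes = np.array(["hom_wt", "het", "hom_mut"])[dose]
    heights = np.array([
        rng.normal(*config.phenotype_model[c]) for c in classes
    ])
    label = "F1 x wild-type" if recurrent_parent == "wt" else "F1 x mutant"
    return label, heights


# --------------------------------------------------------------------------
# fixture files
# --------------------------------------------------------------------------

def write_phenotypes(plants: Sequence[SimulatedPlant], path: str | Path,
                     population: str = "F2") -> None:
    with Path(path).open("w") as fh:
        fh.write("population\tplant_id\theight_cm\n")
        for p in plants:
            fh.write(f"{population}\t{p.plant_id}\t{p.height_cm:.2f}\n")


def read_phenotypes(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    expected = {"population", "plant_id", "height_cm"}
    if not expected.issubset(df.columns):
        raise ValueError(f"phenotype table must have columns {sorted(expected)}")
    return df


def write_fixture_set(sim: Simulation, table: pd.DataFrame,
                      outdir: str | Path, overwrite: bool = False) -> dict[str, Path]:
    """Write reference FASTA, GFF3, 4-sample VCF and phenotype TSV."""
    from .vcfio import write_vcf

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "fasta": outdir / "reference.fa",
        "gff3": outdir / "genes.gff3",
        "vcf": outdir / "variants.vcf",
        "phenotypes": outdir / "phenotypes.tsv",
    }
    for p in paths.values():
        if p.exists() and not overwrite:
            raise FileExistsError(f"{p} exists; pass overwrite=True to replace")
    write_fasta(sim.genome, paths["fasta"])
    write_gff3(sim.genes, paths["gff3"])
    write_vcf(table, paths["vcf"],
              contigs={c: sim.config.chrom_length_bp for c in sim.config.chrom_names})
    write_phenotypes(sim.f2, paths["phenotypes"])
    return paths
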