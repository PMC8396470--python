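"""Variant-effect annotation against gene models.

Each variant is assigned a genic region (precedence: splicing > exonic >
UTR5/UTR3 > intronic > upstream/downstream > intergenic), coding variants
get a codon-level consequence by translating the spliced, strand-oriented
CDS, and candidate proteins are screened for disruption of the Aux/IAA
domain-II degron motif GWPPV, whose Gly->Glu conversion (GWPPV -> EWPPV)
stabilizes the repressor and produces the semi-dominant dwarf phenotype.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import pandas as pd
from Bio.Seq import Seq

from .genome import GeneModel, fetch, revcomp

DEGRON_MOTIF = "GWPPV"

REGION_PRECEDENCE = (
    "splicing", "exonic", "utr5", "utr3", "intronic",
    "upstream", "downstream", "intergenic",
)

FUNCTIONAL_REGIONS = frozenset(
    {"upstream", "utr5", "exonic", "splicing", "utr3", "downstream"}
)


class ReferenceMismatchError(ValueError):
    """The variant's REF allele disagrees with the reference sequence."""


@dataclass
class EffectAnnotation:
    chrom: str
    pos: int
    ref: str
    alt: str
    gene_id: str | None
    region: str
    coding_effect: str  # synonymous|missense|nonsense|frameshift|inframe_indel|none
    aa_change: str | None = None
    codon_change: str | None = None


def _overlaps(a_start: int, a_end: int, b_start: int, b_end: int) -> bool:
    return a_start <= b_end and b_start <= a_end


def _region_in_gene(pos: int, end: int, gene: GeneModel,
                    flank_bp: int, splice_window: int) -> str | None:
    """Region of the variant span [pos, end] relative to one gene."""
    gs, ge = gene.span
    in_exon = any(_overlaps(pos, end, s, e) for s, e in gene.exons)
    introns = gene.introns()
    in_intron = any(_overlaps(pos, end, s, e) for s, e in introns)
    for s, e in introns:
        donor = (s, min(e, s + splice_window - 1))
        acceptor = (max(s, e - splice_window + 1), e)
        if _overlaps(pos, end, *donor) or _overlaps(pos, end, *acceptor):
            return "splicing"
    if in_exon and in_intron:  # spans an exon-intron boundary
        return "splicing"
    if any(_overlaps(pos, end, s, e) for s, e in gene.cds):
        return "exonic"
    if any(_overlaps(pos, end, s, e) for s, e in gene.utr5):
        return "utr5"
    if any(_overlaps(pos, end, s, e) for s, e in gene.utr3):
        return "utr3"
    if in_intron or _overlaps(pos, end, gs, ge):
        return "intronic"
    if gene.strand == "+":
        upstream = (gs - flank_bp, gs - 1)
        downstream = (ge + 1, ge + flank_bp)
    else:
        upstream = (ge + 1, ge + flank_bp)
        downstream = (gs - flank_bp, gs - 1)
    if _overlaps(pos, end, *upstream):
        return "upstream"
    if _overlaps(pos, end, *downstream):
        return "downstream"
    return None


def classify_region(chrom: str, pos: int, ref: str,
                    genes: Sequence[GeneModel],
                    flank_bp: int = 2000,
                    splice_window: int = 2) -> tuple[str, str | None]:
    """Best (region, gene_id) over all genes by the precedence order."""
    if not any(g.chrom == chrom for g in genes):
        warnings.warn(f"variant on unknown chromosome {chrom!r}; "
                      "classified intergenic", stacklevel=2)
        return "intergenic", None
    end = pos + max(len(ref) - 1, 0)
    best = ("intergenic", None)
    best_rank = REGION_PRECEDENCE.index("intergenic")
    for gene in genes:
        if gene.chrom != chrom:
            continue
        region = _region_in_gene(pos, end, gene, flank_bp, splice_window)
        if region is None:
            continue
        rank = REGION_PRECEDENCE.index(region)
        if rank < best_rank:
            best, best_rank = (region, gene.gene_id), rank
    return best


def coding_consequence(chrom: str, pos: int, ref: str, alt: str,
                       gene: GeneModel, genome: Mapping[str, object]
                       ) -> tuple[str, str | None, str | None]:
    """(coding_effect, codon_change, aa_change) of a CDS-overlapping variant.

    SNVs are translated codon-wise with the standard genetic code; indels
    are frameshift when the length change is not a multiple of 3, otherwise
    in-frame.  A REF allele that disagrees with the reference sequence is a
    data-integrity error.
    """
    observed = fetch(genome, chrom, pos - 1, pos - 1 + len(ref)).upper()
    if observed != ref.upper():
        raise ReferenceMismatchError(
            f"{chrom}:{pos} expected REF {ref!r}, reference has {observed!r}"
        )
    if len(ref) != len(alt):
        diff = abs(len(ref) - len(alt))
        return ("frameshift" if diff % 3 else "inframe_indel"), None, None

    off = gene.cds_offset_of(pos)
    if off is None:
        return "none", None, None
    base = alt.upper() if gene.strand == "+" else revcomp(alt.upper())
    cds = gene.cds_sequence(genome).upper()
    ci = off // 3
    codon_ref = cds[ci * 3 : ci * 3 + 3]
    within = off % 3
    codon_alt = codon_ref[:within] + base + codon_ref[within + 1 :]
    aa_ref = str(Seq(codon_ref).translate())
    aa_alt = str(Seq(codon_alt).translate())
    if aa_alt == aa_ref:
        effect = "synonymous"
    elif aa_alt == "*":
        effect = "nonsense"
    else:
        effect = "missense"
    return effect, f"{codon_ref}>{codon_alt}", f"{aa_ref}{ci + 1}{aa_alt}"


def protein_pair(gene: GeneModel, genome: Mapping[str, object],
                 pos: int, ref: str, alt: str) -> tuple[str, str]:
    """Reference and mutant protein for an SNV inside the CDS."""
    if len(ref) != 1 or len(alt) != 1:
        raise ValueError("protein_pair supports SNVs only")
    off = gene.cds_offset_of(pos)
    if off is None:
        raise ValueError(f"{gene.gene_id}: position {pos} not in CDS")
    cds = gene.cds_sequence(genome).upper()
    base = alt.upper() if gene.strand == "+" else revcomp(alt.upper())
    mutant = cds[:off] + base + cds[off + 1 :]
    return (str(Seq(cds).translate(to_stop=False)),
            str(Seq(mutant).translate(to_stop=False)))


@dataclass
class DegronStatus:
    status: str  # "intact" | "altered" | "absent"
    mutant_motif: str | None = None


def degron_check(protein_before: str, protein_after: str,
                 motif: str = DEGRON_MOTIF) -> DegronStatus:
    """Report whether the degron motif survives a protein change."""
    i = protein_before.find(motif)
    if i < 0:
        return DegronStatus("absent")
    after = protein_after[i : i + len(motif)]
    if after == motif:
        return DegronStatus("intact")
    return DegronStatus("altered", mutant_motif=after)


def annotate_table(table: pd.DataFrame, genes: Sequence[GeneModel],
                   genome: Mapping[str, object],
                   flank_bp: int = 2000, splice_window: int = 2) -> pd.DataFrame:
    """Annotate every variant row with region, gene and coding effect."""
    by_id = {g.gene_id: g for g in genes}
    rows = []
    for row in table.itertuples(index=False):
        region, gene_id = classify_region(
            row.chrom, int(row.pos), row.ref, genes, flank_bp, splice_window
        )
        effect, codon_change, aa_change = "none", None, None
        if region == "exonic" and gene_id is not None:
            effect, codon_change, aa_change = coding_consequence(
                row.chrom, int(row.pos), row.ref, row.alt, by_id[gene_id], genome
            )
        rows.append(dict(region=region, gene_id=gene_id, effect=effect,
                         codon_change=codon_change, aa_change=aa_change))
    ann = pd.DataFrame(rows, index=table.index)
    return ann
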