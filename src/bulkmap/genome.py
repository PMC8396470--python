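"""Gene models, sequence utilities and FASTA/GFF3 input-output.

Coordinates follow the GFF3/VCF convention: 1-based, inclusive intervals in
all on-disk files and in :class:`GeneModel`.  Internal slice arithmetic is
0-based half-open.  Interval lists on a :class:`GeneModel` are ordered
5'-to-3' in transcript orientation, so on the minus strand they run from the
highest genomic coordinate downwards.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np

_COMPLEMENT = bytes.maketrans(b"ACGTacgtN", b"TGCAtgcaN")

Interval = tuple[int, int]


def revcomp(seq: str) -> str:
    """Reverse complement of a DNA string."""
    return seq.encode().translate(_COMPLEMENT).decode()[::-1]


def fetch(genome: Mapping[str, object], chrom: str, start0: int, end0: int) -> str:
    """Extract ``[start0, end0)`` from one chromosome of a genome mapping.

    Accepts chromosomes stored as numpy byte arrays (the simulator's native
    representation), plain strings, or pyfaidx records.
    """
    seq = genome[chrom]
    if isinstance(seq, np.ndarray):
        return seq[start0:end0].tobytes().decode()
    if isinstance(seq, str):
        return seq[start0:end0]
    return str(seq[start0:end0])


@dataclass
class GeneModel:
    """Strand-aware exon/CDS/UTR structure of a protein-coding gene.

    All interval lists are 1-based inclusive and sorted 5'-to-3' in
    transcript orientation.
    """

    gene_id: str
    chrom: str
    strand: str
    exons: list[Interval] = field(default_factory=list)
    cds: list[Interval] = field(default_factory=list)
    utr5: list[Interval] = field(default_factory=list)
    utr3: list[Interval] = field(default_factory=list)

    @property
    def span(self) -> Interval:
        """Genomic (start, end) of the whole gene, 1-based inclusive."""
        starts = [s for s, _ in self.exons]
        ends = [e for _, e in self.exons]
        return min(starts), max(ends)

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.cds)

    def cds_genomic(self) -> list[Interval]:
        """CDS intervals in ascending genomic order."""
        return sorted(self.cds)

    def introns(self) -> list[Interval]:
        """Intron intervals (ascending genomic order)."""
        ex = sorted(self.exons)
        out = []
        for (s1, e1), (s2, _) in zip(ex, ex[1:]):
            if s2 > e1 + 1:
                out.append((e1 + 1, s2 - 1))
        return out

    def validate(self) -> None:
        if self.strand not in "+-":
            raise ValueError(f"{self.gene_id}: strand must be + or -")
        for name in ("exons", "cds", "utr5", "utr3"):
            ivs = getattr(self, name)
            for s, e in ivs:
                if s > e or s < 1:
                    raise ValueError(f"{self.gene_id}: bad {name} interval ({s},{e})")
            genomic = sorted(ivs)
            for (_, e1), (s2, _) in zip(genomic, genomic[1:]):
                if s2 <= e1:
                    raise ValueError(f"{self.gene_id}: overlapping {name} intervals")
            transcript = genomic if self.strand == "+" else genomic[::-1]
            if list(ivs) != transcript:
                raise ValueError(
                    f"{self.gene_id}: {name} not sorted in transcript orientation"
                )
        if self.cds and self.cds_length % 3 != 0:
            raise ValueError(f"{self.gene_id}: CDS length not divisible by 3")

    def cds_sequence(self, genome: Mapping[str, object]) -> str:
        """Spliced CDS, 5'-to-3' in transcript orientation."""
        parts = [fetch(genome, self.chrom, s - 1, e) for s, e in self.cds_genomic()]
        seq = "".join(parts)
        return revcomp(seq) if self.strand == "-" else seq

    def cds_offset_of(self, pos: int) -> int | None:
        """0-based offset of genomic position ``pos`` within the spliced CDS.

        Returns None when the position is not inside any CDS interval.
        """
        acc = 0
        for s, e in self.cds:  # transcript order
            if s <= pos <= e:
                return acc + (pos - s if self.strand == "+" else e - pos)
            acc += e - s + 1
        return None

    def genomic_of_cds_offset(self, off: int) -> int:
        """Genomic 1-based position of CDS offset ``off`` (0-based)."""
        acc = 0
        for s, e in self.cds:
            ln = e - s + 1
            if off < acc + ln:
                d = off - acc
                return s + d if self.strand == "+" else e - d
            acc += ln
        raise IndexError(f"CDS offset {off} beyond CDS length {acc}")


# --------------------------------------------------------------------------
# FASTA / GFF3 / TSV writers and readers
# --------------------------------------------------------------------------

def write_fasta(genome: Mapping[str, object], path: str | Path, width: int = 60) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for chrom in genome:
            seq = fetch(genome, chrom, 0, len(genome[chrom]))
            fh.write(f">{chrom}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i : i + width] + "\n")


def read_fasta(path: str | Path) -> Mapping[str, object]:
    """Open a FASTA as a genome mapping with lazy random access."""
    import pyfaidx

    return pyfaidx.Fasta(str(path))


def write_gff3(genes: Sequence[GeneModel], path: str | Path, source: str = "bulkmap") -> None:
    path = Path(path)

    def line(chrom, ftype, s, e, strand, attrs, phase="."):
        return f"{chrom}\t{source}\t{ftype}\t{s}\t{e}\t.\t{strand}\t{phase}\t{attrs}\n"

    with path.open("w") as fh:
        fh.write("##gff-version 3\n")
        for g in genes:
            gs, ge = g.span
            fh.write(line(g.chrom, "gene", gs, ge, g.strand, f"ID={g.gene_id}"))
            mrna = f"{g.gene_id}.t1"
            fh.write(line(g.chrom, "mRNA", gs, ge, g.strand, f"ID={mrna};Parent={g.gene_id}"))
            for ftype, ivs in (
                ("exon", g.exons),
                ("five_prime_UTR", g.utr5),
                ("CDS", g.cds),
                ("three_prime_UTR", g.utr3),
            ):
                # phase for CDS: offset to the next codon start
                acc = 0
                for s, e in ivs:
                    phase = str((3 - acc % 3) % 3) if ftype == "CDS" else "."
                    fh.write(line(g.chrom, ftype, s, e, g.strand, f"Parent={mrna}", phase))
                    acc += e - s + 1


def read_gff3(path: str | Path) -> list[GeneModel]:
    """Parse gene models from a GFF3 file via gffutils."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique")
    genes = []
    for g in db.features_of_type("gene"):
        model = GeneModel(gene_id=g.id, chrom=g.seqid, strand=g.strand)
        for ftype, attr in (
            ("exon", "exons"),
            ("CDS", "cds"),
            ("five_prime_UTR", "utr5"),
            ("three_prime_UTR", "utr3"),
        ):
            ivs = sorted((f.start, f.end) for f in db.children(g, featuretype=ftype))
            if g.strand == "-":
                ivs = ivs[::-1]
            setattr(model, attr, ivs)
        model.validate()
        genes.append(model)
    genes.sort(key=lambda m: (m.chrom, m.span[0]))
    return genes
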