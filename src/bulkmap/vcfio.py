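"""VCF input/output for the four-sample pooled design (pysam-backed).

The on-disk convention is VCF 4.2 with a per-sample AD field holding
(ref_depth, alt_depth); samples appear in the fixed order
wt_parent, mut_parent, wt_bulk, df_bulk.
"""

from __future__ import annotations

from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd
import pysam

from .simcross import SAMPLES


def write_vcf(table: pd.DataFrame, path: str | Path,
              contigs: Mapping[str, int],
              samples: Sequence[str] = SAMPLES) -> None:
    """Write a variant table with per-sample depth columns as a VCF.

    ``table`` needs columns chrom, pos, ref, alt and, for every sample,
    ``{sample}_ref`` / ``{sample}_alt`` depth columns.
    """
    header = pysam.VariantHeader()
    header.add_line('##FORMAT=<ID=AD,Number=R,Type=Integer,'
                    'Description="Allelic depths (ref,alt)">')
    for chrom, length in contigs.items():
        header.contigs.add(chrom, length=length)
    for s in samples:
        header.add_sample(s)

    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for row in table.itertuples(index=False):
            rec = vcf.new_record(
                contig=row.chrom, start=int(row.pos) - 1,
                alleles=(row.ref, row.alt),
            )
            for s in samples:
                rec.samples[s]["AD"] = (
                    int(getattr(row, f"{s}_ref")), int(getattr(row, f"{s}_alt"))
                )
            vcf.write(rec)


def read_vcf(path: str | Path, samples: Sequence[str] | None = None) -> pd.DataFrame:
    """Read a VCF with AD fields back into the flat variant-table layout."""
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        file_samples = list(vcf.header.samples)
        use = list(samples) if samples is not None else file_samples
        missing = set(use) - set(file_samples)
        if missing:
            raise KeyError(f"samples not in VCF: {sorted(missing)}")
        for rec in vcf:
            if len(rec.alts or ()) != 1:
                raise ValueError(f"only biallelic records supported ({rec.contig}:{rec.pos})")
            row = dict(
                chrom=rec.contig, pos=rec.pos, ref=rec.ref, alt=rec.alts[0],
                vtype="SNP" if len(rec.ref) == 1 and len(rec.alts[0]) == 1 else "InDel",
            )
            for s in use:
                ad = rec.samples[s]["AD"]
                row[f"{s}_ref"], row[f"{s}_alt"] = int(ad[0]), int(ad[1])
            rows.append(row)
    return pd.DataFrame(rows)
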