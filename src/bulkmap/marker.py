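"""Allele-specific PCR (AS-PCR) marker design for SNP genotyping.

The allele-specific (upstream) primer ends exactly on the SNP so its
3'-terminal base matches only the targeted allele; one additional
artificial mismatch is placed at the third base from the 3' end to
destabilize extension from the wrong allele.  A common reverse primer is
placed to yield a chosen product length.  The in-silico PCR model requires
a perfect match of a primer's final three bases for extension, which is
the discrimination rule the artificial mismatch sharpens.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np

from .genome import fetch, revcomp

# strong destabilizing transversion for the artificial mismatch
MISMATCH_MAP = {"A": "C", "C": "A", "G": "T", "T": "G"}

# the SNP base counts as position 1 from the 3' end; the mismatch goes at 3
MISMATCH_OFFSET = 3


class PrimerDesignError(ValueError):
    pass


def wallace_tm(seq: str) -> float:
    """Wallace-rule melting temperature: 2(A+T) + 4(G+C) degrees C."""
    s = seq.upper()
    at = s.count("A") + s.count("T")
    gc = s.count("G") + s.count("C")
    return 2.0 * at + 4.0 * gc


def _has_homopolymer(seq: str, run: int = 6) -> bool:
    count, prev = 0, ""
    for b in seq:
        count = count + 1 if b == prev else 1
        prev = b
        if count >= run:
            return True
    return False


@dataclass
class AsPcrDesign:
    chrom: str
    pos: int  # 1-based SNP position
    ref: str
    alt: str
    target_allele: str  # base the 3' end matches
    allele_specific_primer: str
    mismatch_pos: int  # from the 3' end, SNP base = 1
    common_primer: str
    product_length: int
    tm_allele_specific: float
    tm_common: float


def _fit_length(pick, base_len: int, tm_range: tuple[float, float],
                lo: int = 18, hi: int = 30) -> tuple[str, float]:
    """Choose a primer length whose Wallace Tm falls inside the window."""
    for ln in sorted(range(lo, hi + 1), key=lambda x: abs(x - base_len)):
        seq = pick(ln)
        if seq is None:
            continue
        tm = wallace_tm(seq)
        if tm_range[0] <= tm <= tm_range[1]:
            return seq, tm
    raise PrimerDesignError("no primer length satisfies the Tm window")


def design_as_primer(genome: Mapping[str, object], chrom: str, pos: int,
                     ref: str, alt: str, target: str = "alt",
                     primer_len: int = 22, product_len_target: int = 798,
                     tm_range: tuple[float, float] = (55.0, 65.0)
                     ) -> AsPcrDesign:
    """Design the allele-specific / common primer pair for one SNP.

    The allele-specific primer is the ``primer_len`` reference bases ending
    at the SNP, with the 3' base replaced by the targeted allele and the
    base at position 3 from the 3' end swapped by the fixed transversion
    map (A<->C, G<->T).  The common primer is a reverse-complement window
    whose 5' end sits ``product_len_target`` - 1 bases downstream of the
    allele-specific primer's 5' end, so the amplicon has exactly the
    requested length.  Primer lengths are adjusted within 18-30 nt to meet
    a 55-65 degree Wallace-rule Tm; homopolymer runs >= 6 are rejected.
    """
    if target not in ("ref", "alt"):
        raise ValueError("target must be 'ref' or 'alt'")
    allele = (alt if target == "alt" else ref).upper()
    if len(allele) != 1 or len(ref) != 1:
        raise PrimerDesignError("AS-PCR design supports SNPs only")
    chrom_len = len(genome[chrom])
    pos0 = pos - 1

    def pick_as(ln: int) -> str | None:
        if pos0 - ln + 1 < 0:
            return None
        window = fetch(genome, chrom, pos0 - ln + 1, pos0 + 1).upper()
        primer = list(window)
        primer[-1] = allele
        primer[-MISMATCH_OFFSET] = MISMATCH_MAP[primer[-MISMATCH_OFFSET]]
        return "".join(primer)

    if pos0 - primer_len + 1 < 0:
        raise PrimerDesignError("insufficient upstream flank for the primer")
    as_primer, tm_as = _fit_length(pick_as, primer_len, tm_range)
    if _has_homopolymer(as_primer):
        raise PrimerDesignError("homopolymer run under the allele-specific primer")

    as_len = len(as_primer)
    f_start0 = pos0 - as_len + 1
    r_end0 = f_start0 + product_len_target - 1  # 0-based plus-strand 5' end of reverse primer
    if r_end0 >= chrom_len:
        raise PrimerDesignError("insufficient downstream flank for the product")

    def pick_common(ln: int) -> str | None:
        start0 = r_end0 - ln + 1
        if start0 <= pos0:  # keep the reverse primer clear of the SNP
            return None
        return revcomp(fetch(genome, chrom, start0, r_end0 + 1).upper())

    common, tm_common = _fit_length(pick_common, primer_len, tm_range)
    if _has_homopolymer(common):
        raise PrimerDesignError("homopolymer run under the common primer")

    return AsPcrDesign(
        chrom=chrom, pos=pos, ref=ref.upper(), alt=alt.upper(),
        target_allele=allele,
        allele_specific_primer=as_primer, mismatch_pos=MISMATCH_OFFSET,
        common_primer=common,
        product_length=r_end0 - f_start0 + 1,
        tm_allele_specific=tm_as, tm_common=tm_common,
    )


def _seq_to_arr(seq: str) -> np.ndarray:
    return np.frombuffer(seq.upper().encode(), dtype=np.uint8)


def _match_sites(template: np.ndarray, site_seq: str, three_prime: str,
                 max_mismatches: int) -> list[int]:
    """Start positions (0-based) where ``site_seq`` anneals on the plus strand.

    ``three_prime`` is 'right' when the primer's 3' end is the rightmost
    base of the site (forward primer) and 'left' when it is the leftmost
    (reverse primer annealing to the plus strand).  Extension requires the
    3'-terminal base to match exactly and at most one mismatch within the
    terminal three bases (the allele-specific primer carries its designed
    artificial mismatch there); up to ``max_mismatches`` are tolerated over
    the full primer.
    """
    site = _seq_to_arr(site_seq)
    n, m = template.size, site.size
    if n < m:
        return []
    term_idx = m - 1 if three_prime == "right" else 0
    tri_idx = [m - 3, m - 2, m - 1] if three_prime == "right" else [0, 1, 2]
    cand = np.flatnonzero(template[term_idx : n - m + 1 + term_idx] == site[term_idx])
    out = []
    for s in cand:
        window = template[s : s + m]
        tri_mism = int(np.count_nonzero(window[tri_idx] != site[tri_idx]))
        if tri_mism > 1:
            continue
        mism = int(np.count_nonzero(window != site))
        if mism <= max_mismatches:
            out.append(int(s))
    return out


def in_silico_pcr(design: AsPcrDesign, templates: Mapping[str, str],
                  max_mismatches: int = 2, max_product: int = 5000
                  ) -> dict[str, list[int]]:
    """Predicted product lengths per template haplotype.

    Extension requires the primer's 3'-terminal base to match perfectly
    and tolerates at most one mismatch within the terminal three bases.
    On the targeted allele the allele-specific primer carries only its
    designed artificial mismatch there and extends; on the other allele
    the allele base adds a second terminal mismatch and extension fails.
    """
    results: dict[str, list[int]] = {}
    fwd = design.allele_specific_primer
    rev_site = revcomp(design.common_primer)
    for name, seq in templates.items():
        arr = _seq_to_arr(seq)
        f_sites = _match_sites(arr, fwd, "right", max_mismatches)
        r_sites = _match_sites(arr, rev_site, "left", max_mismatches)
        products = []
        for f in f_sites:
            for r in r_sites:
                end = r + len(rev_site) - 1
                if end > f and (length := end - f + 1) <= max_product \
                        and r >= f + len(fwd) - 3:
                    products.append(length)
        results[name] = sorted(products)
    return results


def design_report(design: AsPcrDesign) -> str:
    """Human-readable TSV block describing one design."""
    lines = [
        "field\tvalue",
        f"snp\t{design.chrom}:{design.pos}:{design.ref}>{design.alt}",
        f"target_allele\t{design.target_allele}",
        f"allele_specific_primer\t{design.allele_specific_primer}",
        f"mismatch_pos_from_3prime\t{design.mismatch_pos}",
        f"common_primer\t{design.common_primer}",
        f"product_length\t{design.product_length}",
        f"tm_allele_specific\t{design.tm_allele_specific:.1f}",
        f"tm_common\t{design.tm_common:.1f}",
    ]
    return "\n".join(lines) + "\n"
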