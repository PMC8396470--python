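"""Causal-mutation isolation: genotype calls, exclusion rules, shortlists.

The isolation strategy keeps variants that could plausibly cause the
recessive-parent phenotype and discards the rest using four genetic
properties of the cross: a true causal site is homozygous in both parents
(doubled haploids), identical between the wild-type parent and the
tall bulk, and differentiated between the two bulks.  A functional
prefilter first restricts attention to variants that can affect a gene
product (anything genic except synonymous changes).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .annotate import FUNCTIONAL_REGIONS, degron_check, protein_pair
from .bsa import windowed_delta_at
from .simcross import SAMPLES

R1 = "R1_het_in_wt"
R2 = "R2_wt_inconsistent"
R3 = "R3_pools_identical"
R4 = "R4_het_in_mut"
F0 = "F0_not_functional"
MISSING = "M_missing_call"

# candidate priority classes: amino-acid-changing variants first (the
# screen targets mutations that directly affect the protein), then
# splice-region, then regulatory-region variants
_SEVERITY = {
    "nonsense": 0, "frameshift": 0, "missense": 0, "inframe_indel": 0,
}
_REGION_SEVERITY = {
    "splicing": 1, "utr5": 2, "utr3": 2, "upstream": 3, "downstream": 3,
}


@dataclass(frozen=True)
class CallThresholds:
    """Pooled-genotype calling rules (the source study filters on genotype
    states without stating how pools are called; these are this package's
    defaults, all configurable)."""

    min_call_depth: int = 8
    hom_ref_max: float = 0.1
    hom_alt_min: float = 0.9


@dataclass(frozen=True)
class GenotypeCall:
    sample_id: str
    call: str  # hom_ref | het | hom_alt | missing
    alt_fraction: float
    depth: int


@dataclass
class FilterOutcome:
    kept: bool
    reasons: list[str] = field(default_factory=list)


def call_genotype(ref_depth: int, alt_depth: int,
                  thresholds: CallThresholds = CallThresholds(),
                  sample_id: str = "") -> GenotypeCall:
    """Categorical genotype from pooled depths.

    Missing below ``min_call_depth``; hom_ref at alt fraction <=
    ``hom_ref_max``; hom_alt at >= ``hom_alt_min``; het in between.
    """
    if ref_depth < 0 or alt_depth < 0:
        raise ValueError("depths must be non-negative")
    depth = ref_depth + alt_depth
    if depth < thresholds.min_call_depth:
        return GenotypeCall(sample_id, "missing", float("nan"), depth)
    frac = alt_depth / depth
    if frac <= thresholds.hom_ref_max:
        call = "hom_ref"
    elif frac >= thresholds.hom_alt_min:
        call = "hom_alt"
    else:
        call = "het"
    return GenotypeCall(sample_id, call, frac, depth)


def functional_prefilter(region: str, coding_effect: str) -> tuple[bool, str | None]:
    """Keep variants that can change a gene product.

    Genic regions (upstream, UTR5, exonic, splicing, UTR3, downstream) are
    kept except exonic synonymous changes; everything else is dropped.
    """
    if region is None or coding_effect is None:
        raise ValueError("variant must be annotated before prefiltering")
    if region not in FUNCTIONAL_REGIONS or coding_effect == "synonymous":
        return False, F0
    return True, None


def genetic_property_filter(calls: Mapping[str, GenotypeCall],
                            wt_het_rule: str = "either") -> FilterOutcome:
    """Apply the four exclusion rules to the four pooled genotype calls.

    R1: heterozygous wild-type parent or tall bulk ("either" by default;
    set ``wt_het_rule="both"`` to require both).  R2: wild-type parent and
    tall bulk disagree.  R3: the two bulks agree.  R4: heterozygous mutant
    parent.  All violated rules are reported; a variant is kept iff none
    is violated.  Any missing call excludes the variant with its own code.
    """
    missing = [s for s in SAMPLES if s not in calls or calls[s].call == "missing"]
    if missing:
        return FilterOutcome(kept=False, reasons=[MISSING])
    wt_p = calls["wt_parent"].call
    mut_p = calls["mut_parent"].call
    wt_b = calls["wt_bulk"].call
    df_b = calls["df_bulk"].call
    reasons: list[str] = []
    if wt_het_rule == "both":
        r1 = wt_p == "het" and wt_b == "het"
    else:
        r1 = wt_p == "het" or wt_b == "het"
    if r1:
        reasons.append(R1)
    if wt_p != wt_b:
        reasons.append(R2)
    if df_b == wt_b:
        reasons.append(R3)
    if mut_p == "het":
        reasons.append(R4)
    return FilterOutcome(kept=not reasons, reasons=reasons)


def apply_filters(table: pd.DataFrame, annotations: pd.DataFrame,
                  thresholds: CallThresholds = CallThresholds(),
                  wt_het_rule: str = "either") -> pd.DataFrame:
    """Run prefilter + genetic-property rules over a whole variant table."""
    rows = []
    for i, row in enumerate(table.itertuples(index=False)):
        ann = annotations.iloc[i]
        keep_f, reason_f = functional_prefilter(ann["region"], ann["effect"])
        calls = {
            s: call_genotype(getattr(row, f"{s}_ref"), getattr(row, f"{s}_alt"),
                             thresholds, sample_id=s)
            for s in SAMPLES
        }
        outcome = genetic_property_filter(calls, wt_het_rule)
        reasons = ([] if keep_f else [reason_f]) + outcome.reasons
        rows.append(dict(kept=not reasons, reasons=";".join(reasons)))
    return pd.DataFrame(rows, index=table.index)


def _severity(effect: str, region: str) -> int:
    if effect in _SEVERITY:
        return _SEVERITY[effect]
    return _REGION_SEVERITY.get(region, 9)


def shortlist_candidates(peaks, table: pd.DataFrame,
                         outcomes: pd.DataFrame,
                         annotations: pd.DataFrame,
                         points: pd.DataFrame,
                         windows: pd.DataFrame,
                         genes=None, genome=None) -> pd.DataFrame:
    """Candidate report: kept variants inside peak regions, prioritized.

    Protein-changing variants come first (the screen targets mutations
    that directly affect amino-acid coding), then splice-region and
    regulatory-region variants; within a class, variants are ranked by
    windowed |delta| at the variant (rounded to 0.01 to merge local
    noise), then per-site |delta|, then position.  Missense candidates
    additionally get a degron motif status when gene models and the
    reference sequence are supplied.
    """
    import warnings as _warnings

    if len(peaks) == 0:
        _warnings.warn("empty peak set; candidate report is empty")
        return pd.DataFrame(columns=[
            "gene_id", "chrom", "pos", "ref", "alt", "region", "effect",
            "aa_change", "codon_change", "delta", "windowed_delta",
            "degron_status", "mutant_motif", "rank",
        ])

    in_peak = np.zeros(len(table), dtype=bool)
    pos = table["pos"].to_numpy()
    for p in peaks:
        in_peak |= (table["chrom"] == p.chrom).to_numpy() & (pos > p.start) & (pos <= p.end)
    sel = in_peak & outcomes["kept"].to_numpy()
    if not sel.any():
        _warnings.warn("no kept variants inside peak regions")

    by_id = {g.gene_id: g for g in (genes or [])}
    rows = []
    idx = np.flatnonzero(sel)
    site_delta = points["delta"].to_numpy()
    for i in idx:
        t = table.iloc[i]
        a = annotations.iloc[i]
        wdelta = windowed_delta_at(windows, t["chrom"], int(t["pos"]))
        status, motif = None, None
        if (a["effect"] in ("missense", "nonsense") and genome is not None
                and a["gene_id"] in by_id):
            before, after = protein_pair(
                by_id[a["gene_id"]], genome, int(t["pos"]), t["ref"], t["alt"]
            )
            ds = degron_check(before, after)
            status, motif = ds.status, ds.mutant_motif
        rows.append(dict(
            gene_id=a["gene_id"], chrom=t["chrom"], pos=int(t["pos"]),
            ref=t["ref"], alt=t["alt"], region=a["region"], effect=a["effect"],
            aa_change=a["aa_change"], codon_change=a["codon_change"],
            delta=float(site_delta[i]), windowed_delta=wdelta,
            degron_status=status, mutant_motif=motif,
            severity=_severity(a["effect"], a["region"]),
        ))
    report = pd.DataFrame(rows)
    if report.empty:
        report["rank"] = []
        return report
    report["abs_wdelta"] = report["windowed_delta"].abs().round(2)
    report["abs_delta"] = report["delta"].abs()
    report = report.sort_values(
        by=["severity", "abs_wdelta", "abs_delta", "chrom", "pos"],
        ascending=[True, False, False, True, True],
    ).reset_index(drop=True)
    report["rank"] = np.arange(1, len(report) + 1)
    return report.drop(columns=["abs_wdelta", "abs_delta", "severity"])


def filter_deg(records: pd.DataFrame, fdr_max: float = 0.05,
               min_abs_log2fc: float = 3.0) -> pd.DataFrame:
    """Differential-expression screen: FDR strictly below ``fdr_max`` and
    |log2FC| at least ``min_abs_log2fc`` (the default |log2FC| >= 3 is an
    8-fold linear change)."""
    required = {"gene_id", "log2fc", "fdr"}
    if not required.issubset(records.columns):
        raise ValueError(f"DEG table must have columns {sorted(required)}")
    if ((records["fdr"] < 0) | (records["fdr"] > 1)).any():
        raise ValueError("fdr must lie in [0, 1]")
    keep = (records["fdr"] < fdr_max) & (records["log2fc"].abs() >= min_abs_log2fc)
    return records[keep].reset_index(drop=True)
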