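"""End-to-end orchestration: simulate -> scan -> annotate -> shortlist.

This is the module the acceptance experiments and the command-line tool
build on; every step is an ordinary call into the individual modules so
any stage can be swapped for real data read from VCF/GFF3/FASTA files.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import annotate as ann_mod
from . import bsa, filtering, simcross
from .genome import GeneModel


@dataclass
class PipelineResult:
    sim: simcross.Simulation
    bulks: simcross.Bulks
    table: pd.DataFrame
    points: pd.DataFrame
    band: bsa.NullBandTable
    windows: pd.DataFrame
    peaks: list[bsa.PeakRegion]
    annotations: pd.DataFrame
    outcomes: pd.DataFrame
    shortlist: pd.DataFrame


def run_pipeline(config: simcross.CrossConfig | None = None,
                 seed: int | None = None,
                 window_bp: int = 1_000_000,
                 step_bp: int = 100_000,
                 level: float = 0.95,
                 n_sim: int = 10_000,
                 min_depth: int = 8,
                 min_sites: int = 5,
                 min_windows: int = 3,
                 merge_gap: int = 1) -> PipelineResult:
    """Run the whole analysis on one simulated cross."""
    if config is None:
        config = simcross.CrossConfig()
    if seed is not None:
        config = replace(config, seed=seed)
    sim = simcross.simulate_cross(config)
    bulks = simcross.assign_bulks(sim.f2, config)
    table = simcross.build_variant_table(sim, bulks)

    points = bsa.delta_index_table(table, min_depth=min_depth)
    chrom_lengths = {c: config.chrom_length_bp for c in config.chrom_names}
    windows = bsa.sliding_windows(points, chrom_lengths, window_bp, step_bp,
                                  min_sites=min_sites, min_depth=min_depth)
    med = windows["median_depth"].dropna()
    if med.empty:
        depths = [max(1, int(config.depth_lambda))]
    else:
        depths = np.arange(int(med.min()), int(med.max()) + 2)
    band = bsa.NullBandTable.tabulate(depths, bulk_size=config.bulk_size,
                                      level=level, n_sim=n_sim, rng=sim.rng)
    windows = bsa.attach_bands(windows, band)
    peaks = bsa.call_peaks(windows, min_windows=min_windows, merge_gap=merge_gap)

    annotations = ann_mod.annotate_table(table, sim.genes, sim.genome)
    outcomes = filtering.apply_filters(table, annotations)
    shortlist = filtering.shortlist_candidates(
        peaks, table, outcomes, annotations, points, windows,
        genes=sim.genes, genome=sim.genome,
    )
    return PipelineResult(sim=sim, bulks=bulks, table=table, points=points,
                          band=band, windows=windows, peaks=peaks,
                          annotations=annotations, outcomes=outcomes,
                          shortlist=shortlist)


def recovery_flags(result: PipelineResult) -> dict:
    """Did the scan and shortlist recover the planted causal variant?"""
    causal = result.sim.causal
    pos = int(causal.pos)
    containing = [
        p for p in result.peaks
        if p.direction > 0 and p.chrom == causal.chrom and p.start < pos <= p.end
    ]
    top_is_causal = False
    degron_altered = False
    if len(result.shortlist):
        top = result.shortlist.iloc[0]
        top_is_causal = top["chrom"] == causal.chrom and int(top["pos"]) == pos
        degron_altered = (top["degron_status"] == "altered"
                          and top["mutant_motif"] == "EWPPV")
    return {
        "peak_contains_causal": bool(containing),
        "n_positive_peaks": sum(p.direction > 0 for p in result.peaks),
        "causal_top_ranked": top_is_causal,
        "degron_altered": degron_altered,
        "recovered": bool(containing) and top_is_causal and degron_altered,
    }


def recovery_rate(n_seeds: int, base_seed: int = 0,
                  config: simcross.CrossConfig | None = None,
                  **pipeline_kwargs) -> tuple[float, list[dict]]:
    """Fraction of seeds where the causal variant is fully recovered."""
    if config is None:
        config = simcross.CrossConfig()
    flags = []
    for i in range(n_seeds):
        res = run_pipeline(replace(config, seed=base_seed + i), **pipeline_kwargs)
        flags.append(recovery_flags(res))
    rate = float(np.mean([f["recovered"] for f in flags]))
    return rate, flags
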