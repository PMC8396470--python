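"""Delta(SNP-index) bulked-segregant scan with Monte-Carlo null bands.

At each variant site the SNP-index of a pool is the fraction of reads that
carry the alternate (mutant-parent) allele; Delta(SNP-index) is the dwarf
bulk's index minus the tall bulk's.  Near the causal locus the statistic
approaches +1, at unlinked loci its expectation is 0.  Significance is
judged against an empirical null obtained by resampling bulks of unselected
F2 genotypes and re-sequencing them in silico at matched depth.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

F2_GENOTYPE_PROBS = (0.25, 0.5, 0.25)
BACKCROSS_GENOTYPE_PROBS = (0.5, 0.5, 0.0)


def snp_index(ref_depth, alt_depth):
    """Alt-read fraction alt/(ref+alt); NaN where total depth is zero."""
    ref = np.asarray(ref_depth, dtype=float)
    alt = np.asarray(alt_depth, dtype=float)
    if np.any(ref < 0) or np.any(alt < 0):
        raise ValueError("depths must be non-negative")
    total = ref + alt
    with np.errstate(invalid="ignore", divide="ignore"):
        out = np.where(total > 0, alt / np.where(total > 0, total, 1), np.nan)
    if out.ndim == 0:
        return float(out)
    return out


def harmonic_depth(depth_a, depth_b):
    """Harmonic mean of two pool depths (matches the read-noise variance of
    an equal-depth design); 0 where either pool has no reads."""
    a = np.asarray(depth_a, dtype=float)
    b = np.asarray(depth_b, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        h = np.where((a > 0) & (b > 0), 2.0 / (1.0 / np.where(a > 0, a, 1)
                                               + 1.0 / np.where(b > 0, b, 1)), 0.0)
    return h


def delta_index_table(table: pd.DataFrame,
                      df_sample: str = "df_bulk",
                      wt_sample: str = "wt_bulk",
                      min_depth: int = 8) -> pd.DataFrame:
    """Per-site SNP-index for both bulks and their difference.

    Sites where either bulk is below ``min_depth`` are flagged low
    confidence; the delta is NaN wherever either index is undefined.
    """
    for s in (df_sample, wt_sample):
        if f"{s}_ref" not in table.columns:
            raise KeyError(f"unknown sample {s!r} in variant table")
    out = table[["chrom", "pos"]].copy()
    d_ref = table[f"{df_sample}_ref"].to_numpy()
    d_alt = table[f"{df_sample}_alt"].to_numpy()
    w_ref = table[f"{wt_sample}_ref"].to_numpy()
    w_alt = table[f"{wt_sample}_alt"].to_numpy()
    out["index_df"] = snp_index(d_ref, d_alt)
    out["index_wt"] = snp_index(w_ref, w_alt)
    out["delta"] = out["index_df"] - out["index_wt"]
    out["depth_df"] = d_ref + d_alt
    out["depth_wt"] = w_ref + w_alt
    out["low_confidence"] = (out["depth_df"] < min_depth) | (out["depth_wt"] < min_depth)
    return out


def sliding_windows(points: pd.DataFrame,
                    chrom_lengths: Mapping[str, int],
                    window_bp: int = 1_000_000,
                    step_bp: int = 100_000,
                    min_sites: int = 5,
                    min_depth: int = 8) -> pd.DataFrame:
    """Tile each chromosome with overlapping windows of mean delta.

    Windows are [start, end) half-open at ``step_bp`` spacing.  Sites with
    NaN delta or depth below ``min_depth`` in either bulk are ignored;
    windows with fewer than ``min_sites`` usable sites get a NaN mean and
    can never be significant.
    """
    if not window_bp >= step_bp > 0:
        raise ValueError("require window_bp >= step_bp > 0")
    for chrom, grp in points.groupby("chrom", sort=False):
        if not grp["pos"].is_monotonic_increasing:
            raise ValueError(f"points not sorted by position on {chrom}")

    usable = points[
        points["delta"].notna()
        & (points["depth_df"] >= min_depth)
        & (points["depth_wt"] >= min_depth)
    ]
    rows = []
    for chrom, length in chrom_lengths.items():
        grp = usable[usable["chrom"] == chrom]
        pos = grp["pos"].to_numpy()
        delta = grp["delta"].to_numpy()
        depth = harmonic_depth(grp["depth_df"].to_numpy(), grp["depth_wt"].to_numpy())
        for start in range(0, int(length), int(step_bp)):
            end = start + int(window_bp)
            lo = np.searchsorted(pos, start + 1)  # pos is 1-based
            hi = np.searchsorted(pos, end, side="left")
            n = hi - lo
            if n >= min_sites:
                mean_delta = float(delta[lo:hi].mean())
                med_depth = float(np.median(depth[lo:hi]))
            else:
                mean_delta, med_depth = np.nan, np.nan
            rows.append(dict(chrom=chrom, start=start, end=end,
                             n_sites=int(n), mean_delta=mean_delta,
                             median_depth=med_depth))
    return pd.DataFrame(rows)


# --------------------------------------------------------------------------
# Monte-Carlo null band
# --------------------------------------------------------------------------

def _simulate_null_delta(depths: np.ndarray, bulk_size: int, n_sim: int,
                         rng: np.random.Generator,
                         genotype_probs: Sequence[float]) -> np.ndarray:
    """(n_sim, len(depths)) matrix of null deltas for unlinked markers."""
    depths = np.asarray(depths, dtype=int)
    p = np.asarray(genotype_probs, dtype=float)
    p = p / p.sum()

    def pool_freq() -> np.ndarray:
        counts = rng.multinomial(bulk_size, p, size=(n_sim, depths.size))
        alleles = counts[..., 1] + 2 * counts[..., 2]
        return alleles / (2.0 * bulk_size)

    f_df, f_wt = pool_freq(), pool_freq()
    reads_df = rng.binomial(depths[None, :], f_df)
    reads_wt = rng.binomial(depths[None, :], f_wt)
    return reads_df / depths[None, :] - reads_wt / depths[None, :]


def null_band(depth: int, bulk_size: int, level: float = 0.95,
              n_sim: int = 10_000, rng: np.random.Generator | None = None,
              genotype_probs: Sequence[float] = F2_GENOTYPE_PROBS
              ) -> tuple[float, float]:
    """Null band for Delta(SNP-index) at one depth.

    Each of the two bulks draws ``bulk_size`` unselected F2 genotypes
    i.i.d. with probabilities ``genotype_probs`` (1:2:1 for an F2 design,
    1:1 for a backcross), forms the pool allele frequency, and sequences it
    as Binomial(depth, frequency) reads; the band is the empirical
    (alpha/2, 1-alpha/2) quantile pair of the resulting delta.
    """
    if depth < 1 or bulk_size < 1:
        raise ValueError("depth and bulk_size must be >= 1")
    if not 0 < level < 1:
        raise ValueError("level must lie in (0, 1)")
    if n_sim < 1000:
        raise ValueError("n_sim too small for stable quantiles")
    if rng is None:
        rng = np.random.default_rng()
    deltas = _simulate_null_delta(np.array([depth]), bulk_size, n_sim, rng,
                                  genotype_probs)[:, 0]
    alpha = 1 - level
    lo, hi = np.quantile(deltas, [alpha / 2, 1 - alpha / 2])
    return float(lo), float(hi)


@dataclass
class NullBandTable:
    """Null bands tabulated per depth, linearly interpolated between depths."""

    depths: np.ndarray
    lo: np.ndarray
    hi: np.ndarray
    bulk_size: int
    level: float

    @classmethod
    def tabulate(cls, depths: Sequence[int], bulk_size: int,
                 level: float = 0.95, n_sim: int = 10_000,
                 rng: np.random.Generator | None = None,
                 genotype_probs: Sequence[float] = F2_GENOTYPE_PROBS
                 ) -> "NullBandTable":
        if rng is None:
            rng = np.random.default_rng()
        depths = np.unique(np.asarray(depths, dtype=int))
        depths = depths[depths >= 1]
        if depths.size == 0:
            raise ValueError("no valid depths to tabulate")
        deltas = _simulate_null_delta(depths, bulk_size, n_sim, rng, genotype_probs)
        alpha = 1 - level
        lo = np.quantile(deltas, alpha / 2, axis=0)
        hi = np.quantile(deltas, 1 - alpha / 2, axis=0)
        return cls(depths=depths, lo=lo, hi=hi, bulk_size=bulk_size, level=level)

    def lookup(self, depth) -> tuple[np.ndarray, np.ndarray]:
        d = np.clip(np.asarray(depth, dtype=float),
                    self.depths[0], self.depths[-1])
        return (np.interp(d, self.depths, self.lo),
                np.interp(d, self.depths, self.hi))


def attach_bands(windows: pd.DataFrame, band: NullBandTable) -> pd.DataFrame:
    """Add ci_low/ci_high (at the window's median depth) and significance."""
    out = windows.copy()
    lo, hi = band.lookup(out["median_depth"].fillna(band.depths[0]))
    out["ci_low"] = lo
    out["ci_high"] = hi
    mean = out["mean_delta"]
    out["significant"] = (mean > out["ci_high"]) | (mean < out["ci_low"])
    out.loc[mean.isna(), "significant"] = False
    out["direction"] = np.where(mean > out["ci_high"], 1,
                                np.where(mean < out["ci_low"], -1, 0))
    out.loc[mean.isna(), "direction"] = 0
    return out


# --------------------------------------------------------------------------
# peak calling
# --------------------------------------------------------------------------

@dataclass
class PeakRegion:
    chrom: str
    start: int  # bp, half-open like the windows
    end: int
    direction: int  # +1 or -1
    peak_delta: float
    n_windows: int


def call_peaks(windows: pd.DataFrame, min_windows: int = 3,
               merge_gap: int = 1) -> list[PeakRegion]:
    """Runs of same-direction significant windows become peak regions.

    Consecutive significant windows of one direction are joined when at
    most ``merge_gap`` non-significant windows separate them; a run
    qualifies when it contains at least ``min_windows`` significant
    windows.  Region bounds are the union of member windows.
    """
    if "direction" not in windows.columns:
        raise ValueError("windows must carry bands (see attach_bands)")
    peaks: list[PeakRegion] = []
    for chrom, grp in windows.groupby("chrom", sort=False):
        grp = grp.sort_values("start").reset_index(drop=True)
        for sign in (1, -1):
            sig_idx = grp.index[grp["direction"] == sign].to_numpy()
            if sig_idx.size == 0:
                continue
            runs: list[list[int]] = [[int(sig_idx[0])]]
            for i in sig_idx[1:]:
                if i - runs[-1][-1] - 1 <= merge_gap:
                    runs[-1].append(int(i))
                else:
                    runs.append([int(i)])
            for run in runs:
                if len(run) < min_windows:
                    continue
                members = grp.loc[run]
                extreme = members["mean_delta"].max() if sign > 0 else members["mean_delta"].min()
                peaks.append(PeakRegion(
                    chrom=chrom,
                    start=int(members["start"].min()),
                    end=int(members["end"].max()),
                    direction=sign,
                    peak_delta=float(extreme),
                    n_windows=len(run),
                ))
    peaks.sort(key=lambda p: (p.chrom, p.start))
    return peaks


def peaks_to_bed(peaks: Sequence[PeakRegion], path: str | Path) -> None:
    """Write peak regions as BED (0-based half-open)."""
    with Path(path).open("w") as fh:
        for i, p in enumerate(peaks):
            name = f"peak_{i + 1}_{'pos' if p.direction > 0 else 'neg'}"
            fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{name}\t{p.peak_delta:.4f}\n")


def windowed_delta_at(windows: pd.DataFrame, chrom: str, pos: int) -> float:
    """Windowed mean delta interpolated at a genomic position."""
    grp = windows[(windows["chrom"] == chrom) & windows["mean_delta"].notna()]
    if grp.empty:
        return float("nan")
    centers = ((grp["start"] + grp["end"]) / 2.0).to_numpy()
    order = np.argsort(centers)
    return float(np.interp(pos, centers[order], grp["mean_delta"].to_numpy()[order]))


def plot_delta(windows: pd.DataFrame, points: pd.DataFrame | None,
               path: str | Path) -> None:
    """Per-chromosome plot of windowed delta with its confidence band."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    chroms = list(dict.fromkeys(windows["chrom"]))
    fig, axes = plt.subplots(len(chroms), 1, figsize=(9, 2.4 * len(chroms)),
                             sharey=True, squeeze=False)
    for ax, chrom in zip(axes[:, 0], chroms):
        grp = windows[windows["chrom"] == chrom]
        mid = (grp["start"] + grp["end"]) / 2e6
        if points is not None:
            pts = points[points["chrom"] == chrom]
            ax.plot(pts["pos"] / 1e6, pts["delta"], ".", ms=2, alpha=0.3,
                    color="grey")
        ax.fill_between(mid, grp["ci_low"], grp["ci_high"], alpha=0.25,
                        color="tab:blue", label="95% null band")
        ax.plot(mid, grp["mean_delta"], color="tab:red", lw=1.5,
                label="windowed Δ(SNP-index)")
        ax.axhline(0.0, color="k", lw=0.5)
        ax.set_ylabel(chrom)
        ax.set_ylim(-1.05, 1.05)
    axes[-1, 0].set_xlabel("position (Mb)")
    axes[0, 0].legend(loc="upper right", fontsize=8)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)
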