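"""Delta(SNP-index) statistics, windows, null bands and peak calling."""

import itertools

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from bulkmap import (
    NullBandTable,
    attach_bands,
    call_peaks,
    delta_index_table,
    null_band,
    sliding_windows,
    snp_index,
)


class TestSnpIndex:
    @pytest.mark.parametrize("ref,alt,expected", [
        (10, 30, 0.75),
        (0, 30, 1.0),
        (30, 0, 0.0),
    ])
    def test_values(self, ref, alt, expected):
        assert snp_index(ref, alt) == pytest.approx(expected)

    def test_zero_depth_is_missing(self):
        assert np.isnan(snp_index(0, 0))

    def test_negative_depths_rejected(self):
        with pytest.raises(ValueError):
            snp_index(-1, 5)

    def test_bounds_hold_for_any_depths(self, rng):
        ref = rng.integers(0, 100, 1000)
        alt = rng.integers(0, 100, 1000)
        idx = snp_index(ref, alt)
        ok = ~np.isnan(idx)
        assert np.all((idx[ok] >= 0) & (idx[ok] <= 1))


def _points(rows):
    df = pd.DataFrame(rows, columns=["chrom", "pos", "df_ref", "df_alt",
                                     "wt_ref", "wt_alt"])
    df = df.rename(columns={"df_ref": "df_bulk_ref", "df_alt": "df_bulk_alt",
                            "wt_ref": "wt_bulk_ref", "wt_alt": "wt_bulk_alt"})
    return delta_index_table(df)


class TestDeltaIndex:
    def test_causal_pattern_gives_delta_one(self):
        pts = _points([("c1", 100, 0, 40, 40, 0)])
        assert pts["delta"].iloc[0] == pytest.approx(1.0)

    def test_unlinked_pattern_gives_delta_zero(self):
        pts = _points([("c1", 100, 20, 20, 20, 20)])
        assert pts["delta"].iloc[0] == pytest.approx(0.0)

    def test_missing_propagates(self):
        pts = _points([("c1", 100, 0, 0, 20, 20)])
        assert np.isnan(pts["delta"].iloc[0])

    def test_low_depth_flagged(self):
        pts = _points([("c1", 100, 3, 2, 20, 20)])
        assert bool(pts["low_confidence"].iloc[0])

    def test_unknown_sample_rejected(self):
        df = pd.DataFrame({"chrom": ["c1"], "pos": [1],
                           "df_bulk_ref": [1], "df_bulk_alt": [1],
                           "wt_bulk_ref": [1], "wt_bulk_alt": [1]})
        with pytest.raises(KeyError):
            delta_index_table(df, df_sample="nope")

    def test_delta_bounds(self, rng):
        rows = [("c1", i + 1, int(rng.integers(0, 50)), int(rng.integers(0, 50)),
                 int(rng.integers(0, 50)), int(rng.integers(0, 50)))
                for i in range(500)]
        pts = _points(rows)
        ok = pts["delta"].notna()
        assert pts.loc[ok, "delta"].between(-1, 1).all()


def _window_points(chrom_data):
    """chrom_data: list of (chrom, pos, delta) with constant depth 40."""
    rows = []
    for chrom, pos, delta in chrom_data:
        alt = int(round(40 * delta))
        rows.append((chrom, pos, 40 - alt, alt, 40, 0))
    # wt bulk all-ref so index_wt = 0 and delta = index_df
    return _points(rows)


class TestSlidingWindows:
    def test_constant_field_gives_constant_means(self):
        pts = _window_points([("c1", p, 0.3) for p in range(1000, 900_000, 9000)])
        win = sliding_windows(pts, {"c1": 1_000_000},
                              window_bp=200_000, step_bp=100_000)
        good = win["mean_delta"].dropna()
        assert len(good) > 3
        assert np.allclose(good, 0.3, atol=1e-9)

    def test_single_site_window_mean_is_that_site(self):
        pts = _window_points([("c1", 50_000, 0.6)])
        win = sliding_windows(pts, {"c1": 100_000}, window_bp=100_000,
                              step_bp=100_000, min_sites=1)
        assert win["mean_delta"].iloc[0] == pytest.approx(0.6)

    def test_half_overlapping_windows_bracket_a_step_change(self):
        # delta steps from 0.0 to 1.0 at 100 kb
        data = [("c1", p, 0.0) for p in range(5_000, 100_000, 5_000)]
        data += [("c1", p, 1.0) for p in range(100_000, 200_000, 5_000)]
        pts = _window_points(data)
        win = sliding_windows(pts, {"c1": 200_000}, window_bp=100_000,
                              step_bp=50_000, min_sites=1)
        means = win["mean_delta"].dropna()
        low, high = means.min(), means.max()
        assert low == pytest.approx(0.0, abs=1e-9)
        assert high == pytest.approx(1.0, abs=1e-9)
        assert ((means > 0.2) & (means < 0.8)).any()

    def test_unsorted_input_rejected(self):
        pts = _window_points([("c1", 500, 0.1), ("c1", 100, 0.1)])
        with pytest.raises(ValueError):
            sliding_windows(pts, {"c1": 1000})

    def test_sparse_windows_get_missing_mean(self):
        pts = _window_points([("c1", 50_000, 0.5)])
        win = sliding_windows(pts, {"c1": 100_000}, window_bp=100_000,
                              step_bp=100_000, min_sites=5)
        assert np.isnan(win["mean_delta"].iloc[0])


def _enumerate_null_delta(depth: int, bulk_size: int):
    """Exact null distribution of delta by brute-force enumeration.

    Each bulk's pooled allele count over ``bulk_size`` F2 plants is
    Binomial(2*bulk_size, 1/2) (genotypes 1:2:1 = Binomial(2, 1/2) alleles
    per plant); reads are Binomial(depth, count/(2*bulk_size)).  The state
    space is tiny for depth <= 3 and bulk_size <= 2.
    """
    n_alleles = 2 * bulk_size
    outcomes = {}
    for k_df, k_wt in itertools.product(range(n_alleles + 1), repeat=2):
        p_k = (stats.binom.pmf(k_df, n_alleles, 0.5)
               * stats.binom.pmf(k_wt, n_alleles, 0.5))
        f_df, f_wt = k_df / n_alleles, k_wt / n_alleles
        for r_df, r_wt in itertools.product(range(depth + 1), repeat=2):
            p = (p_k * stats.binom.pmf(r_df, depth, f_df)
                 * stats.binom.pmf(r_wt, depth, f_wt))
            if p <= 0:
                continue
            delta = round(r_df / depth - r_wt / depth, 12)
            outcomes[delta] = outcomes.get(delta, 0.0) + p
    values = np.array(sorted(outcomes))
    probs = np.array([outcomes[v] for v in values])
    return values, probs


def _exact_quantile(values, probs, q):
    cdf = np.cumsum(probs)
    return values[np.searchsorted(cdf, q)]


class TestNullBand:
    def test_band_is_symmetric(self, rng):
        lo, hi = null_band(50, 30, n_sim=20_000, rng=rng)
        assert lo < 0 < hi
        assert abs(abs(lo) - hi) < 0.05

    def test_band_width_shrinks_with_depth(self, rng):
        widths = []
        for depth in (10, 50, 200):
            lo, hi = null_band(depth, 30, n_sim=20_000, rng=rng)
            widths.append(hi - lo)
        assert widths[0] >= widths[1] >= widths[2]

    @pytest.mark.parametrize("depth,bulk", [(2, 2), (3, 2), (2, 1)])
    def test_matches_exhaustive_enumeration(self, depth, bulk, rng):
        values, probs = _enumerate_null_delta(depth, bulk)
        grid = np.diff(values).min()
        lo, hi = null_band(depth, bulk, n_sim=50_000, rng=rng)
        assert abs(lo - _exact_quantile(values, probs, 0.025)) <= grid + 1e-9
        assert abs(hi - _exact_quantile(values, probs, 0.975)) <= grid + 1e-9

    def test_parameter_validation(self, rng):
        with pytest.raises(ValueError):
            null_band(0, 30, rng=rng)
        with pytest.raises(ValueError):
            null_band(50, 30, level=1.2, rng=rng)
        with pytest.raises(ValueError):
            null_band(50, 30, n_sim=10, rng=rng)

    def test_table_interpolates_between_depths(self, rng):
        table = NullBandTable.tabulate([10, 100], 30, n_sim=20_000, rng=rng)
        lo10, hi10 = table.lookup(10)
        lo55, hi55 = table.lookup(55)
        lo100, hi100 = table.lookup(100)
        assert hi100 <= hi55 <= hi10
        # clamped outside the tabulated range
        assert table.lookup(1)[1] == hi10


def _windows_frame(directions):
    """Build an attach_bands-style frame from per-window direction codes."""
    rows = []
    for i, d in enumerate(directions):
        mean = 0.0 if d == 0 else (0.5 if d > 0 else -0.5)
        rows.append(dict(chrom="c1", start=i * 100, end=i * 100 + 200,
                         n_sites=10, mean_delta=mean, median_depth=50.0,
                         ci_low=-0.2, ci_high=0.2,
                         significant=d != 0, direction=d))
    return pd.DataFrame(rows)


class TestCallPeaks:
    def test_flat_field_yields_no_peaks(self):
        assert call_peaks(_windows_frame([0] * 20)) == []

    def test_two_separated_spikes_become_two_regions(self):
        win = _windows_frame([0, 1, 1, 1, 0, 0, 0, 0, 1, 1, 1, 0])
        peaks = call_peaks(win, min_windows=3, merge_gap=1)
        assert len(peaks) == 2

    def test_small_gap_is_merged(self):
        win = _windows_frame([1, 1, 0, 1, 1])
        peaks = call_peaks(win, min_windows=4, merge_gap=1)
        assert len(peaks) == 1
        assert peaks[0].n_windows == 4
        assert peaks[0].start == 0 and peaks[0].end == 600

    def test_direction_separation(self):
        win = _windows_frame([1, 1, 1, 0, -1, -1, -1])
        peaks = call_peaks(win, min_windows=3, merge_gap=0)
        assert sorted(p.direction for p in peaks) == [-1, 1]

    def test_requires_bands(self):
        with pytest.raises(ValueError):
            call_peaks(pd.DataFrame({"chrom": [], "start": []}))


def test_null_calibration_of_per_site_outlier_rate():
    """About 5% of unlinked-site deltas fall outside the 95% band.

    Sites are simulated from the full generator with a phenotype model that
    carries no genotype information, so bulks are effectively random draws
    from the F2 and every site is null.  The genetic map is stretched so
    adjacent sites are > 1 Morgan apart: the 5% band is a marginal,
    per-site statement, so its empirical check needs effectively unlinked
    sites (linked sites share one bulk genotype draw and the realized
    outlier fraction would fluctuate wildly).
    """
    from conftest import small_config
    from bulkmap import assign_bulks, build_variant_table, simulate_cross
    from bulkmap.bsa import harmonic_depth

    flat = {"hom_wt": (150.0, 10.0), "het": (150.0, 10.0),
            "hom_mut": (150.0, 10.0)}
    cfg = small_config(chrom_length_bp=2_000_000, n_marker_snps=12_000,
                       cm_per_mb=1_250_000.0,
                       n_induced_mutations=0, n_artifact_sites=0,
                       f2_size=300, bulk_size=30, phenotype_model=flat,
                       seed=97)
    sim = simulate_cross(cfg)
    bulks = assign_bulks(sim.f2, cfg)
    table = build_variant_table(sim, bulks)
    pts = delta_index_table(table)
    ok = pts["delta"].notna() & (pts["depth_df"] > 0) & (pts["depth_wt"] > 0)
    pts = pts[ok]
    depth = harmonic_depth(pts["depth_df"].to_numpy(), pts["depth_wt"].to_numpy())
    band = NullBandTable.tabulate(
        np.arange(int(depth.min()), int(depth.max()) + 2), cfg.bulk_size,
        n_sim=20_000, rng=np.random.default_rng(5))
    lo, hi = band.lookup(depth)
    outside = (pts["delta"].to_numpy() > hi) | (pts["delta"].to_numpy() < lo)
    rate = outside.mean()
    assert 0.04 <= rate <= 0.06
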