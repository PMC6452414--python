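from fractions import Fraction

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poolscan import (
    GenomeLayout,
    HpScan,
    SweepThresholds,
    call_sweeps,
    make_sliding_windows,
    pool_allele_counts,
    pooled_heterozygosity,
    scan_counts,
    sweep_report,
    z_transform,
)
from poolscan.genome_io import PoolData
from poolscan.sweeps import ZeroVarianceError, loci_table

from conftest import make_record


class TestPoolAlleleCounts:
    @pytest.mark.parametrize(
        "depths, expected",
        [
            ((12, 8), (12, 8)),
            ((0, 20), (20, 0)),
            ((10, 6, 4), (10, 6)),  # multiallelic: two largest depths
            ((4, 6, 10), (10, 6)),
        ],
    )
    def test_counts(self, depths, expected):
        rec = make_record(
            alts=("G",) * (len(depths) - 1),
            pools=(PoolData(tuple(depths), None, None),),
        )
        pc = pool_allele_counts(rec, 0)
        assert (pc.n_maj, pc.n_min) == expected
        assert pc.n_maj >= pc.n_min >= 0

    def test_zero_depth_site_skipped(self):
        rec = make_record(pools=(PoolData((0, 0), None, None),))
        assert pool_allele_counts(rec, 0) is None


class TestSlidingWindows:
    def test_single_window_chromosome(self):
        w = make_sliding_windows(GenomeLayout((("chr1", 150_000),)))
        assert list(zip(w["start"], w["end"])) == [(0, 150_000)]

    def test_300kb_gives_three_full_windows(self):
        w = make_sliding_windows(GenomeLayout((("chr1", 300_000),)))
        assert w["start"].tolist() == [0, 75_000, 150_000]
        assert (w["end"] - w["start"] == 150_000).all()

    def test_short_chromosome_contributes_no_windows(self):
        lay = GenomeLayout((("chr1", 100_000), ("chr2", 150_000)))
        w = make_sliding_windows(lay)
        assert set(w["chrom"]) == {"chr2"}

    def test_interior_bases_covered_exactly_twice(self):
        lay = GenomeLayout((("chr1", 750_000),))
        w = make_sliding_windows(lay)
        rng = np.random.default_rng(0)
        for pos in rng.integers(150_000, 600_000, 50):
            cover = ((w["start"] <= pos) & (pos < w["end"])).sum()
            assert cover == 2


class TestHpFormula:
    def test_symmetric_counts_give_half(self):
        assert pooled_heterozygosity(5, 5) == pytest.approx(0.5)

    def test_monomorphic_window_gives_zero(self):
        assert pooled_heterozygosity(10 + 7, 0 + 0) == 0.0

    def test_worked_window(self):
        # SNPs (10,2) and (8,4): Σmaj=18, Σmin=6 → 2·18·6/24² = 0.375
        assert pooled_heterozygosity(18, 6) == pytest.approx(0.375)

    @given(
        pairs=st.lists(
            st.tuples(st.integers(0, 200), st.integers(0, 200)), min_size=1, max_size=40
        )
    )
    @settings(max_examples=300, deadline=None, derandomize=True)
    def test_range_and_extremes(self, pairs):
        maj = sum(max(p) for p in pairs)
        mn = sum(min(p) for p in pairs)
        if maj + mn == 0:
            return
        hp = pooled_heterozygosity(maj, mn)
        assert 0.0 <= hp <= 0.5
        assert (hp == 0.0) == (mn == 0)
        assert (hp == pytest.approx(0.5)) == (maj == mn)

    def test_site_label_order_irrelevant_after_resorting(self):
        """Feeding (min,maj) instead of (maj,min) at any site changes nothing
        because per-site counts are re-sorted before summation."""
        rng = np.random.default_rng(1)
        depths = rng.integers(0, 40, size=(30, 2))
        rec_pairs = [tuple(d) for d in depths]
        swapped = [(b, a) if i % 3 == 0 else (a, b) for i, (a, b) in enumerate(rec_pairs)]

        def window_hp(pairs):
            counts = [
                pool_allele_counts(
                    make_record(pools=(PoolData(tuple(p), None, None),)), 0
                )
                for p in pairs
            ]
            counts = [c for c in counts if c is not None]
            return pooled_heterozygosity(
                sum(c.n_maj for c in counts), sum(c.n_min for c in counts)
            )

        assert window_hp(rec_pairs) == pytest.approx(window_hp(swapped))


def _scan_from_hp(hp_values):
    n = len(hp_values)
    windows = pd.DataFrame(
        {
            "chrom": ["chr1"] * n,
            "start": np.arange(n) * 75_000,
            "end": np.arange(n) * 75_000 + 150_000,
            "n_snps": [50] * n,
            "sum_maj": [0] * n,
            "sum_min": [0] * n,
            "hp": hp_values,
        }
    )
    return HpScan(pool="t", windows=windows)


class TestZTransform:
    def test_two_point_gives_plus_minus_one(self):
        scan = z_transform(_scan_from_hp([0.2, 0.4]))
        assert scan.windows["zhp"].tolist() == pytest.approx([-1.0, 1.0])

    def test_constant_hp_raises_zero_variance(self):
        with pytest.raises(ZeroVarianceError):
            z_transform(_scan_from_hp([0.3, 0.3, 0.3]))

    def test_mean_zero_sd_one_with_independent_summation(self):
        rng = np.random.default_rng(8)
        scan = z_transform(_scan_from_hp(rng.uniform(0, 0.5, 500).tolist()))
        z = scan.windows["zhp"].to_numpy()
        # independent recomputation with plain Python sums
        mean = sum(z) / len(z)
        sd = (sum((x - mean) ** 2 for x in z) / len(z)) ** 0.5
        assert abs(mean) < 1e-9
        assert abs(sd - 1.0) < 1e-9

    def test_unscored_windows_carry_no_zhp(self):
        scan = z_transform(_scan_from_hp([0.1, 0.2, float("nan"), 0.3]))
        assert np.isnan(scan.windows["zhp"].iloc[2])


class TestScanOracle:
    def _brute_force(self, counts, windows, min_snps):
        """Per-window Hp by direct iteration over the flat SNP list."""
        out = []
        for w in windows.itertuples(index=False):
            maj = mn = k = 0
            for s in counts.itertuples(index=False):
                if s.chrom == w.chrom and w.start <= s.pos < w.end:
                    maj += s.n_maj
                    mn += s.n_min
                    k += 1
            if k < min_snps or maj + mn == 0:
                out.append(float("nan"))
            else:
                out.append(float(2 * Fraction(maj) * Fraction(mn) / (maj + mn) ** 2))
        return out

    def test_windowed_hp_equals_brute_force(self):
        lay = GenomeLayout((("chr1", 600_000), ("chr2", 450_000)))
        rng = np.random.default_rng(123)
        n = 400
        chrom = np.where(rng.random(n) < 0.6, "chr1", "chr2")
        pos = np.array([rng.integers(0, lay.length(c)) for c in chrom])
        a = rng.integers(0, 30, n)
        b = rng.integers(0, 30, n)
        counts = pd.DataFrame(
            {"chrom": chrom, "pos": pos, "n_maj": np.maximum(a, b), "n_min": np.minimum(a, b)}
        )
        scan = scan_counts(counts, lay, min_snps=3)
        expected = self._brute_force(counts, scan.windows, min_snps=3)
        got = scan.windows["hp"].tolist()
        assert len(got) == len(expected)
        for g, e in zip(got, expected):
            if np.isnan(e):
                assert np.isnan(g)
            else:
                assert g == pytest.approx(e, abs=1e-12)

    def test_scan_independent_of_row_order(self):
        lay = GenomeLayout((("chr1", 600_000),))
        rng = np.random.default_rng(5)
        counts = pd.DataFrame(
            {
                "chrom": "chr1",
                "pos": rng.integers(0, 600_000, 200),
                "n_maj": rng.integers(5, 30, 200),
                "n_min": rng.integers(0, 5, 200),
            }
        )
        a = scan_counts(counts, lay, min_snps=1).windows
        b = scan_counts(counts.sample(frac=1, random_state=1), lay, min_snps=1).windows
        assert a["hp"].tolist() == pytest.approx(b["hp"].tolist(), nan_ok=True)


def _mk_scan(zhp_by_window, chrom="chr1"):
    n = len(zhp_by_window)
    windows = pd.DataFrame(
        {
            "chrom": [chrom] * n,
            "start": np.arange(n) * 75_000,
            "end": np.arange(n) * 75_000 + 150_000,
            "n_snps": 50,
            "sum_maj": 0,
            "sum_min": 0,
            "hp": 0.2,
            "zhp": zhp_by_window,
        }
    )
    return HpScan(pool="t", windows=windows)


class TestSweepCalling:
    def test_single_candidate_window(self):
        loci = call_sweeps(_mk_scan([0.0, -4.5, 0.5]))
        assert len(loci) == 1
        l = loci[0]
        assert (l.tier, l.start, l.end, l.n_windows) == ("candidate", 75_000, 225_000, 1)

    def test_overlapping_windows_merge_and_tiers_are_independent(self):
        loci = call_sweeps(_mk_scan([-5.2, -6.1, 0.0]))
        by_tier = {l.tier: l for l in loci}
        cand = by_tier["candidate"]
        assert (cand.start, cand.end, cand.n_windows) == (0, 225_000, 2)
        assert cand.min_zhp == pytest.approx(-6.1)
        assert (by_tier["extreme"].start, by_tier["extreme"].end) == (75_000, 225_000)

    def test_book_ended_windows_merge(self):
        # windows [0,150k) and [150k,300k): book-ended, not overlapping
        windows = pd.DataFrame(
            {
                "chrom": ["chr1", "chr1"],
                "start": [0, 150_000],
                "end": [150_000, 300_000],
                "n_snps": 50,
                "sum_maj": 0,
                "sum_min": 0,
                "hp": 0.2,
                "zhp": [-4.2, -4.8],
            }
        )
        loci = call_sweeps(HpScan(pool="t", windows=windows))
        assert len(loci) == 1
        assert (loci[0].start, loci[0].end, loci[0].n_windows) == (0, 300_000, 2)

    def test_different_chromosomes_stay_separate(self):
        a = _mk_scan([-4.5]).windows
        b = _mk_scan([-4.5], chrom="chr2").windows
        scan = HpScan(pool="t", windows=pd.concat([a, b], ignore_index=True))
        loci = call_sweeps(scan)
        assert {l.chrom for l in loci} == {"chr1", "chr2"}

    def test_no_window_below_threshold_no_loci(self):
        assert call_sweeps(_mk_scan([-1.0, -3.9, 0.0])) == []

    def test_within_tier_loci_are_non_overlapping(self):
        rng = np.random.default_rng(17)
        loci = call_sweeps(_mk_scan(list(rng.uniform(-8, 1, 200))))
        for tier in ("candidate", "putative", "extreme"):
            tl = sorted((l for l in loci if l.tier == tier), key=lambda l: l.start)
            for x, y in zip(tl, tl[1:]):
                assert x.end <= y.start

    def test_stricter_threshold_loci_contained_in_looser(self):
        rng = np.random.default_rng(23)
        scan = _mk_scan(list(rng.uniform(-8, 1, 300)))
        loci = call_sweeps(scan)
        cand = [l for l in loci if l.tier == "candidate"]
        for tier in ("putative", "extreme"):
            for l in (x for x in loci if x.tier == tier):
                assert any(
                    c.chrom == l.chrom and c.start <= l.start and l.end <= c.end for c in cand
                )

    def test_selected_window_count_monotone_in_threshold(self):
        rng = np.random.default_rng(29)
        scan = _mk_scan(list(rng.uniform(-8, 1, 300)))
        z = scan.windows["zhp"]
        prev = None
        for thr in (-4, -5, -6, -7):
            n = int((z <= thr).sum())
            if prev is not None:
                assert n <= prev
            prev = n

    def test_all_windows_below_putative_merge_per_chromosome(self):
        a = _mk_scan([-5.5, -5.2, -5.9]).windows
        b = _mk_scan([-5.1, -5.3], chrom="chr2").windows
        scan = HpScan(pool="t", windows=pd.concat([a, b], ignore_index=True))
        put = [l for l in call_sweeps(scan) if l.tier == "putative"]
        assert len(put) == 2
        assert {l.chrom for l in put} == {"chr1", "chr2"}


class TestSweepReport:
    def test_tier_counts_and_shared_sections(self):
        loci_a = call_sweeps(_mk_scan([-6.5, 0, 0, -4.2]))
        loci_b = call_sweeps(_mk_scan([-4.5, 0, 0, 0]))
        rep = sweep_report({"A": loci_a, "B": loci_b})
        counts = rep["tier_counts"].set_index("pool")
        assert counts.loc["A", "candidate"] == 2
        assert counts.loc["A", "extreme"] == 1
        assert counts.loc["B", "candidate"] == 1
        shared = rep["shared"]
        assert len(shared) == 1  # both pools sweep the first window region
        assert shared.iloc[0]["tier"] == "candidate"

    def test_disjoint_pools_have_empty_shared_section(self):
        rep = sweep_report(
            {"A": call_sweeps(_mk_scan([-4.5, 0])), "B": call_sweeps(_mk_scan([0, 0, 0, -4.5]))}
        )
        assert rep["shared"].empty

    def test_loci_table_columns(self):
        tab = loci_table(call_sweeps(_mk_scan([-4.5])), pool="A")
        assert tab.columns.tolist() == [
            "pool", "chrom", "start", "end", "min_zhp", "n_windows", "tier",
        ]
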