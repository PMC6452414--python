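import math
import random

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from poolscan import (
    FilterCriteria,
    VariantType,
    Zygosity,
    apply_hard_filters,
    classify_variant_type,
    classify_zygosity,
    mask_low_gq,
    titv_ratio,
)
from poolscan.filtering import (
    MaskedPoolError,
    count_titv,
    hard_filter_frame,
    titv_from_alleles,
)
from poolscan.genome_io import PoolData

from conftest import PASS_INFO, make_record


class TestHardFilters:
    @pytest.mark.parametrize(
        "overrides, expected_reasons",
        [
            ({"QD": 1.5}, ("QD",)),
            ({"FS": 70.0}, ("FS",)),
            ({"MQ": 39.9}, ("MQ",)),
            ({"HaplotypeScore": 13.5}, ("HaplotypeScore",)),
            ({"MQRankSum": -13.0}, ("MQRankSum",)),
            ({"ReadPosRankSum": -9.0}, ("ReadPosRankSum",)),
            ({"QD": 1.0, "FS": 80.0}, ("FS", "QD")),
        ],
    )
    def test_single_and_multiple_violations_listed(self, overrides, expected_reasons):
        rec = make_record(info={**PASS_INFO, **overrides})
        verdict = apply_hard_filters(rec)
        assert not verdict.passed
        assert verdict.reasons == expected_reasons

    def test_low_qual_fails(self):
        verdict = apply_hard_filters(make_record(qual=29.9))
        assert verdict.reasons == ("QUAL",)

    def test_thresholds_are_strict_boundaries_pass(self):
        info = {"QD": 2.0, "MQ": 40.0, "FS": 60.0, "HaplotypeScore": 13.0,
                "MQRankSum": -12.5, "ReadPosRankSum": -8.0}
        verdict = apply_hard_filters(make_record(qual=30.0, info=info))
        assert verdict.passed and verdict.reasons == ()

    def test_absent_metrics_never_fail(self):
        verdict = apply_hard_filters(make_record(qual=None, info={}))
        assert verdict.passed

    def test_verdict_completeness_relaxing_flips_exactly_that_reason(self):
        """Relaxing only one violated criterion removes exactly that reason."""
        rec = make_record(qual=10.0, info={**PASS_INFO, "QD": 0.5, "FS": 90.0})
        base = apply_hard_filters(rec)
        assert base.reasons == ("FS", "QD", "QUAL")
        relax = {
            "QUAL": FilterCriteria(qual_min=5.0),
            "QD": FilterCriteria(qd_min=0.1),
            "FS": FilterCriteria(fs_max=100.0),
        }
        for reason, criteria in relax.items():
            new = apply_hard_filters(rec, criteria)
            assert set(base.reasons) - set(new.reasons) == {reason}

    @given(
        qd=st.floats(0, 40),
        mq=st.floats(0, 70),
        fs=st.floats(0, 120),
        qual=st.floats(0, 100),
        delta=st.floats(0.1, 10),
    )
    @settings(max_examples=100, deadline=None, derandomize=True)
    def test_tightening_any_threshold_is_monotone(self, qd, mq, fs, qual, delta):
        rec = make_record(qual=qual, info={**PASS_INFO, "QD": qd, "MQ": mq, "FS": fs})
        base = apply_hard_filters(rec).passed
        for tight in (
            FilterCriteria(qd_min=2.0 + delta),
            FilterCriteria(mq_min=40.0 + delta),
            FilterCriteria(fs_max=60.0 - delta),
            FilterCriteria(qual_min=30.0 + delta),
        ):
            tightened = apply_hard_filters(rec, tight).passed
            assert not (tightened and not base)

    def test_frame_path_agrees_with_record_path(self):
        rng = np.random.default_rng(11)
        n = 500
        table = pd.DataFrame(
            {
                "QUAL": rng.uniform(0, 60, n),
                "QD": rng.uniform(0, 5, n),
                "MQ": rng.uniform(30, 60, n),
                "FS": rng.uniform(0, 120, n),
                "HaplotypeScore": rng.uniform(0, 26, n),
                "MQRankSum": rng.uniform(-25, 5, n),
                "ReadPosRankSum": rng.uniform(-16, 5, n),
            }
        )
        table.loc[rng.choice(n, 50, replace=False), "QD"] = np.nan
        mask = hard_filter_frame(table)
        for i in range(n):
            row = table.iloc[i]
            info = {k: row[k] for k in PASS_INFO if not math.isnan(row[k])}
            rec = make_record(qual=row["QUAL"], info=info)
            assert apply_hard_filters(rec).passed == bool(mask.iloc[i])


class TestGqMask:
    def _two_pool_record(self, gq1, gq2):
        gt = (0,) * 50 + (1,) * 10
        pools = (PoolData((12, 8), gt, gq1), PoolData((11, 9), gt, gq2))
        return make_record(pools=pools)

    def test_low_gq_pool_masked_boundary_retained(self):
        rec = mask_low_gq(self._two_pool_record(19, 20))
        assert rec.pools[0].genotype is None and rec.pools[0].gq is None
        assert rec.pools[1].genotype is not None

    def test_read_depths_survive_masking(self):
        rec = mask_low_gq(self._two_pool_record(5, 99))
        assert rec.pools[0].allele_depths == (12, 8)

    def test_all_pools_masked_drops_record(self):
        assert mask_low_gq(self._two_pool_record(19, 3)) is None

    def test_absent_gq_is_retained(self):
        pools = (PoolData((12, 8), (0,) * 59 + (1,), None),)
        rec = mask_low_gq(make_record(pools=pools))
        assert rec.pools[0].genotype is not None


class TestVariantType:
    @pytest.mark.parametrize(
        "ref, alts, expected",
        [
            ("A", ("G",), VariantType.SNP),
            ("A", ("G", "T"), VariantType.SNP),
            ("AT", ("A",), VariantType.INDEL),
            ("A", ("AT",), VariantType.INDEL),
            ("A", ("G", "AT"), VariantType.MIXED),
        ],
    )
    def test_classification(self, ref, alts, expected):
        n = 1 + len(alts)
        pools = (PoolData((10,) * n, None, None),)
        assert classify_variant_type(make_record(ref=ref, alts=alts, pools=pools)) is expected


class TestZygosity:
    def _rec(self, genotype):
        return make_record(pools=(PoolData((12, 8), genotype, 60),))

    def test_all_alt_is_fixed(self):
        assert classify_zygosity(self._rec((1,) * 60), 0) is Zygosity.FIXED

    def test_half_ref_half_alt_is_segregating(self):
        assert classify_zygosity(self._rec((0,) * 30 + (1,) * 30), 0) is Zygosity.SEGREGATING

    def test_all_ref_is_reference(self):
        assert classify_zygosity(self._rec((0,) * 60), 0) is Zygosity.REFERENCE

    def test_masked_pool_raises(self):
        with pytest.raises(MaskedPoolError):
            classify_zygosity(self._rec(None), 0)


class TestTiTv:
    def test_worked_examples(self):
        recs = [make_record(ref=r, alts=(a,)) for r, a in [("A", "G"), ("C", "T"), ("A", "C")]]
        assert titv_ratio(recs) == pytest.approx(2.0)
        tvs = [make_record(ref=r, alts=(a,)) for r, a in [("A", "C"), ("G", "T")]]
        assert titv_ratio(tvs) == 0.0

    def test_zero_transversions_is_nan(self):
        assert math.isnan(titv_ratio([make_record(ref="A", alts=("G",))]))

    def test_multiallelic_counts_one_substitution_per_alt(self):
        rec = make_record(ref="A", alts=("G", "C"), pools=(PoolData((10, 5, 5), None, None),))
        assert titv_ratio([rec]) == pytest.approx(1.0)

    def test_indels_excluded(self):
        recs = [
            make_record(ref="A", alts=("G",)),
            make_record(ref="AT", alts=("A",), pools=(PoolData((10, 5), None, None),)),
            make_record(ref="A", alts=("C",)),
        ]
        assert titv_ratio(recs) == pytest.approx(1.0)

    def test_uniform_substitution_types_give_half(self):
        """4 of the 12 ordered substitution types are transitions, so uniform
        draws give Ti/Tv ≈ (1/3)/(2/3) = 0.5."""
        types = [
            (r, a) for r in "ACGT" for a in "ACGT" if r != a
        ]
        rng = random.Random(42)
        draws = [types[rng.randrange(12)] for _ in range(12_000)]
        ti, tv = count_titv(draws)
        ratio = ti / tv
        # 3 SD of the ratio via the delta method at p = 1/3
        assert abs(ratio - 0.5) < 0.03

    def test_order_invariance_and_merge_additivity(self):
        pairs = [("A", "G"), ("C", "A"), ("C", "T"), ("G", "T"), ("T", "C")]
        ti, tv = count_titv(pairs)
        rng = random.Random(7)
        for _ in range(5):
            rng.shuffle(pairs)
            assert count_titv(pairs) == (ti, tv)
        ti1, tv1 = count_titv(pairs[:2])
        ti2, tv2 = count_titv(pairs[2:])
        assert (ti1 + ti2, tv1 + tv2) == (ti, tv)

    def test_vectorised_path_agrees(self):
        rng = np.random.default_rng(3)
        bases = np.array(list("ACGT"))
        refs = bases[rng.integers(0, 4, 300)]
        shift = rng.integers(1, 4, 300)
        alts = bases[(np.searchsorted(bases, refs) + shift) % 4]
        recs = [make_record(ref=r, alts=(a,)) for r, a in zip(refs, alts)]
        assert titv_from_alleles(refs, alts) == pytest.approx(titv_ratio(recs))
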