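"""Unit and property tests for the T1/ECV metric chain."""

import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from iecvstage import (
    MetricsUnavailableError,
    Segment,
    SegmentalT1Panel,
    bsa_du_bois,
    compute_cohort_metrics,
    compute_ecv_metrics,
    ecv_fraction,
    partition_coefficient,
    select_usable_segments,
)
from iecvstage.metrics import indexed_volume
from iecvstage.utils import round_half_up


def make_panel(native=1170.0, post=640.0, flags=("none",) * 6,
               blood_native=1820.0, blood_post=480.0, hct=0.41):
    segs = tuple(Segment(native, post, f) for f in flags)
    return SegmentalT1Panel(segs, blood_native, blood_post, hct)


class TestBsaDuBois:
    def test_reference_value(self):
        assert bsa_du_bois(180, 70) == pytest.approx(1.886, abs=1e-3)

    def test_weight_power_law(self):
        assert bsa_du_bois(175, 160) / bsa_du_bois(175, 80) == pytest.approx(
            2**0.425, rel=1e-12
        )

    @pytest.mark.parametrize("h,w", [(0, 70), (180, 0), (-5, 70), (180, -1)])
    def test_domain_errors(self, h, w):
        with pytest.raises(ValueError):
            bsa_du_bois(h, w)


class TestSegmentSelection:
    def test_no_exclusions(self):
        assert len(select_usable_segments(make_panel())) == 6

    def test_all_infarct_unavailable(self):
        with pytest.raises(MetricsUnavailableError):
            select_usable_segments(make_panel(flags=("infarct",) * 6))

    def test_midwall_kept_infarct_dropped(self):
        flags = ("midwall", "infarct", "none", "none", "none", "infarct")
        usable = select_usable_segments(make_panel(flags=flags))
        assert len(usable) == 4
        assert sum(s.lge == "midwall" for s in usable) == 1

    def test_missing_t1_segments_dropped(self):
        segs = (Segment(np.nan, np.nan),) * 6
        panel = SegmentalT1Panel(segs, 1820, 480, 0.41)
        with pytest.raises(MetricsUnavailableError):
            select_usable_segments(panel)


class TestPartitionCoefficient:
    def test_ratio_identity(self):
        # myocardial dR1 equal to blood dR1 -> lambda = 1
        assert partition_coefficient(1200, 600, 1200, 600) == pytest.approx(1.0)

    def test_half_blood_delta(self):
        # choose the blood pair so blood dR1 is exactly twice myocardial dR1
        native, post = 1166.0, 645.0
        dr1_myo = 1 / post - 1 / native
        blood_native = 1800.0
        blood_post = 1 / (2 * dr1_myo + 1 / blood_native)
        lam = partition_coefficient(native, post, blood_native, blood_post)
        assert lam == pytest.approx(0.5, rel=1e-12)

    def test_post_above_native_rejected(self):
        with pytest.raises(ValueError):
            partition_coefficient(600, 700, 1800, 480)

    def test_nonphysiologic_blood_kinetics_rejected(self):
        with pytest.raises(ValueError):
            partition_coefficient(1200, 600, 480, 1800)


class TestEcvFraction:
    def test_zero_hematocrit_boundary(self):
        assert ecv_fraction(0.45, 0.0) == pytest.approx(0.45)

    def test_group_mean_consistency(self):
        # lambda 0.45 with Hct 0.41 sits at the 26.5% control ECV scale
        assert ecv_fraction(0.45, 0.41) == pytest.approx(0.2655)
        assert ecv_fraction(0.46, 0.40) == pytest.approx(0.276)

    @pytest.mark.parametrize("hct", [1.0, 1.5, -0.1])
    def test_hematocrit_domain(self, hct):
        with pytest.raises(ValueError):
            ecv_fraction(0.45, hct)


class TestComputeEcvMetrics:
    def test_arithmetic_identity(self):
        # force ECV = 0.25 via lambda = 0.25 / (1 - hct)
        hct = 0.40
        lam = 0.25 / (1 - hct)
        blood_native, blood_post = 1800.0, 480.0
        dr1_b = 1 / blood_post - 1 / blood_native
        native = 1200.0
        post = 1 / (1 / native + lam * dr1_b)
        panel = make_panel(native, post, blood_native=blood_native,
                           blood_post=blood_post, hct=hct)
        m = compute_ecv_metrics(panel, lv_mass_g=105.0, bsa_m2=2.0)  # 100 ml myo
        assert m.ecv_fraction == pytest.approx(0.25, rel=1e-12)
        assert m.myocardial_volume_ml == pytest.approx(100.0)
        assert m.fibrosis_volume_ml == pytest.approx(25.0, rel=1e-12)
        assert m.iecv_ml_m2 == pytest.approx(12.5, rel=1e-12)

    def test_group_level_indexing(self):
        # published group means: fibrosis volume / BSA at 1 d.p.
        assert round_half_up(indexed_volume(29.9, 1.86), 1) == 16.1
        assert round_half_up(indexed_volume(44.4, 1.88), 1) == 23.6

    def test_chain_identity(self):
        panel = make_panel()
        m = compute_ecv_metrics(panel, 150.0, 1.9)
        assert m.iecv_ml_m2 * 1.9 / m.myocardial_volume_ml == pytest.approx(
            m.ecv_fraction, rel=1e-12
        )
        assert m.fibrosis_volume_ml == pytest.approx(
            m.ecv_fraction * m.myocardial_volume_ml, rel=1e-12
        )

    def test_segment_order_invariance(self):
        natives = [1150, 1160, 1170, 1180, 1190, 1200]
        posts = [630, 635, 640, 645, 650, 655]
        flags = ["none", "midwall", "none", "none", "none", "none"]
        def build(order):
            segs = tuple(Segment(natives[i], posts[i], flags[i]) for i in order)
            return SegmentalT1Panel(segs, 1820, 480, 0.41)
        m1 = compute_ecv_metrics(build(range(6)), 150, 1.9)
        m2 = compute_ecv_metrics(build([5, 3, 1, 0, 2, 4]), 150, 1.9)
        assert m1 == m2

    def test_propagates_unavailable(self):
        with pytest.raises(MetricsUnavailableError):
            compute_ecv_metrics(make_panel(flags=("infarct",) * 6), 150, 1.9)

    @settings(max_examples=50, derandomize=True, deadline=None)
    @given(
        drop=st.floats(min_value=1.0, max_value=400.0),
        extra=st.floats(min_value=1.0, max_value=200.0),
    )
    def test_monotone_in_myocardial_delta_r1(self, drop, extra):
        """Larger myocardial dR1 (lower post T1) increases lambda/ECV/iECV."""
        base = compute_ecv_metrics(make_panel(post=1170 - drop), 150, 1.9)
        more = compute_ecv_metrics(make_panel(post=1170 - drop - extra), 150, 1.9)
        assert more.partition_coefficient > base.partition_coefficient
        assert more.ecv_fraction > base.ecv_fraction
        assert more.fibrosis_volume_ml > base.fibrosis_volume_ml
        assert more.iecv_ml_m2 > base.iecv_ml_m2


class TestCohortMetrics:
    def test_generator_round_trip_exact(self, big_cohort, big_metrics):
        """Noise-free recovery: computed ECV/iECV equal the generator targets."""
        ok = big_metrics["metrics_status"] == "ok"
        assert ok.sum() > 0.9 * len(big_cohort)
        d_ecv = np.abs(
            big_metrics.loc[ok, "ecv_fraction"] - big_cohort.loc[ok, "true_ecv_fraction"]
        )
        d_iecv = np.abs(
            big_metrics.loc[ok, "iecv_ml_m2"] - big_cohort.loc[ok, "true_iecv"]
        )
        assert d_ecv.max() < 1e-9
        assert d_iecv.max() < 1e-9 * big_cohort.loc[ok, "true_iecv"].max()

    def test_missing_t1_flagged_not_raised(self, cohort):
        m = compute_cohort_metrics(cohort)
        miss = cohort["missing_t1"] == 1
        assert (m.loc[miss, "metrics_status"] == "no_usable_segments").all()
        assert m.loc[miss, "iecv_ml_m2"].isna().all()

    def test_physiologic_ranges(self, big_metrics):
        ok = big_metrics["metrics_status"] == "ok"
        ecv = big_metrics.loc[ok, "ecv_fraction"]
        assert ((ecv > 0) & (ecv < 1)).all()
        assert (big_metrics.loc[ok, "partition_coefficient"] > 0).all()
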