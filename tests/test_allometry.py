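"""Ratio calibrations, OLS trendlines, and fossil size estimates.

Expected numbers were frozen from an independent oracle (direct arithmetic
and numpy.polyfit on the bundled calibration table); a few are re-derived
inline where the oracle is a one-liner.
"""

import math

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

from varanosize.allometry import (
    DegenerateFitError,
    ProxyTrendline,
    RatioCalibration,
    build_estimate_table,
    compute_ratio_model,
    estimate_pcl,
    fit_trendline,
    per_specimen_ratios,
    predict_from_trendline,
)
from varanosize.records import FossilMeasurement, Proxy, SpecimenRecord

KOMODO_IDS = ["AMNH R 37908", "AMNH R 37909"]
INDO_ASIAN_A_IDS = [
    "AMNH R 29932",
    "AMNH R 118713",
    "AMNH R 77646",
    "UF 64743",
    "AMNH R 141071",
    "AMNH R 49230",
]


def _spec(i, pcl, proxy, kind=Proxy.BCL):
    kw = {"bcl": proxy} if kind is Proxy.BCL else {"dvl": proxy}
    return SpecimenRecord(specimen_id=f"S{i}", species="sp", pcl=pcl, **kw)


class TestPerSpecimenRatios:
    def test_komodoensis_ratio_is_direct_division(self, specimens):
        rec = next(s for s in specimens if s.specimen_id == "AMNH R 37908")
        (ratio,) = per_specimen_ratios([rec], "BCL")
        assert ratio == pytest.approx(718 / 44, abs=1e-12)
        assert round(ratio, 3) == 16.318

    def test_equal_pcl_and_proxy_gives_unity(self):
        assert per_specimen_ratios([_spec(0, 50, 50)], "BCL") == [1.0]

    def test_full_table_extremes(self, specimens):
        ratios = per_specimen_ratios(specimens, Proxy.BCL)
        assert len(ratios) == 21
        assert min(ratios) == pytest.approx(393 / 29.5, abs=1e-9)  # ornatus
        assert max(ratios) == pytest.approx(650 / 28, abs=1e-9)  # gouldii

    def test_missing_proxy_names_specimen(self):
        rec = SpecimenRecord(specimen_id="NO-DVL", species="x", pcl=100, bcl=10)
        with pytest.raises(ValueError, match="NO-DVL"):
            per_specimen_ratios([rec], "DVL")


class TestRatioCalibration:
    @pytest.mark.parametrize(
        "member_ids,proxy,mean,sd,n",
        [
            (None, "BCL", 17.68, 2.322, 21),
            (None, "DVL", 37.84, 3.791, 21),
            (KOMODO_IDS, "BCL", 16.76, 0.474, 2),
            (KOMODO_IDS, "DVL", 39.93, 2.309, 2),
            (INDO_ASIAN_A_IDS, "BCL", 18.57, 2.73, 6),
            (INDO_ASIAN_A_IDS, "DVL", 36.91, 2.562, 6),
        ],
    )
    def test_group_statistics(self, specimens, member_ids, proxy, mean, sd, n):
        res = RatioCalibration(specimens, proxy, member_ids=member_ids).fit()
        assert res.n == n
        assert res.mean_ratio == pytest.approx(mean, abs=0.005)
        assert res.sd == pytest.approx(sd, abs=0.005)

    def test_ratio_of_sums_differs_from_mean_of_ratios(self, specimens):
        # the two conventions disagree on this table; the calibration uses
        # the sum ratio, which is what every published group mean matches
        ros = RatioCalibration(specimens, "BCL").fit().mean_ratio
        mor = float(np.mean(per_specimen_ratios(specimens, "BCL")))
        assert round(ros, 2) == 17.68
        assert round(mor, 2) == 17.65
        assert ros != pytest.approx(mor, abs=1e-3)

    def test_identical_specimens_have_zero_sd(self):
        recs = [_spec(i, 100, 10) for i in range(2)]
        res = RatioCalibration(recs, "BCL").fit()
        assert res.mean_ratio == 10.0 and res.sd == 0.0

    def test_single_specimen_model_has_no_sd(self):
        res = RatioCalibration([_spec(0, 100, 10)], "BCL").fit()
        assert res.sd is None and res.n == 1

    def test_empty_group_raises(self):
        with pytest.raises(ValueError, match="no members"):
            RatioCalibration([], "BCL")

    def test_unknown_member_id_raises(self, specimens):
        with pytest.raises(KeyError, match="GHOST"):
            RatioCalibration(specimens, "BCL", member_ids=["GHOST"])

    def test_from_dataframe_matches_records(self, specimens):
        from varanosize.io import load_bundled_fixture

        df = load_bundled_fixture("specimens")
        res = RatioCalibration.from_dataframe(df, "BCL").fit()
        assert res.mean_ratio == pytest.approx(
            RatioCalibration(specimens, "BCL").fit().mean_ratio, rel=1e-12
        )

    @given(
        data=st.lists(
            st.tuples(
                st.floats(100, 2000),
                st.floats(5, 100),
            ),
            min_size=2,
            max_size=12,
        ),
        scale=st.floats(0.01, 100),
    )
    def test_scale_equivariance_and_boundedness(self, data, scale):
        recs = [_spec(i, p, x) for i, (p, x) in enumerate(data)]
        res = RatioCalibration(recs, "BCL").fit()
        ratios = per_specimen_ratios(recs, "BCL")
        assert min(ratios) - 1e-9 <= res.mean_ratio <= max(ratios) + 1e-9
        scaled = [_spec(i, p * scale, x * scale) for i, (p, x) in enumerate(data)]
        res2 = RatioCalibration(scaled, "BCL").fit()
        assert res2.mean_ratio == pytest.approx(res.mean_ratio, rel=1e-9)
        assert res2.sd == pytest.approx(res.sd, rel=1e-6, abs=1e-9)


class TestTrendline:
    def test_komodoensis_two_point_bcl_line(self, specimens):
        model = ProxyTrendline(
            [s for s in specimens if s.species == "komodoensis"], "BCL"
        ).fit()
        assert model.slope == pytest.approx(17.67, abs=0.005)
        assert model.intercept == pytest.approx(-59.67, abs=0.005)
        assert model.r_squared == pytest.approx(1.0, abs=1e-9)

    def test_exact_line_recovered(self):
        recs = [_spec(i, 2 * x + 1, x) for i, x in enumerate([1, 2, 5, 9])]
        m = fit_trendline(recs, "BCL")
        assert m.slope == pytest.approx(2, abs=1e-9)
        assert m.intercept == pytest.approx(1, abs=1e-9)
        assert m.r_squared == pytest.approx(1, abs=1e-9)

    def test_all_data_dvl_line_matches_numpy_oracle(self, specimens):
        m = fit_trendline(specimens, "DVL")
        x = np.array([s.dvl for s in specimens])
        y = np.array([s.pcl for s in specimens])
        slope, intercept = np.polyfit(x, y, 1)
        assert m.slope == pytest.approx(slope, rel=1e-9)
        assert m.intercept == pytest.approx(intercept, rel=1e-9)
        assert m.r_squared == pytest.approx(np.corrcoef(x, y)[0, 1] ** 2, rel=1e-9)

    def test_line_passes_through_centroid(self, specimens):
        m = fit_trendline(specimens, "BCL")
        xbar = np.mean([s.bcl for s in specimens])
        ybar = np.mean([s.pcl for s in specimens])
        assert m.predict(xbar) == pytest.approx(ybar, rel=1e-9)

    def test_degenerate_fit_rejected(self):
        recs = [_spec(i, p, 10) for i, p in enumerate([100, 200, 300])]
        with pytest.raises(DegenerateFitError):
            ProxyTrendline(recs, "BCL")

    def test_prediction_from_identity_line(self):
        recs = [_spec(i, x, x) for i, x in enumerate([1, 2, 3])]
        m = fit_trendline(recs, "BCL")
        f = FossilMeasurement(taxon="q", proxy_kind=Proxy.BCL, length=7)
        assert predict_from_trendline(m, f) == pytest.approx(7, abs=1e-9)

    def test_komodoensis_line_passes_through_calibration_point(self, specimens):
        m = ProxyTrendline(
            [s for s in specimens if s.species == "komodoensis"], "BCL"
        ).fit()
        assert m.predict(44) == pytest.approx(718, abs=1e-6)


class TestEstimatePcl:
    def test_priscus_from_komodoensis_dvl_model(self, specimens):
        model = compute_ratio_model(
            [s for s in specimens if s.species == "komodoensis"], "DVL", "komodoensis"
        )
        fossil = FossilMeasurement(taxon="Varanus priscus", proxy_kind=Proxy.DVL, length=53)
        est = estimate_pcl(model, fossil)
        assert est.pcl_mm == pytest.approx(2116, abs=0.5)
        assert est.ci_halfwidth_mm == pytest.approx(169.6, abs=0.05)

    def test_zero_sd_model_gives_zero_halfwidth(self):
        recs = [_spec(i, 100, 10) for i in range(4)]
        model = compute_ratio_model(recs, "BCL")
        est = estimate_pcl(model, FossilMeasurement(taxon="q", proxy_kind=Proxy.BCL, length=5))
        assert est.pcl_mm == 50 and est.ci_halfwidth_mm == 0

    def test_proxy_mismatch_rejected(self, specimens):
        model = compute_ratio_model(specimens, "BCL")
        with pytest.raises(ValueError, match="mismatch"):
            estimate_pcl(model, FossilMeasurement(taxon="q", proxy_kind=Proxy.DVL, length=5))

    def test_single_specimen_estimate_warns_without_interval(self):
        model = compute_ratio_model([_spec(0, 100, 10)], "BCL")
        with pytest.warns(UserWarning, match="n=1"):
            est = estimate_pcl(model, FossilMeasurement(taxon="q", proxy_kind=Proxy.BCL, length=3))
        assert est.pcl_mm == 30 and est.ci_halfwidth_mm is None

    def test_fossil_length_scaling_is_exact(self, specimens):
        model = compute_ratio_model(specimens, "BCL")
        e1 = estimate_pcl(model, FossilMeasurement(taxon="q", proxy_kind=Proxy.BCL, length=10))
        e3 = estimate_pcl(model, FossilMeasurement(taxon="q", proxy_kind=Proxy.BCL, length=30))
        assert e3.pcl_mm == pytest.approx(3 * e1.pcl_mm, rel=1e-12)
        assert e3.ci_halfwidth_mm == pytest.approx(3 * e1.ci_halfwidth_mm, rel=1e-12)

    @given(
        sd_scale=st.floats(1.01, 5),
        length_scale=st.floats(1.01, 5),
    )
    def test_ci_halfwidth_monotonicity(self, sd_scale, length_scale):
        # half-width = z * sd * L / sqrt(n): increasing in sd and L,
        # decreasing in n
        z, sd, L, n = 1.96, 2.0, 40.0, 6
        base = z * sd * L / math.sqrt(n)
        assert z * sd * sd_scale * L / math.sqrt(n) > base
        assert z * sd * L * length_scale / math.sqrt(n) > base
        assert z * sd * L / math.sqrt(n + 1) < base


class TestEstimateTable:
    def test_default_plan_reproduces_reference(
        self, specimens, fossils, group_config, reference_estimates
    ):
        ests = build_estimate_table(specimens, fossils, group_config)
        assert len(ests) == 11
        for est, (_, ref) in zip(ests, reference_estimates.iterrows()):
            assert est.model.group_label == ref["group"]
            assert est.fossil.proxy_kind.value == ref["proxy"]
            assert est.pcl_mm == pytest.approx(float(ref["pcl_est_mm"]), abs=0.5)

    def test_amnhophilis_all_varanus_bcl_row(self, specimens, fossils, group_config):
        ests = build_estimate_table(specimens, fossils, group_config)
        row = next(
            e
            for e in ests
            if e.fossil.label == "V. amnhophilis"
            and e.model.group_label == "all_varanus"
            and e.fossil.proxy_kind is Proxy.BCL
        )
        assert round(row.pcl_mm, 1) == 678.6
        assert round(row.ci_halfwidth_mm, 1) == 38.1

    def test_empty_plan_gives_empty_output(self, specimens, fossils, group_config):
        from varanosize.io import GroupConfig

        cfg = GroupConfig(groups=group_config.groups, estimates=[])
        assert build_estimate_table(specimens, [], cfg) == []

    def test_unresolvable_plan_row_raises(self, specimens, group_config):
        with pytest.raises(KeyError, match="Saniwa"):
            build_estimate_table(specimens, [], group_config)
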