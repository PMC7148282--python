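import numpy as np
import pandas as pd
import pytest

from wearvalid.parameter_level import (
    Parameter,
    bland_altman,
    derive_boundary,
    parameter_decision,
)

PRINTED_BOUNDARIES = [
    (Parameter.SCL, 0.0, 16.0, 1.6),
    (Parameter.SCR_RATE, 0.0, 25.0, 2.5),
    (Parameter.S_AMPL, 0.0, 6.0, 0.6),
    (Parameter.HR, 60.0, 110.0, 5.0),
    (Parameter.SD_INTERVAL, 0.0, 0.56, 0.06),
    (Parameter.RMSSD, 0.0, 0.71, 0.07),
]


class TestBoundaries:
    @pytest.mark.parametrize("param,lo,hi,expected", PRINTED_BOUNDARIES)
    def test_ten_percent_of_plausible_range(self, param, lo, hi, expected):
        b = derive_boundary(param, lo, hi)
        assert b.boundary == pytest.approx(expected, abs=1e-12)

    def test_degenerate_range_rejected(self):
        with pytest.raises(ValueError):
            derive_boundary(Parameter.HR, 60.0, 60.0)

    def test_fraction_bounds(self):
        with pytest.raises(ValueError):
            derive_boundary(Parameter.HR, 60.0, 110.0, fraction=1.5)


def pairs_from_diffs(diffs, rd_base=10.0):
    rd = np.full(len(diffs), rd_base) + np.arange(len(diffs)) * 0.1
    return pd.DataFrame(
        {
            "participant": [f"p{i}" for i in range(len(diffs))],
            "rd": rd,
            "wd": rd + np.asarray(diffs, float),
        }
    )


class TestBlandAltman:
    def test_constant_offset(self):
        b = derive_boundary(Parameter.HR, 60, 110)
        res = bland_altman(pairs_from_diffs([2.0] * 6), b)
        assert res.mean_diff == pytest.approx(2.0)
        assert res.sd_diff == pytest.approx(0.0)
        assert res.pct_within_boundary == 100.0

    def test_hand_computed_four_pair_oracle(self):
        diffs = [-1.0, 0.0, 1.0, 2.0]
        # by hand: mean 0.5, sd = sqrt(((1.5)^2+(0.5)^2+(0.5)^2+(1.5)^2)/3)
        sd = np.sqrt(5.0 / 3.0)
        b = derive_boundary(Parameter.HR, 60, 110)
        res = bland_altman(pairs_from_diffs(diffs), b)
        assert res.mean_diff == pytest.approx(0.5, abs=1e-12)
        assert res.sd_diff == pytest.approx(sd, abs=1e-12)
        assert res.loa_low == pytest.approx(0.5 - 1.96 * sd, abs=1e-12)
        assert res.loa_high == pytest.approx(0.5 + 1.96 * sd, abs=1e-12)
        assert res.pct_within_boundary == 100.0

    def test_gaussian_pct_within_loa_near_95(self):
        rng = np.random.default_rng(11)
        res = bland_altman(
            pairs_from_diffs(rng.normal(0, 1.0, size=10000)),
            derive_boundary(Parameter.HR, 60, 110),
        )
        assert res.pct_within_loa == pytest.approx(95.0, abs=0.6)

    def test_swapping_devices_negates_stats(self):
        rng = np.random.default_rng(4)
        df = pairs_from_diffs(rng.normal(0, 2, size=30))
        b = derive_boundary(Parameter.HR, 60, 110)
        res = bland_altman(df, b)
        swapped = df.rename(columns={"rd": "wd", "wd": "rd"})
        res2 = bland_altman(swapped, b)
        assert res2.mean_diff == pytest.approx(-res.mean_diff)
        assert res2.loa_low == pytest.approx(-res.loa_high)
        assert res2.loa_high == pytest.approx(-res.loa_low)

    def test_missing_pairs_dropped_and_counted(self):
        df = pairs_from_diffs([0.1, 0.2, -0.1, 0.3])
        df.loc[1, "wd"] = np.nan
        res = bland_altman(df, derive_boundary(Parameter.HR, 60, 110))
        assert res.n == 3 and res.n_dropped == 1

    def test_too_few_pairs_rejected(self):
        with pytest.raises(ValueError):
            bland_altman(
                pairs_from_diffs([0.1, 0.2]),
                derive_boundary(Parameter.HR, 60, 110),
            )

    def test_log_transform_recorded_for_skewed_diffs(self):
        rng = np.random.default_rng(8)
        rd = rng.lognormal(0.0, 0.8, size=80) + 1.0
        wd = rd * rng.lognormal(0.5, 0.8, size=80)
        df = pd.DataFrame(
            {"participant": [f"p{i}" for i in range(80)], "rd": rd, "wd": wd}
        )
        res = bland_altman(df, derive_boundary(Parameter.SCL, 0, 16))
        assert res.normality_p_raw is not None and res.normality_p_raw < 0.05
        assert res.transform == "log"
        # statistics remain raw-scale
        assert res.mean_diff == pytest.approx(float((wd - rd).mean()))


class TestDecision:
    def _result(self, loa, mean=None, ci=None, n=10):
        from wearvalid.parameter_level import BlandAltmanResult

        mean = mean if mean is not None else (loa[0] + loa[1]) / 2
        ci = ci or (mean - 0.1, mean + 0.1)
        return BlandAltmanResult(
            parameter=Parameter.HR,
            pairs=pd.DataFrame(
                {"participant": ["a"] * n, "rd": np.arange(n, dtype=float),
                 "wd": np.arange(n, dtype=float),
                 "mean": np.arange(n, dtype=float), "diff": np.zeros(n)}
            ),
            mean_diff=mean, sd_diff=1.0,
            loa_low=loa[0], loa_high=loa[1],
            pct_within_boundary=100.0, pct_within_loa=95.0,
            n=n, n_dropped=0, transform="none",
            normality_p_raw=0.5, normality_p_transformed=None,
            mean_diff_ci=ci,
        )

    def test_limits_inside_boundary_valid(self):
        b = derive_boundary(Parameter.HR, 60, 110)
        v = parameter_decision(self._result((-2.0, 3.0), ci=(-1.0, 2.0)), b)
        assert v.status == "valid" and not v.biased

    def test_limit_outside_boundary_invalid(self):
        b = derive_boundary(Parameter.HR, 60, 110)
        v = parameter_decision(self._result((-6.0, 1.0)), b)
        assert v.status == "invalid"

    def test_ci_excluding_zero_flags_bias(self):
        b = derive_boundary(Parameter.HR, 60, 110)
        v = parameter_decision(
            self._result((-4.0, 1.0), mean=-1.2, ci=(-2.1, -0.3)), b
        )
        assert v.biased
        assert any("underestimates" in r for r in v.reasons)

    def test_enlarging_boundary_never_invalidates(self):
        small = derive_boundary(Parameter.HR, 60, 110, fraction=0.05)
        large = derive_boundary(Parameter.HR, 60, 110, fraction=0.20)
        rng = np.random.default_rng(2)
        for _ in range(25):
            lo = rng.uniform(-8, 0)
            hi = lo + rng.uniform(0, 8)
            res = self._result((lo, hi))
            if parameter_decision(res, small).status == "valid":
                assert parameter_decision(res, large).status == "valid"
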