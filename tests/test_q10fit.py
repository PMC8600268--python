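"""Fluctuating-temperature Q10 models and their nonlinear fits."""

import subprocess
import textwrap

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from hopperdev import (
    UnidentifiableModelError,
    adult_mass,
    development_days,
    fit_development_q10,
    fit_growth_q10,
    normalize_relative,
)
from hopperdev.q10fit import Q10Fit

from conftest import make_rearing_frame


class TestModelForms:
    @pytest.mark.parametrize(
        "c,q10,tvar,expected",
        [
            (100.0, 3.0, 0.0, 50.0),      # bracket = 2 at tvar 0
            (100.0, 1.0, 4.0, 50.0),      # temperature-insensitive
            (100.0, 4.0, 4.0, 43.19),     # 100 / (4**0.4 + 4**-0.4)
        ],
    )
    def test_development_days_values(self, c, q10, tvar, expected):
        assert development_days(c, q10, tvar) == pytest.approx(expected, abs=0.01)

    def test_adult_mass_values(self):
        assert adult_mass(0.01, 10.0, 1.0, 3.0) == pytest.approx(0.2)
        assert adult_mass(0.005, 43.19, 4.0, 4.0) == pytest.approx(0.500, abs=0.001)

    def test_domain_errors(self):
        with pytest.raises(ValueError):
            development_days(-1.0, 2.0, 4.0)
        with pytest.raises(ValueError):
            development_days(100.0, 0.0, 4.0)
        with pytest.raises(ValueError):
            adult_mass(0.005, -1.0, 2.0, 4.0)

    @settings(deadline=None)
    @given(c=st.floats(10.0, 500.0), q10=st.floats(0.3, 10.0))
    def test_development_days_monotone_in_tvar(self, c, q10):
        """Strictly decreasing in Tvar whenever q10 != 1: the bracket is
        2*cosh((Tvar/10)*ln q10), even in ln q10, so more variance always
        speeds development; at q10 = 1 it is flat."""
        tvars = np.linspace(0.0, 8.0, 9)
        d = development_days(c, q10, tvars)
        if abs(q10 - 1.0) > 1e-3:
            assert np.all(np.diff(d) < 0)
        else:
            assert d == pytest.approx(np.full_like(tvars, c / 2.0))

    @settings(deadline=None)
    @given(
        c_dev=st.floats(20.0, 300.0),
        c_growth=st.floats(0.001, 0.1),
        q10=st.floats(0.5, 8.0),
        tvar_a=st.floats(0.0, 8.0),
        tvar_b=st.floats(0.0, 8.0),
    )
    def test_mass_invariance_under_shared_q10(self, c_dev, c_growth, q10, tvar_a, tvar_b):
        """When d follows the development model with the same Q10, the
        brackets cancel and mass is independent of Tvar (exact algebra)."""
        masses = [
            adult_mass(c_growth, development_days(c_dev, q10, tv), q10, tv)
            for tv in (tvar_a, tvar_b)
        ]
        assert masses[0] == pytest.approx(masses[1], rel=1e-12)
        assert masses[0] == pytest.approx(c_growth * c_dev, rel=1e-12)


class TestDevelopmentFit:
    def test_noiseless_recovery_is_exact(self, rng):
        df = make_rearing_frame(100.0, 4.0, [2.0, 4.0], 10, 0.0, rng)
        fit = fit_development_q10(df)[0]
        assert fit.converged
        assert fit.q10 == pytest.approx(4.0, abs=1e-3)
        assert fit.c == pytest.approx(100.0, abs=0.1)

    @pytest.mark.parametrize("draw", range(10))
    def test_noiseless_round_trip_random_parameters(self, draw):
        rng = np.random.default_rng(1000 + draw)
        c = rng.uniform(40.0, 200.0)
        q10 = rng.uniform(0.5, 6.0)
        df = make_rearing_frame(c, q10, [1.0, 3.0, 5.0], 4, 0.0, rng)
        fit = fit_development_q10(df)[0]
        # the model is invariant under q10 -> 1/q10 (cosh symmetry), so
        # either representative is an exact recovery
        assert min(abs(fit.q10 - q10), abs(fit.q10 - 1.0 / q10)) < 1e-3 * q10
        assert fit.c == pytest.approx(c, rel=1e-3)

    def test_monte_carlo_bias_is_small(self):
        """200 noisy replicate fits (sd 2 days, n=40): median in [3.5, 4.5]
        and |mean - 4| < 0.3 at truth Q10 = 4."""
        rng = np.random.default_rng(202)
        est = []
        for _ in range(200):
            df = make_rearing_frame(100.0, 4.0, [2.0, 4.0], 20, 2.0, rng)
            est.append(fit_development_q10(df)[0].q10)
        est = np.array(est)
        assert 3.5 <= np.median(est) <= 4.5
        assert abs(est.mean() - 4.0) < 0.3

    def test_single_tvar_group_is_unidentifiable(self, rng):
        df = make_rearing_frame(100.0, 4.0, [4.0], 10, 0.0, rng)
        with pytest.raises(UnidentifiableModelError, match="X"):
            fit_development_q10(df)

    def test_groups_are_fit_independently(self, rng):
        a = make_rearing_frame(100.0, 4.0, [2.0, 4.0], 8, 0.0, rng, site="A1")
        b = make_rearing_frame(80.0, 2.0, [2.0, 4.0], 8, 0.0, rng, site="C1")
        fits = fit_development_q10(pd.concat([a, b], ignore_index=True))
        by_site = {f.group[0]: f for f in fits}
        assert by_site["A1"].q10 == pytest.approx(4.0, abs=1e-3)
        assert by_site["C1"].q10 == pytest.approx(2.0, abs=1e-3)

    def test_agrees_with_gnls_reference_fit(self, tmp_path, rng):
        """Independent oracle: the same model fitted by nlme::gnls in R."""
        df = make_rearing_frame(90.0, 3.0, [2.0, 4.0], 15, 1.5, rng)
        csv = tmp_path / "obs.csv"
        df[["tvar_c", "dev_days"]].to_csv(csv, index=False)
        script = tmp_path / "fit.R"
        script.write_text(textwrap.dedent(f"""
            suppressMessages(library(nlme))
            d <- read.csv("{csv}")
            m <- gnls(dev_days ~ c/(q10^(tvar_c/10) + q10^(-tvar_c/10)),
                      data=d, start=list(c=100, q10=2))
            cat(coef(m)[["c"]], coef(m)[["q10"]], "\\n")
        """))
        out = subprocess.run(
            ["Rscript", str(script)], capture_output=True, text=True, check=True
        )
        c_ref, q10_ref = map(float, out.stdout.split())
        fit = fit_development_q10(df)[0]
        assert fit.c == pytest.approx(c_ref, rel=1e-5)
        assert fit.q10 == pytest.approx(q10_ref, rel=1e-5)


class TestGrowthFit:
    @staticmethod
    def _growth_frame(c, q10, rng, n=30):
        tvar = rng.choice([2.0, 4.0], size=n)
        d = rng.uniform(30.0, 60.0, size=n)
        m = adult_mass(c, d, q10, tvar)
        return pd.DataFrame(
            {"site": "X", "photoperiod": "s", "sex": "f",
             "tvar_c": tvar, "dev_days": d, "mass_g": m}
        )

    def test_noiseless_recovery(self, rng):
        fit = fit_growth_q10(self._growth_frame(0.005, 3.0, rng))[0]
        assert fit.q10 == pytest.approx(3.0, abs=1e-3)
        assert fit.c == pytest.approx(0.005, rel=1e-3)

    def test_q10_one_reduces_to_linear_scaling(self, rng):
        df = self._growth_frame(0.004, 1.0, rng)
        fit = fit_growth_q10(df)[0]
        # the fitted bracket must be flat: predicted mass matches c*2*d
        assert fit.c * 2.0 == pytest.approx(
            float(np.mean(df["mass_g"] / df["dev_days"])), rel=1e-6
        )

    def test_cancellation_exercised_in_reverse(self, rng):
        """Constant observed mass with d from the development model forces
        the growth fit to the development Q10."""
        tvar = np.repeat([2.0, 4.0], 15)
        d = development_days(120.0, 3.5, tvar)
        df = pd.DataFrame(
            {"site": "X", "photoperiod": "s", "sex": "f",
             "tvar_c": tvar, "dev_days": d, "mass_g": 0.5}
        )
        fit = fit_growth_q10(df)[0]
        assert fit.q10 == pytest.approx(3.5, rel=1e-3)


class TestNormalizeRelative:
    @staticmethod
    def _fits(q10s):
        return [
            Q10Fit((f"g{i}",), "development", q, 100.0, 0.0, 10, True)
            for i, q in enumerate(q10s)
        ]

    @pytest.mark.parametrize(
        "q10s,expected",
        [([2.0, 4.0], [0.5, 1.0]), ([3.0], [1.0]), ([1.5, 3.0, 2.0], [0.5, 1.0, 2 / 3])],
    )
    def test_examples(self, q10s, expected):
        rel = [r for _, r in normalize_relative(self._fits(q10s))]
        assert rel == pytest.approx(expected, abs=1e-4)

    def test_scale_invariant_and_idempotent(self):
        base = [1.2, 2.5, 0.8, 4.1]
        rel1 = [r for _, r in normalize_relative(self._fits(base))]
        rel2 = [r for _, r in normalize_relative(self._fits([7.3 * q for q in base]))]
        rel3 = [r for _, r in normalize_relative(self._fits(rel1))]
        assert rel1 == pytest.approx(rel2)
        assert rel1 == pytest.approx(rel3)
        assert max(rel1) == 1.0

    def test_empty_list_is_an_error(self):
        with pytest.raises(ValueError):
            normalize_relative([])
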