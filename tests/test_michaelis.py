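"""Velocities, Michaelis-Menten fitting, efficiencies and fold ratios."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from scfkin import (
    MMDataset,
    MichaelisMentenModel,
    NoiseSpec,
    OverConversionWarning,
    ValidationError,
    VelocityPoint,
    catalytic_efficiency,
    fit_michaelis,
    fold_ratio,
    gen_mm_titration,
    reaction_velocity,
)


class TestReactionVelocity:
    def test_zero_conversion_gives_zero_velocity(self):
        assert reaction_velocity(0.0, 1000, 10, 2) == 0.0

    def test_stated_formula(self):
        # fraction x [S] / ([SCF] x t)
        assert reaction_velocity(0.1, 1000, 10, 2) == pytest.approx(5.0)

    def test_over_conversion_warns(self):
        with pytest.warns(OverConversionWarning):
            reaction_velocity(0.5, 1000, 10, 2)
        pt = VelocityPoint(100, 0.5, 1000, 10, 2)
        assert pt.over_converted

    @pytest.mark.parametrize("kwargs", [
        dict(fraction_converted=0.1, substrate_conc=1000, scf_conc=10, time=0),
        dict(fraction_converted=0.1, substrate_conc=1000, scf_conc=0, time=2),
        dict(fraction_converted=1.5, substrate_conc=1000, scf_conc=10, time=2),
    ])
    def test_invalid_inputs_rejected(self, kwargs):
        with pytest.raises(ValidationError):
            reaction_velocity(**kwargs)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(
        f=st.floats(0.001, 0.2), s=st.floats(1, 1e4), e=st.floats(0.1, 1e3),
        t=st.floats(0.1, 100), a=st.floats(0.5, 2.0),
    )
    def test_scaling_linearity(self, f, s, e, t, a):
        """Linear in fraction and substrate; inverse-linear in SCF, time."""
        v = reaction_velocity(f, s, e, t)
        assert reaction_velocity(f, s * a, e, t) == pytest.approx(a * v)
        assert reaction_velocity(f, s, e * a, t) == pytest.approx(v / a)
        assert reaction_velocity(f, s, e, t * a) == pytest.approx(v / a)


class TestMichaelisMentenFit:
    def test_exact_recovery_and_half_saturation(self):
        # elongating-E2 parameters on mono-ubiquitylated Cyclin E
        kcat, Km = 3.7, 317.0
        data = gen_mm_titration(kcat, Km, scf_conc=1.0, substrate_conc=1000.0,
                                top_conc=5000.0, n_dilutions=10, time=0.5)
        res = fit_michaelis(data)
        assert res.Km == pytest.approx(Km, rel=1e-6)
        assert res.kcat == pytest.approx(kcat, rel=1e-6)
        assert res.r_squared == pytest.approx(1.0, abs=1e-9)
        assert res.predict(Km) == pytest.approx(kcat / 2, rel=1e-6)

    def test_noisy_recovery_within_20_percent(self):
        kcat, Km = 3.7, 317.0
        data = gen_mm_titration(
            kcat, Km, scf_conc=1.0, substrate_conc=1000.0, top_conc=5000.0,
            n_dilutions=10, time=0.5,
            noise=NoiseSpec(multiplicative_cv=0.05, replicates=2, seed=3),
        )
        res = fit_michaelis(data)
        assert abs(res.Km - Km) / Km < 0.20
        assert abs(res.kcat - kcat) / kcat < 0.20
        assert res.Km_se > 0 and res.kcat_se > 0
        assert res.r_squared <= 1.0

    def test_two_point_dataset_rejected(self):
        pts = [VelocityPoint(c, 0.05, 1000, 10, 2) for c in (100.0, 200.0)]
        with pytest.raises(ValidationError, match="insufficient titration"):
            MMDataset(pts)

    def test_flat_velocities_rejected(self):
        pts = [VelocityPoint(c, 0.05, 1000, 10, 2)
               for c in (100.0, 200.0, 400.0)]
        with pytest.raises(ValidationError, match="flat"):
            MichaelisMentenModel(MMDataset(pts))

    def test_km_outside_titration_range_warns(self):
        data = gen_mm_titration(2.0, 5000.0, scf_conc=1.0,
                                substrate_conc=1000.0, top_conc=100.0,
                                n_dilutions=5, time=0.5)
        with pytest.warns(UserWarning, match="outside"):
            MichaelisMentenModel(data).fit()

    def test_velocity_monotone_with_kcat_asymptote(self):
        res = fit_michaelis(gen_mm_titration(
            2.0, 300.0, scf_conc=1.0, substrate_conc=1000.0,
            top_conc=4000.0, n_dilutions=8, time=0.5))
        conc = np.geomspace(1, 1e7, 50)
        v = res.predict(conc)
        assert np.all(np.diff(v) > 0)
        assert v[-1] == pytest.approx(res.kcat, rel=1e-3)

    def test_from_dataframe_roundtrip(self):
        data = gen_mm_titration(1.0, 200.0, scf_conc=1.0,
                                substrate_conc=500.0, top_conc=2000.0,
                                n_dilutions=6, time=1.0)
        res = MichaelisMentenModel.from_dataframe(
            data.to_frame(), substrate="test").fit()
        assert res.Km == pytest.approx(200.0, rel=1e-6)


class TestEfficiencyAndFolds:
    def test_elongation_efficiencies_match_reported_comparison(self):
        """kobs/Km for the two chain-elongating E2s on mono-ubiquitylated
        Cyclin E reproduce the published 2-significant-figure values."""
        fast = catalytic_efficiency(40.0, 317.0)
        slow = catalytic_efficiency(1.0, 1300.0)
        assert fast.rounded == pytest.approx(1.3e8)
        assert slow.rounded == pytest.approx(7.7e5)
        assert fast.efficiency == pytest.approx(40.0 / 317.0e-9)

    def test_zero_rate_gives_zero_efficiency(self):
        assert catalytic_efficiency(0.0, 317.0).efficiency == 0.0

    def test_nonpositive_km_rejected(self):
        with pytest.raises(ValidationError):
            catalytic_efficiency(1.0, 0.0)

    @settings(deadline=None, derandomize=True, max_examples=40)
    @given(kobs=st.floats(1e-3, 100), Km=st.floats(1.0, 1e5))
    def test_doubling_km_halves_efficiency(self, kobs, Km):
        a = catalytic_efficiency(kobs, Km).efficiency
        b = catalytic_efficiency(kobs, 2 * Km).efficiency
        assert b == pytest.approx(a / 2)

    @pytest.mark.parametrize("a,b,fold", [
        (5.0, 0.1, 50),   # priming: beta-Catenin vs Cyclin E
        (5.0, 0.2, 25),   # priming: promiscuous E2 vs RBR E3
        (0.5, 0.1, 5),    # priming: RBR E3 vs promiscuous E2 on Cyclin E
        (3.0, 3.0, 1),
    ])
    def test_fold_ratios(self, a, b, fold):
        ratio, rounded = fold_ratio(a, b)
        assert rounded == fold
        assert ratio == pytest.approx(a / b)

    def test_fold_ratio_rejects_nonpositive_denominator(self):
        with pytest.raises(ValidationError):
            fold_ratio(1.0, 0.0)
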