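"""The autoregulation feedback model: equilibria, perturbations, structure."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from splitreg.kinetics import (
    CellState,
    IsoformKinetics,
    PerturbationSpec,
    PoolKinetics,
    SteadyStateError,
    apply_perturbation,
    simulate_trajectory,
    steady_state,
)


class TestSteadyState:
    def test_feedback_free_closed_form(self):
        kins = [IsoformKinetics("x", k_tx=100, k_sp=10, k_deg0=0.5, alpha=0)]
        st_ = steady_state(kins, PoolKinetics())
        assert st_.P[0] == pytest.approx(10.0, rel=1e-12)
        assert st_.M[0] == pytest.approx(200.0, rel=1e-12)

    def test_closed_form_full_state(self):
        kins = [IsoformKinetics("a", k_tx=60, k_sp=3, k_deg0=0.2, alpha=0, k_tl=0.02),
                IsoformKinetics("b", k_tx=90, k_sp=2, k_deg0=0.4, alpha=0, k_tl=0.01)]
        pool = PoolKinetics(k_on=2.0, k_off=0.5, k_pdeg=0.05)
        s = steady_state(kins, pool)
        F_exp = (0.02 * 300 + 0.01 * 225) / 0.05
        assert s.F == pytest.approx(F_exp, rel=1e-10)
        assert s.G == pytest.approx(2.0 / 0.5 * F_exp, rel=1e-10)

    def test_matches_integrate_to_equilibrium_oracle(self, default_kins, default_pool):
        """With feedback on, the root-found equilibrium must agree with an
        independent long-horizon ODE integration started far from it."""
        s = steady_state(default_kins, default_pool)
        start = CellState(s.isoform_ids, s.P * 1.3, s.M * 0.7, s.F * 2.0, s.G * 0.5)
        traj = simulate_trajectory(default_kins, default_pool, None, horizon_h=8000.0,
                                   n_steps=9, initial_state=start, rtol=1e-12, atol=1e-12)
        final = traj.final.as_vector()
        ref = s.as_vector()
        assert np.max(np.abs(final - ref) / (np.abs(ref) + 1e-12)) < 1e-8

    def test_free_pool_independent_of_polymer_exchange(self, default_kins):
        """At equilibrium k_on*F = k_off*G, so F* cannot depend on either rate."""
        s1 = steady_state(default_kins, PoolKinetics(k_on=1.0, k_off=0.1))
        s2 = steady_state(default_kins, PoolKinetics(k_on=1.0, k_off=0.05))
        s3 = steady_state(default_kins, PoolKinetics(k_on=3.0, k_off=0.1))
        assert s2.F == pytest.approx(s1.F, rel=1e-12)
        assert s3.F == pytest.approx(s1.F, rel=1e-12)
        assert s2.G == pytest.approx(2 * s1.G, rel=1e-10)

    def test_no_steady_state_without_protein_decay(self, default_kins):
        with pytest.raises(SteadyStateError, match="k_pdeg"):
            steady_state(default_kins, PoolKinetics(k_pdeg=0.0))

    def test_no_steady_state_without_depolymerization(self, default_kins):
        with pytest.raises(SteadyStateError, match="k_off"):
            steady_state(default_kins, PoolKinetics(k_off=0.0))

    def test_no_polymerization_empties_polymer_pool(self, default_kins):
        s = steady_state(default_kins, PoolKinetics(k_on=0.0))
        assert s.G == 0.0

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(
        k_tx=st.floats(1.0, 500.0),
        k_sp=st.floats(0.1, 20.0),
        k_deg0=st.floats(0.01, 5.0),
        alpha=st.floats(0.0, 20.0),
        k_pdeg=st.floats(1e-3, 1.0),
    )
    def test_equilibrium_is_nonnegative_fixed_point(self, k_tx, k_sp, k_deg0, alpha, k_pdeg):
        kins = [IsoformKinetics("h", k_tx=k_tx, k_sp=k_sp, k_deg0=k_deg0, alpha=alpha)]
        s = steady_state(kins, PoolKinetics(k_pdeg=k_pdeg))
        assert (s.as_vector() >= 0).all()  # residual bound enforced internally


class TestPerturbations:
    def test_none_is_identity(self, default_kins, default_pool):
        kins2, pool2 = apply_perturbation(default_kins, default_pool, PerturbationSpec())
        assert list(kins2) == list(default_kins)
        assert pool2 == default_pool

    def test_colchicine_scales_only_koff(self, default_kins, default_pool):
        kins2, pool2 = apply_perturbation(default_kins, default_pool,
                                          PerturbationSpec("colchicine", 10.0))
        assert pool2.k_off == pytest.approx(10 * default_pool.k_off)
        assert pool2.k_on == default_pool.k_on
        assert list(kins2) == list(default_kins)

    def test_adrenergic_scales_only_targets(self, default_kins, default_pool):
        spec = PerturbationSpec("adrenergic", targets={"Tubb6": 4.0})
        kins2, _ = apply_perturbation(default_kins, default_pool, spec)
        for k_old, k_new in zip(default_kins, kins2):
            factor = 4.0 if k_old.isoform_id == "Tubb6" else 1.0
            assert k_new.k_tx == pytest.approx(factor * k_old.k_tx)

    def test_adrenergic_unknown_target_fails(self, default_kins, default_pool):
        with pytest.raises(ValueError, match="targets"):
            apply_perturbation(default_kins, default_pool,
                               PerturbationSpec("adrenergic", targets={"Nope1": 2.0}))

    @pytest.mark.parametrize("kind,magnitude", [
        ("colchicine", 0.5),   # must depolymerize
        ("taxol", 2.0),        # must stabilize
        ("volcano", 1.0),      # unknown kind
    ])
    def test_invalid_specs_rejected(self, kind, magnitude):
        with pytest.raises(ValueError):
            PerturbationSpec(kind, magnitude)


class TestTrajectories:
    def test_unperturbed_trajectory_is_constant(self, default_kins, default_pool):
        traj = simulate_trajectory(default_kins, default_pool, None, horizon_h=6.0)
        base = traj.at(0).as_vector()
        for i in range(len(traj.t)):
            dev = np.abs(traj.at(i).as_vector() - base) / (np.abs(base) + 1.0)
            assert dev.max() < 1e-7

    def test_colchicine_degrades_mrna_not_premrna(self, default_kins, default_pool):
        base = steady_state(default_kins, default_pool)
        traj = simulate_trajectory(default_kins, default_pool,
                                   PerturbationSpec("colchicine", 10.0), horizon_h=6.0)
        f = traj.final
        assert (f.M < 0.9 * base.M).all()                      # mature mRNA down
        assert np.abs(f.P / base.P - 1).max() < 1e-3           # pre-mRNA untouched
        assert f.F > base.F                                    # free pool released

    def test_taxol_raises_mrna_not_premrna(self, default_kins, default_pool):
        base = steady_state(default_kins, default_pool)
        f = simulate_trajectory(default_kins, default_pool,
                                PerturbationSpec("taxol", 0.1), horizon_h=6.0).final
        assert (f.M > 1.1 * base.M).all()
        assert np.abs(f.P / base.P - 1).max() < 1e-3

    def test_feedback_off_makes_drugs_inert_on_mrna(self, default_pool):
        kins = [IsoformKinetics("x", alpha=0.0), IsoformKinetics("y", k_tx=50, alpha=0.0)]
        base = steady_state(kins, default_pool)
        for kind, mag in (("colchicine", 10.0), ("taxol", 0.1)):
            traj = simulate_trajectory(kins, default_pool, PerturbationSpec(kind, mag), 6.0)
            assert np.abs(traj.M / base.M[:, None] - 1).max() < 1e-6
            assert np.abs(traj.P / base.P[:, None] - 1).max() < 1e-6

    def test_pre_mrna_trajectory_invariant_to_polymer_perturbation(self, default_kins, default_pool):
        """The P equations never reference F or G, so any k_off perturbation
        leaves the pre-mRNA trajectory numerically identical."""
        base = simulate_trajectory(default_kins, default_pool, None, 6.0,
                                   rtol=1e-12, atol=1e-12)
        pert = simulate_trajectory(default_kins, default_pool,
                                   PerturbationSpec("colchicine", 10.0), 6.0,
                                   rtol=1e-12, atol=1e-12)
        assert np.max(np.abs(pert.P - base.P)) < 1e-10

    def test_drug_induced_mrna_change_is_transient(self, default_kins, default_pool):
        """Equilibrium F is independent of k_off, so colchicine's mRNA drop at
        6 h must largely recover on long horizons."""
        base = steady_state(default_kins, default_pool)
        spec = PerturbationSpec("colchicine", 10.0)
        m6 = simulate_trajectory(default_kins, default_pool, spec, 6.0).final.M
        m_long = simulate_trajectory(default_kins, default_pool, spec, 5000.0, n_steps=9).final.M
        dev6 = np.abs(m6 / base.M - 1).min()
        dev_long = np.abs(m_long / base.M - 1).max()
        assert dev6 > 0.2           # a real transient at the readout time
        assert dev_long < 0.01      # essentially full recovery at equilibrium

    def test_delayed_onset(self, default_kins, default_pool):
        spec = PerturbationSpec("colchicine", 10.0, onset_time=3.0)
        traj = simulate_trajectory(default_kins, default_pool, spec, 6.0)
        base = steady_state(default_kins, default_pool)
        i_pre = np.searchsorted(traj.t, 2.9)
        assert np.abs(traj.M[:, i_pre] / base.M - 1).max() < 1e-6
        assert (traj.final.M < 0.95 * base.M).all()


class TestValidation:
    def test_negative_rate_rejected(self):
        with pytest.raises(ValueError):
            IsoformKinetics("x", k_tx=-1)

    def test_zero_splicing_rejected(self):
        with pytest.raises(ValueError, match="k_sp"):
            IsoformKinetics("x", k_sp=0)

    def test_duplicate_isoform_ids_rejected(self, default_pool):
        kins = [IsoformKinetics("x"), IsoformKinetics("x")]
        with pytest.raises(ValueError, match="duplicate"):
            steady_state(kins, default_pool)
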