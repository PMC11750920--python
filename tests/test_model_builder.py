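"""Network construction, asymmetry transform, flows, resistances, Peclet."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import mbwsim as m
from mbwsim import reference
from mbwsim.model_builder import alveolar_peak_flows

f_c_strategy = st.floats(min_value=0.05, max_value=1.95).filter(
    lambda v: abs(v - 1.0) > 1e-3
)
area_strategy = st.integers(min_value=1, max_value=5)


def flows_of(model):
    return np.array([u.Q_hat_in for u in model.units])


class TestSymmetricBuild:
    def test_unit_count_from_layout(self, sym_model):
        # 10 TU + 1 + 2*10 + 4 + 8 + 16 + 32*6 per the {1,10,1,1,1,6} layout
        layout = m.AreaLayout()
        expected = 10 + sum(2**a * ma for a, ma in enumerate(layout.m_au))
        assert expected == 251
        assert len(sym_model) == 251

    def test_total_volume_is_resting_position(self, sym_model):
        assert sym_model.total_volume == pytest.approx(3000, rel=0.01)

    def test_dead_space_volume(self, sym_model):
        assert sym_model.dead_space_volume == pytest.approx(144.6, rel=0.01)

    def test_tu_units_are_one_tenth_of_proximal_tree(self, scaling, sym_model):
        _, scaled = scaling
        v03 = sum(
            2**z * math.pi / 4 * scaled.generation(z).d_cm ** 2 * scaled.generation(z).l_cm
            for z in range(4)
        )
        tu = sym_model.units[0]
        assert tu.V_base == pytest.approx(v03 / 10, rel=1e-12)
        assert tu.A == pytest.approx(tu.V_base / tu.l, rel=1e-12)

    def test_per_element_geometry_matches_published_rows(self, sym_model):
        for row in reference.SU_ROWS:
            zp = row.z - 4 - sum(m.AreaLayout().m_au[: row.area])
            u = sym_model.su_unit(row.area, 0, zp)
            assert u.l == pytest.approx(row.l_cm, rel=0.005)
            assert u.A == pytest.approx(row.A_cm2, rel=0.005)

    def test_axial_positions_match_published_column(self, sym_model):
        for row in reference.SU_ROWS:
            zp = row.z - 4 - sum(m.AreaLayout().m_au[: row.area])
            u = sym_model.su_unit(row.area, 0, zp)
            assert u.x == pytest.approx(row.x_cm, abs=0.05)

    def test_branching_structure(self, sym_model):
        for u in sym_model.units:
            if u.is_tu:
                assert len(u.children) == 1
            elif u.a < 5 and u.z_prime == sym_model.layout.m_au[u.a] - 1:
                assert len(u.children) == 2  # area boundary bifurcation
            elif u.a == 5 and u.z_prime == 5:
                assert u.children == []  # terminal
            else:
                assert len(u.children) == 1

    def test_each_su_unit_lumps_2_pow_z_minus_a_airways(self, scaling, sym_model):
        _, scaled = scaling
        u = sym_model.su_unit(5, 3, 2)  # z = 20
        gen = scaled.generation(20)
        assert u.V_airway == pytest.approx(
            2 ** (20 - 5) * math.pi / 4 * gen.d_cm**2 * gen.l_cm, rel=1e-12
        )

    def test_missing_generation_rejected(self, raw_table):
        import pandas as pd

        df = raw_table.df
        df = df[df["z"] != 12]
        with pytest.raises(ValueError, match="0..23"):
            m.build_symmetric(m.WeibelTable(df))


class TestAsymmetry:
    def test_identity_factor_leaves_model_unchanged(self, sym_model):
        asym = m.apply_asymmetry(sym_model, m.AsymmetrySpec(3, 1.0 - 1e-15))
        np.testing.assert_allclose(asym.volumes, sym_model.volumes, rtol=1e-12)
        np.testing.assert_allclose(asym.lengths, sym_model.lengths, rtol=1e-12)

    def test_volume_ratio_seven_for_175_at_area4(self, sym_model):
        asym = m.apply_asymmetry(sym_model, m.AsymmetrySpec(4, 1.75))
        part = m.partition_lung_units(asym, 4)
        v1 = asym.volumes[part.labels == 1].sum()
        v2 = asym.volumes[part.labels == 2].sum()
        assert v1 / v2 == pytest.approx(1.75 / 0.25, rel=1e-9)

    @given(area_strategy, f_c_strategy)
    @settings(deadline=None, max_examples=15)
    def test_total_volume_conserved(self, sym_model, area, f_c):
        asym = m.apply_asymmetry(sym_model, m.AsymmetrySpec(area, f_c))
        # brute-force summation oracle over the unit list
        total = sum(u.V_base for u in asym.units)
        assert total == pytest.approx(sym_model.total_volume, rel=1e-12)

    @given(area_strategy, f_c_strategy)
    @settings(deadline=None, max_examples=10)
    def test_sibling_factors_sum_to_two(self, area, f_c):
        spec = m.AsymmetrySpec(area, f_c)
        for e in range(0, 2**area, 2):
            assert spec.factor(area, e) + spec.factor(area, e + 1) == pytest.approx(2.0)

    def test_geometry_scales_with_cube_root_of_factor(self, sym_model):
        spec = m.AsymmetrySpec(2, 1.5)
        asym = m.apply_asymmetry(sym_model, spec)
        for (a, e, zp) in [(2, 0, 0), (3, 1, 0), (5, 7, 3)]:
            f = spec.f_tot(a, e)
            u0 = sym_model.su_unit(a, e, zp)
            u1 = asym.su_unit(a, e, zp)
            assert u1.l == pytest.approx(f ** (1 / 3) * u0.l, rel=1e-12)
            assert u1.A == pytest.approx(f ** (2 / 3) * u0.A, rel=1e-12)
            assert u1.m_alv == pytest.approx(f * u0.m_alv, rel=1e-12)

    def test_inherited_factor_product(self):
        spec = m.AsymmetrySpec(2, 1.75)
        # area-2 factors inherit unchanged into areas 3..5
        assert spec.f_tot(2, 0) == pytest.approx(1.75)
        assert spec.f_tot(2, 1) == pytest.approx(0.25)
        assert spec.f_tot(5, 0) == pytest.approx(1.75)  # descendant of (2,0)
        assert spec.f_tot(5, 8) == pytest.approx(0.25)  # descendant of (2,1)
        assert spec.f_tot(1, 0) == 1.0  # above the asymmetry

    def test_degenerate_factor_rejected(self):
        with pytest.raises(ValueError):
            m.AsymmetrySpec(3, 2.0)
        with pytest.raises(ValueError):
            m.AsymmetrySpec(0, 1.5)


class TestFlows:
    def test_entrance_flow_equals_tracheal_flow(self, sym_model):
        q = flows_of(sym_model)
        assert q[0] == pytest.approx(250.0)
        assert q[sym_model.su_unit(0, 0, 0).index] == pytest.approx(250.0)

    def test_flow_halves_at_each_conducting_bifurcation(self, sym_model):
        expected = {1: 125.0, 2: 62.5, 3: 31.25, 4: 15.625}
        for a, val in expected.items():
            u = sym_model.su_unit(a, 0, 0)
            assert u.Q_hat_in == pytest.approx(val, rel=1e-9)

    def test_flow_continuity_at_every_unit(self, sym_model):
        q = flows_of(sym_model)
        q_alv = alveolar_peak_flows(sym_model, q)
        for u in sym_model.units:
            children = sum(q[c] for c in u.children)
            assert q[u.index] == pytest.approx(children + q_alv[u.index], rel=1e-9)

    def test_asymmetric_flows_scale_with_f_tot(self, sym_model):
        spec = m.AsymmetrySpec(3, 1.25)
        asym = m.default_model(asymmetry=spec)
        q_sym = flows_of(sym_model)
        q_asym = flows_of(asym)
        for u_s, u_a in zip(sym_model.units, asym.units):
            f = 1.0 if u_a.is_tu else spec.f_tot(u_a.a, u_a.e) if u_a.a >= 3 else 1.0
            assert q_asym[u_a.index] == pytest.approx(f * q_sym[u_s.index], rel=1e-9)

    def test_asymmetric_flows_match_subtree_resummation(self, sym_model):
        # brute-force re-summation of alveolar flows over each subtree
        asym = m.default_model(asymmetry=m.AsymmetrySpec(2, 1.75))
        q = flows_of(asym)
        q_alv = alveolar_peak_flows(asym, q)
        subtree = np.zeros(len(asym))
        for u in reversed(asym.units):
            subtree[u.index] = q_alv[u.index] + sum(subtree[c] for c in u.children)
        np.testing.assert_allclose(q, subtree, rtol=1e-9)


class TestResistancesAndPeclet:
    def test_published_anchor_rows(self, sym_model):
        q = flows_of(sym_model)
        r_d = m.diffusive_resistances(sym_model)
        pe = m.peclet(sym_model, q)
        i15 = sym_model.su_unit(2, 0, 0).index
        i4 = sym_model.su_unit(0, 0, 0).index
        assert r_d[i15] == pytest.approx(1.41e-2, rel=0.01)
        assert pe[i15] == pytest.approx(0.880, rel=0.01)
        assert r_d[i4] == pytest.approx(1.24, rel=0.01)
        assert pe[i4] == pytest.approx(309.074, rel=0.01)

    def test_tu_internal_link_direct_arithmetic(self, sym_model):
        r_d = m.diffusive_resistances(sym_model)
        tu = sym_model.units[1]
        assert r_d[1] == pytest.approx(tu.l / (0.6 * tu.A), rel=1e-12)
        assert r_d[1] == pytest.approx(1.33, rel=0.01)

    def test_inlet_link_is_blocking(self, sym_model):
        r_d = m.diffusive_resistances(sym_model)
        assert r_d[0] == 1e100

    def test_full_reference_table_regression(self, sym_model):
        report = m.reference_report(sym_model)
        assert len(report) == 21
        assert report["peclet_ok"].all()
        assert report["R_D_ok"].all()

    def test_peclet_equals_flow_times_resistance(self, sym_model):
        # Pe and R_D share the same link length and cross-section
        q = flows_of(sym_model)
        r_d = m.diffusive_resistances(sym_model)
        pe = m.peclet(sym_model, q)
        np.testing.assert_allclose(pe[1:], (q * r_d)[1:], rtol=1e-12)

    def test_zero_flow_gives_zero_peclet(self, sym_model):
        pe = m.peclet(sym_model, np.zeros(len(sym_model)))
        assert (pe == 0).all()

    def test_nonpositive_diffusivity_rejected(self, sym_model):
        with pytest.raises(ValueError):
            m.diffusive_resistances(sym_model, 0.0)


class TestTransition:
    def test_he_n2_transition_at_generation_15(self, sym_model):
        pe = m.peclet(sym_model, flows_of(sym_model))
        assert m.transition_generation(sym_model, pe) == 15
        # crossing sits between the printed z=14 and z=15 entrance values
        i14 = sym_model.su_unit(1, 0, 9).index
        assert pe[i14] > 1.0

    def test_vanishing_diffusion_has_no_transition(self, sym_model):
        pe = m.peclet(sym_model, flows_of(sym_model), D=1e-12)
        assert m.transition_generation(sym_model, pe) is None

    def test_stronger_flow_pushes_transition_deeper(self, sym_model):
        q = flows_of(sym_model)
        base = m.transition_generation(sym_model, m.peclet(sym_model, q))
        deeper = m.transition_generation(sym_model, m.peclet(sym_model, 10 * q))
        assert deeper >= base + 1


class TestTimeConstants:
    def test_symmetric_factorisation_identity(self, sym_model):
        q = flows_of(sym_model)
        tau_d, tau_c = m.time_constants(sym_model, q)
        asym = m.default_model(asymmetry=m.AsymmetrySpec(2, 1.0 - 1e-15))
        tau_d2, tau_c2 = m.time_constants(asym, flows_of(asym))
        np.testing.assert_allclose(tau_d2, tau_d, rtol=1e-9)
        np.testing.assert_allclose(tau_c2, tau_c, rtol=1e-9)

    def test_convective_constants_invariant_under_asymmetry(self, sym_model):
        q = flows_of(sym_model)
        _, tau_c = m.time_constants(sym_model, q)
        asym = m.default_model(asymmetry=m.AsymmetrySpec(4, 1.75))
        _, tau_c2 = m.time_constants(asym, flows_of(asym))
        np.testing.assert_allclose(tau_c2, tau_c, rtol=1e-9)

    def test_diffusive_constants_scale_inside_uniform_subtree(self, sym_model):
        # away from the factor boundary both link ends share f_tot, so
        # tau_D' / tau_D = f_tot**(2/3)
        spec = m.AsymmetrySpec(2, 1.75)
        asym = m.default_model(asymmetry=spec)
        tau_d, _ = m.time_constants(sym_model, flows_of(sym_model))
        tau_d2, _ = m.time_constants(asym, flows_of(asym))
        u = asym.su_unit(5, 0, 3)  # deep inside the even subtree
        ratio = tau_d2[u.index] / tau_d[u.index]
        assert ratio == pytest.approx(1.75 ** (2 / 3), rel=1e-9)


class TestPartition:
    def test_area4_shared_region_is_dead_space(self, sym_model):
        part = m.partition_lung_units(sym_model, 4)
        assert part.V_LU0 == pytest.approx(sym_model.dead_space_volume, rel=1e-12)
        assert part.dt_LU0 == pytest.approx(0.578, abs=0.002)

    def test_area1_shared_region_is_tu_plus_entrance(self, sym_model):
        part = m.partition_lung_units(sym_model, 1)
        assert (part.labels == 0).sum() == 11  # 10 TU + the single area-0 AU

    @pytest.mark.parametrize("area", [1, 2, 3, 4, 5])
    def test_partition_covers_and_balances(self, sym_model, area):
        part = m.partition_lung_units(sym_model, area)
        counts = np.bincount(part.labels, minlength=3)
        assert counts.sum() == 251
        assert counts[1] == counts[2]  # sibling subtrees are congruent

    def test_json_export(self, sym_model, tmp_path):
        import json

        p = tmp_path / "model.json"
        sym_model.to_json(p)
        data = json.loads(p.read_text())
        assert data["meta"]["n_units"] == 251
        assert len(data["units"]) == 251
        assert data["units"][10]["label"] == "SU-(0,0,0)"
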