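"""Spring-network solver tests against closed forms and the homogenized
oracle."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from nanobeam.designs import NanobeamDesign, build_two_helix, preset
from nanobeam.errors import SingularSystemError, ValidationError
from nanobeam.mechanics import (DS, HJ, NICK, MaterialParams, SpringSystem,
                                apparent_stiffness, assemble, bundle_sweep,
                                force_extension, homogenized_stiffness,
                                solve_tension)


def single_helix(bp=3600):
    return NanobeamDesign(n_helices=1, bp_per_helix=bp)


class TestAssemble:
    def test_c170l_element_census(self, material):
        sys_ = assemble(preset("C170L"), material)
        for h in range(2):
            labels = sys_.labels[h * 3600:(h + 1) * 3600]
            counts = {lab: int(np.sum(labels == lab)) for lab in (DS, HJ, NICK)}
            assert counts == {DS: 2750, HJ: 850, NICK: 0}
        assert sys_.stiffness.size == 2 * 3600

    def test_identity_degradation_uniform_springs(self):
        mat = MaterialParams(alpha=1.0, beta=1.0)
        sys_ = assemble(preset("C170N"), mat)
        assert np.allclose(sys_.stiffness, 1100 / 0.34)
        assert sys_.stiffness[0] == pytest.approx(3235.294, abs=1e-3)

    def test_degraded_spring_values(self, material):
        mat = material.with_factors(alpha=0.02, beta=0.005)
        sys_ = assemble(preset("C170N"), mat)
        k = mat.k_intact
        assert set(np.round(np.unique(sys_.stiffness), 6)) == {
            round(k, 6), round(0.02 * k, 6), round(0.005 * k, 6)}

    def test_single_helix_has_no_ties(self, material):
        sys_ = assemble(single_helix(), material)
        assert sys_.rigid_ties == []

    def test_overlapping_blocks_rejected(self, material):
        bad = NanobeamDesign(n_helices=2, bp_per_helix=100,
                             junction_sites=(((0, 1), 50),),
                             nick_sites=((0, 51),))
        with pytest.raises(ValidationError, match="5[01]"):
            assemble(bad, material)

    def test_block_outside_helix_rejected(self, material):
        bad = NanobeamDesign(n_helices=2, bp_per_helix=100,
                             junction_sites=(((0, 1), 1),))
        with pytest.raises(ValidationError):
            assemble(bad, material)


class TestSolveTension:
    def test_single_intact_helix_closed_form(self, material):
        # series springs: delta = F L0 / EA
        sys_ = assemble(single_helix(3600), material)
        assert solve_tension(sys_, 10.0) == pytest.approx(
            10 * 1224 / 1100, rel=1e-9)

    def test_parallel_doubling(self, material):
        d = NanobeamDesign(n_helices=2, bp_per_helix=3600)
        sys_ = assemble(d, material)
        assert solve_tension(sys_, 10.0) == pytest.approx(
            0.5 * 10 * 1224 / 1100, rel=1e-9)

    @settings(max_examples=20, deadline=None, derandomize=True)
    @given(f=st.floats(0.1, 200.0))
    def test_linearity(self, f):
        mat = MaterialParams(alpha=0.05, beta=0.01)
        sys_ = assemble(build_two_helix(420, 21), mat)
        d1 = solve_tension(sys_, f)
        d2 = solve_tension(sys_, 2 * f)
        assert d2 == pytest.approx(2 * d1, rel=1e-9)

    def test_disconnected_load_path(self):
        # one helix of 2 bp with the middle spring removed by hand
        sys_ = SpringSystem(
            n_helices=1, bp_per_helix=2,
            node_a=np.array([0]), node_b=np.array([1]),
            stiffness=np.array([100.0]), labels=np.array([DS], dtype=object),
            rigid_ties=[], fixed_plate=frozenset({0}),
            loaded_plate=frozenset({2}))
        with pytest.raises(SingularSystemError):
            solve_tension(sys_, 1.0)


class TestApparentStiffness:
    def test_single_helix_equals_ea_for_any_length(self, material):
        for bp in (100, 3600, 7000):
            res = apparent_stiffness(single_helix(bp), material)
            assert res.apparent_stiffness == pytest.approx(1100, rel=1e-9)
            assert res.apparent_stiffness == pytest.approx(
                res.slope * res.L0, rel=1e-12)

    def test_n_intact_helices_parallel(self, material):
        for n in (2, 5):
            d = NanobeamDesign(n_helices=n, bp_per_helix=1000)
            res = apparent_stiffness(d, material)
            assert res.apparent_stiffness == pytest.approx(n * 1100, rel=1e-9)

    def test_c170l_matches_homogenized_with_spec_alpha(self):
        mat = MaterialParams(alpha=0.0209)
        res = apparent_stiffness(preset("C170L"), mat)
        assert res.apparent_stiffness == pytest.approx(181.0, rel=0.02)


class TestHomogenizedOracle:
    def test_no_degradation(self):
        mat = MaterialParams(alpha=0.5, beta=0.5)
        for n in (1, 2, 6):
            assert homogenized_stiffness(n, 0, 0, mat) == pytest.approx(
                n * 1100, rel=1e-12)

    def test_frozen_closed_form_values(self):
        # C_rep = 16 + 5/0.0209 = 255.234 -> K = 46200 / C_rep
        k = homogenized_stiffness(2, 1.0, 0.0, MaterialParams(alpha=0.0209))
        assert k == pytest.approx(181.0, abs=0.1)
        k2 = homogenized_stiffness(
            2, 0.5, 0.5, MaterialParams(alpha=0.0209, beta=0.00576))
        assert k2 == pytest.approx(205.9, abs=0.1)

    def test_precondition(self):
        with pytest.raises(ValidationError):
            homogenized_stiffness(2, 4.0, 2.0, MaterialParams())  # 22 bp > 21

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(alpha=st.floats(0.005, 1.0), beta=st.floats(0.005, 1.0),
           j=st.floats(0.0, 2.0), nu=st.floats(0.0, 2.0))
    def test_monotone_in_factors_and_densities(self, alpha, beta, j, nu):
        base = homogenized_stiffness(
            2, j, nu, MaterialParams(alpha=alpha, beta=beta))
        up_a = homogenized_stiffness(
            2, j, nu, MaterialParams(alpha=min(1.0, alpha * 1.1), beta=beta))
        denser = homogenized_stiffness(
            2, j + 0.1, nu, MaterialParams(alpha=alpha, beta=beta))
        assert up_a >= base - 1e-9
        if alpha < 0.9:
            assert denser < base + 1e-9

    def test_network_stiffness_increases_with_alpha(self, material):
        design = build_two_helix(840, 21, ligated=True)
        ks = [apparent_stiffness(design, material.with_factors(alpha=a)
                                 ).apparent_stiffness
              for a in (0.01, 0.05, 0.2, 1.0)]
        assert all(b > a for a, b in zip(ks, ks[1:]))


class TestOracleEquivalence:
    @pytest.mark.parametrize("spacing", [14, 21, 42])
    @pytest.mark.parametrize("alpha", [0.01, 0.1, 1.0])
    def test_two_helix_network_vs_homogenized(self, spacing, alpha):
        mat = MaterialParams(alpha=alpha, beta=0.006)
        j = 21.0 / spacing
        for ligated, nu in ((True, 0.0), (False, j)):
            design = build_two_helix(4210, spacing, ligated=ligated)
            net = apparent_stiffness(design, mat).apparent_stiffness
            hom = homogenized_stiffness(2, j, nu, mat)
            assert abs(net - hom) / hom < 0.02

    def test_exact_multiple_tighter_bound(self):
        mat = MaterialParams(alpha=0.02, beta=0.006)
        for spacing in (21, 42):
            design = build_two_helix(210 * spacing, spacing, ligated=False)
            net = apparent_stiffness(design, mat).apparent_stiffness
            hom = homogenized_stiffness(2, 21.0 / spacing, 21.0 / spacing, mat)
            assert abs(net - hom) / hom < 0.005


class TestOrderingAndCurves:
    def test_published_stiffness_ordering(self, calib):
        ks = {n: apparent_stiffness(preset(n), calib.material
                                    ).apparent_stiffness
              for n in ("C85L", "C85N", "C170L", "C170N")}
        assert ks["C85L"] > ks["C85N"] > ks["C170L"] > ks["C170N"]

    def test_ligated_at_least_as_stiff_as_nicked(self, calib):
        for lig, nick in (("C85L", "C85N"), ("C170L", "C170N")):
            k_l = apparent_stiffness(preset(lig), calib.material)
            k_n = apparent_stiffness(preset(nick), calib.material)
            assert k_l.apparent_stiffness >= k_n.apparent_stiffness

    def test_force_extension_linear_through_origin(self, material):
        curve = force_extension(preset("C85L"),
                                material.with_factors(alpha=0.02, beta=0.01),
                                np.arange(5.0, 70.0, 5.0))
        slope = curve.forces / curve.extensions
        assert np.allclose(slope, slope[0], rtol=1e-9)


class TestBundleSweep:
    def test_single_intact_helix_normalized_unity(self, material):
        table = bundle_sweep([1], ["pair"], material, 0.0, 0.0)
        assert table["normalized"].iloc[0] == pytest.approx(1.0, rel=1e-9)

    def test_strictly_increasing_in_helix_count(self, calib):
        table = bundle_sweep([2, 6, 10], ["honeycomb"], calib.material,
                             1.0, 0.5)
        ks = table["stiffness_pN"].to_numpy()
        assert np.all(np.diff(ks) > 0)

    def test_equal_densities_give_proportional_stiffness(self, calib):
        """6- vs 10-helix rings with identical per-helix densities and length
        have identical per-helix modulus: K6/K10 = 0.6."""
        table = bundle_sweep([6, 10], ["honeycomb"], calib.material,
                             2.0, 0.5, length_nm=428.0)
        k6, k10 = table["stiffness_pN"]
        assert k6 / k10 == pytest.approx(0.6, abs=0.01)
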