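import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from polynuc.nucleus import GeometryError
from polynuc.params import ARM_IDS, arrangement_ids, default_params
from polynuc.saw import (
    chirality_sign,
    chirality_signs_along,
    grow_nucleus,
    grow_single_chain,
    place_initial_beads,
    sample_arrangement,
    step_is_valid,
    validate_nucleus,
)

finite = st.floats(-50, 50, allow_nan=False)
point = st.tuples(finite, finite, finite)


class TestChiralitySign:
    def test_collinear_points_are_degenerate(self):
        p = [(0, 0, 0), (1, 0, 0), (2, 0, 0), (3, 0, 0)]
        assert chirality_sign(*p) == 0

    def test_coplanar_zigzag_is_degenerate(self):
        p = [(0, 0, 0), (1, 1, 0), (2, 0, 0), (3, 1, 0)]
        assert chirality_sign(*p) == 0

    @pytest.mark.parametrize("handedness", [+1, -1])
    def test_helix_sign_matches_handedness(self, handedness):
        # four consecutive points on a helix whose handedness is the sign
        # of its pitch: the bond-vector triple product has the same sign
        t = np.arange(4) * 1.2
        pts = np.stack([np.cos(t), np.sin(t) * handedness, 0.4 * t], axis=1)
        assert chirality_sign(*pts) == handedness

    @given(p0=point, p1=point, p2=point, p3=point)
    @settings(max_examples=200, deadline=None)
    def test_mirror_reflection_negates_sign(self, p0, p1, p2, p3):
        sign = chirality_sign(p0, p1, p2, p3)
        mirror = [(-x, y, z) for x, y, z in (p0, p1, p2, p3)]
        assert chirality_sign(*mirror) == -sign

    def test_signs_along_matches_scalar_windows(self):
        rng = np.random.default_rng(0)
        chain = rng.normal(size=(10, 3))
        signs = chirality_signs_along(chain)
        expected = [chirality_sign(*chain[i : i + 4]) for i in range(7)]
        assert signs.tolist() == expected


class TestSampleArrangement:
    def test_single_nonzero_weight_is_deterministic(self):
        ids = arrangement_ids()
        weights = {a: 0.0 for a in ids}
        weights[ids[3]] = 2.5
        rng = np.random.default_rng(1)
        assert all(sample_arrangement(weights, rng) == ids[3] for _ in range(20))

    def test_uniform_weights_within_binomial_noise(self):
        ids = arrangement_ids()
        rng = np.random.default_rng(2)
        n = 10_000
        draws = [sample_arrangement({a: 1.0 for a in ids}, rng) for _ in range(n)]
        p = 1.0 / len(ids)
        sd = np.sqrt(n * p * (1 - p))
        for a in ids:
            assert abs(draws.count(a) - n * p) < 3 * sd

    def test_two_to_one_weights_reproduce_ratio(self):
        # binomial oracle: with weights (2, 1) the count of the first
        # arrangement is Binomial(n, 2/3)
        ids = arrangement_ids()
        weights = {a: 0.0 for a in ids}
        weights[ids[0]] = 2.0
        weights[ids[1]] = 1.0
        rng = np.random.default_rng(3)
        n = 6000
        hits = sum(sample_arrangement(weights, rng) == ids[0] for _ in range(n))
        sd = np.sqrt(n * (2 / 3) * (1 / 3))
        assert abs(hits - n * 2 / 3) < 3 * sd

    def test_all_zero_weights_rejected(self):
        with pytest.raises(ValueError):
            sample_arrangement({a: 0.0 for a in arrangement_ids()}, np.random.default_rng(0))


class TestPlaceInitialBeads:
    def test_beads_touch_envelope_and_chromocenter(self, params):
        rng = np.random.default_rng(7)
        centers = place_initial_beads(arrangement_ids()[0], params, rng)
        radii = np.linalg.norm(centers, axis=1)
        assert np.allclose(radii, params.nucleus_radius - params.bead_radius, atol=1e-6)
        cc = np.asarray(params.chromocenter_position)
        d = np.linalg.norm(centers - cc, axis=1)
        assert np.allclose(d, params.chromocenter_radius + params.bead_radius, atol=1e-6)

    def test_beads_do_not_overlap(self, params):
        rng = np.random.default_rng(8)
        for _ in range(50):
            centers = place_initial_beads(arrangement_ids()[5], params, rng)
            dmat = np.linalg.norm(centers[:, None] - centers[None, :], axis=-1)
            np.fill_diagonal(dmat, np.inf)
            assert dmat.min() >= 2 * params.bead_radius - 1e-7

    def test_tiny_chromocenter_contact_circle_infeasible(self):
        # the circle of centers touching both chromocenter and NE shrinks
        # with the chromocenter until five touching beads cannot fit on it
        tiny = default_params(chromocenter_radius=0.05)
        with pytest.raises(GeometryError):
            place_initial_beads(arrangement_ids()[0], tiny, np.random.default_rng(0))


class TestStepIsValid:
    def test_confinement_violation(self, small_params):
        chains = {a: np.array([[0.0, 0.0, 0.0]]) for a in ARM_IDS}
        outside = [small_params.nucleus_radius, 0.0, 0.0]
        assert not step_is_valid(chains, "X", outside, small_params)

    def test_coincident_with_existing_bead(self, small_params):
        chains = {a: np.array([[0.0, 0.0, float(i)]]) for i, a in enumerate(ARM_IDS)}
        assert not step_is_valid(chains, "X", [0.0, 0.0, 1.0], small_params)

    def test_open_space_near_pole_is_valid(self, params):
        rng = np.random.default_rng(11)
        init = place_initial_beads(arrangement_ids()[0], params, rng)
        chains = {a: init[i : i + 1].copy() for i, a in enumerate(ARM_IDS)}
        tip = chains["X"][-1]
        # step inward, toward the nucleus center
        candidate = tip - params.bond_length * tip / np.linalg.norm(tip)
        assert step_is_valid(chains, "X", candidate, params)

    def test_growth_engine_agrees_with_reference_checker(self, small_nucleus, small_params):
        # every accepted bead of a grown nucleus must pass the pure-numpy
        # validity check applied to the partial chains that preceded it
        arm = "3R"
        chain = small_nucleus.chains[arm]
        partial = {a: small_nucleus.chains[a][: len(chain) - 1].copy() for a in ARM_IDS}
        partial[arm] = chain[:-1].copy()
        assert step_is_valid(partial, arm, chain[-1], small_params)


class TestGrowNucleus:
    def test_completes_with_all_invariants(self, nucleus, params):
        assert nucleus.total_beads == 248
        assert validate_nucleus(nucleus, params) == []

    def test_same_seed_reproduces_nucleus(self, params):
        a = grow_nucleus(params, np.random.default_rng(99))
        b = grow_nucleus(params, np.random.default_rng(99))
        assert a.arrangement_id == b.arrangement_id
        for arm in ARM_IDS:
            assert np.array_equal(a.chains[arm], b.chains[arm])

    def test_bond_lengths_exact(self, nucleus, params):
        for arm in ARM_IDS:
            lengths = np.linalg.norm(np.diff(nucleus.chains[arm], axis=0), axis=1)
            assert np.allclose(lengths, params.bond_length, rtol=1e-9)

    def test_independent_mode_also_validates(self, small_params):
        p = small_params.with_updates(growth_mode="independent")
        nuc = grow_nucleus(p, np.random.default_rng(5))
        assert validate_nucleus(nuc, p) == []

    def test_joint_mode_validates_at_low_density(self):
        # joint all-or-none acceptance is only tractable well below the
        # default packing density
        p = default_params(
            growth_mode="joint",
            nucleus_radius=12.0,
            arm_bead_counts={"X": 5, "2L": 5, "2R": 5, "3L": 5, "3R": 5},
        )
        nuc = grow_nucleus(p, np.random.default_rng(5))
        assert validate_nucleus(nuc, p) == []


class TestSingleChain:
    def test_one_bead_chain(self, params):
        chain = grow_single_chain(1, params, np.random.default_rng(0))
        assert chain.shape == (1, 3)

    def test_two_bead_end_to_end_is_exactly_one_bond(self, params):
        chain = grow_single_chain(2, params, np.random.default_rng(0))
        assert np.linalg.norm(chain[1] - chain[0]) == pytest.approx(params.bond_length)

    def test_free_chain_passes_shared_clearance_validator(self, params):
        from scipy.spatial.distance import pdist, squareform

        chain = grow_single_chain(60, params, np.random.default_rng(4))
        d = squareform(pdist(chain))
        n = len(chain)
        mask = np.abs(np.subtract.outer(np.arange(n), np.arange(n))) > 1
        assert d[mask].min() >= 2 * params.bead_radius - 1e-7

    def test_confined_chain_stays_inside(self, params):
        chain = grow_single_chain(
            40, params, np.random.default_rng(6), confine_radius=params.nucleus_radius
        )
        assert np.linalg.norm(chain, axis=1).max() <= params.nucleus_radius - params.bead_radius + 1e-7
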