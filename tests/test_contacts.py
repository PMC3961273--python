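import numpy as np
import pytest

from polynuc.contacts import (
    ContactProfile,
    TracingStats,
    bead_ne_contact,
    call_peaks,
    contact_profile,
    fraction_above_threshold,
    locus_locus_contacts,
    ne_contact_mask,
)
from polynuc.nucleus import NucleusModel
from polynuc.params import ARM_IDS, default_params
from polynuc.traceio import synth_profiles


def _stats(upper, lower):
    return TracingStats(
        arm_ids=np.array([], dtype=object),
        bead_index=np.array([], dtype=int),
        mean=np.array([]),
        sd=np.array([]),
        upper_threshold=upper,
        lower_threshold=lower,
        n_replicates=2,
    )


class TestBeadNeContact:
    def test_touching_bead_is_in_contact(self, params):
        c = [0.0, 0.0, params.nucleus_radius - params.bead_radius]
        assert bead_ne_contact(c, params)

    def test_center_of_nucleus_is_not(self, params):
        assert not bead_ne_contact([0.0, 0.0, 0.0], params)

    def test_gap_exactly_at_cutoff_is_contact(self, params):
        r = params.nucleus_radius - params.bead_radius - params.ne_contact_distance
        assert bead_ne_contact([r, 0.0, 0.0], params)

    def test_gap_just_beyond_cutoff_is_not(self, params):
        r = params.nucleus_radius - params.bead_radius - params.ne_contact_distance - 1e-6
        assert not bead_ne_contact([r, 0.0, 0.0], params)

    def test_center_outside_allowed_region_raises(self, params):
        with pytest.raises(ValueError):
            bead_ne_contact([params.nucleus_radius, 0.0, 0.0], params)

    def test_mask_agrees_with_scalar(self, nucleus, params):
        beads = nucleus.all_beads()
        mask = ne_contact_mask(beads, params)
        scalar = np.array([bead_ne_contact(b, params) for b in beads])
        assert np.array_equal(mask, scalar)


class TestLocusLocusContacts:
    def test_toy_nucleus_agrees_with_brute_force(self, small_nucleus, small_params):
        pairs = set(map(frozenset, locus_locus_contacts(small_nucleus, small_params)))
        cutoff = 2 * small_params.bead_radius + small_params.locus_contact_distance
        expected = set()
        flat = [
            (a, i, small_nucleus.chains[a][i])
            for a in ARM_IDS
            for i in range(len(small_nucleus.chains[a]))
        ]
        for x in range(len(flat)):
            for y in range(x + 1, len(flat)):
                (aa, ia, pa), (ab, ib, pb) = flat[x], flat[y]
                if aa == ab and abs(ia - ib) == 1:
                    continue
                if np.linalg.norm(pa - pb) <= cutoff + 1e-12:
                    expected.add(frozenset([(aa, ia), (ab, ib)]))
        assert pairs == expected

    def test_touching_beads_count(self, small_params):
        chains = {a: np.array([[0.0, 0.0, float(3 * i)]]) for i, a in enumerate(ARM_IDS)}
        chains["2L"] = np.array([[2.0 * small_params.bead_radius, 0.0, 0.0]])
        nuc = NucleusModel("d", np.zeros(3), "", chains, 0)
        pairs = locus_locus_contacts(nuc, small_params)
        assert frozenset([("X", 0), ("2L", 0)]) in set(map(frozenset, pairs))

    def test_far_beads_give_empty_list(self, small_params):
        chains = {a: np.array([[0.0, 0.0, 7.0 * i]]) for i, a in enumerate(ARM_IDS)}
        nuc = NucleusModel("d", np.zeros(3), "", chains, 0)
        assert locus_locus_contacts(nuc, small_params) == []


class TestContactProfile:
    def _nuclei_with_fixed_contacts(self, params, pattern):
        """Nuclei whose X-arm beads are at controlled radii: True = touching
        the NE, False = at the center region."""
        out = []
        rc = params.nucleus_radius - params.bead_radius
        for row in pattern:
            chains = {}
            for a in ARM_IDS:
                n = 4
                pts = np.zeros((n, 3))
                for i in range(n):
                    pts[i] = [0.0, 0.0, rc if (a == "X" and row[i]) else 1.0 + 0.1 * i]
                chains[a] = pts
            out.append(NucleusModel("d", np.zeros(3), "", chains, 0))
        return out

    def test_always_and_never_contacting_beads(self, params):
        pattern = [[True, False, True, False]] * 3
        nuclei = self._nuclei_with_fixed_contacts(params, pattern)
        prof = contact_profile(nuclei, "X", params)
        assert prof.frequencies.tolist() == [1.0, 0.0, 1.0, 0.0]

    def test_frequencies_are_multiples_of_one_over_n(self, params):
        pattern = [
            [True, False, False, True],
            [True, True, False, False],
            [False, True, False, True],
        ]
        nuclei = self._nuclei_with_fixed_contacts(params, pattern)
        prof = contact_profile(nuclei, "X", params)
        assert np.allclose(prof.frequencies * 3, np.round(prof.frequencies * 3))
        assert prof.n_nuclei == 3

    def test_empty_list_raises(self, params):
        with pytest.raises(ValueError):
            contact_profile([], "X", params)


class TestFractionAboveThreshold:
    def test_threshold_one_gives_zero(self):
        prof = ContactProfile("X", np.linspace(0, 1, 11), 10, np.arange(11) * 3.1)
        assert fraction_above_threshold(_stats(1.0, 0.0), [prof]) == 0.0

    def test_gaussian_frequencies_match_normal_tail(self):
        # iid Gaussian "frequencies" against a mean + 2 sigma cut: the
        # exceedance probability is the upper normal tail, 0.02275
        rng = np.random.default_rng(42)
        values = rng.normal(0.5, 0.05, size=200_000)
        prof = ContactProfile("X", values, 1, np.arange(len(values)) * 3.1)
        frac = fraction_above_threshold(_stats(0.6, 0.0), [prof], exclude_first_bead=False)
        assert frac == pytest.approx(0.02275, abs=0.002)


class TestCallPeaks:
    def _profile(self, freqs):
        freqs = np.asarray(freqs, dtype=float)
        return ContactProfile("2R", freqs, 24, np.arange(len(freqs)) * 3.1)

    def test_flat_profile_between_thresholds_gives_no_calls(self):
        prof = self._profile([0.3] * 20)
        assert call_peaks(prof, _stats(0.5, 0.14)) == []

    def test_adjacent_peaks_one_bond_apart_are_merged(self):
        freqs = [0.3] * 10
        freqs[4], freqs[5] = 0.7, 0.8  # one bond = one Kuhn length apart
        calls = call_peaks(self._profile(freqs), _stats(0.5, 0.14), kuhn_length=3.1)
        assert len(calls) == 1
        assert calls[0].bead_index == 5 and calls[0].frequency == 0.8

    def test_peaks_two_bonds_apart_are_kept_separately(self):
        freqs = [0.3] * 10
        freqs[3], freqs[5] = 0.7, 0.8
        calls = call_peaks(self._profile(freqs), _stats(0.5, 0.14), kuhn_length=3.1)
        assert sorted(c.bead_index for c in calls) == [3, 5]

    def test_tie_goes_to_lower_bead_index(self):
        freqs = [0.3] * 10
        freqs[4], freqs[5] = 0.8, 0.8
        calls = call_peaks(self._profile(freqs), _stats(0.5, 0.14), kuhn_length=3.1)
        assert [c.bead_index for c in calls] == [4]

    def test_boundary_frequency_is_not_a_call(self):
        freqs = [0.3] * 10
        freqs[4] = 0.5  # exactly at the threshold: strict inequality
        assert call_peaks(self._profile(freqs), _stats(0.5, 0.14)) == []

    def test_anti_contacts_called_below_lower_threshold(self):
        freqs = [0.3] * 10
        freqs[7] = 0.05
        calls = call_peaks(self._profile(freqs), _stats(0.5, 0.14))
        assert len(calls) == 1 and calls[0].call_type == "anti_contact"

    def test_planted_peaks_recovered_with_binomial_false_call_rate(self, params):
        # generator ground truth: plant p=0.8 contacts well separated on a
        # null baseline; the caller must find every planted position, and
        # the per-bead false-call probability equals the binomial tail
        # above the threshold
        baseline, n_nuclei, upper = 0.30, 24, 0.505
        planted = [("3R", 10, 0.8), ("3R", 20, 0.8), ("X", 15, 0.8)]
        planted_set = {(a, b) for a, b, _ in planted}
        rng = np.random.default_rng(7)
        n_exp = 400
        n_found = 0
        n_false = 0
        n_null_beads = 0
        for _ in range(n_exp):
            profs = synth_profiles(params, baseline, planted, [], n_nuclei, rng)
            for arm, prof in profs.items():
                calls = call_peaks(prof, _stats(upper, 0.0), kuhn_length=params.bond_length)
                for c in calls:
                    if c.call_type != "contact":
                        continue
                    # a call within one Kuhn length of a planted site counts
                    # as recovering it
                    if any(
                        a == arm and abs(b - c.bead_index) * params.bond_length <= params.bond_length
                        for a, b in planted_set
                    ):
                        n_found += 1
                    else:
                        n_false += 1
            n_null_beads += sum(len(p.frequencies) for p in profs.values()) - len(planted)
        assert n_found >= 0.99 * n_exp * len(planted)
        # binomial oracle for the false-call rate per null bead (merging
        # makes calls slightly rarer than raw exceedances, so allow a band)
        from scipy.stats import binom

        p_tail = binom.sf(np.floor(upper * n_nuclei), n_nuclei, baseline)
        observed = n_false / n_null_beads
        assert observed <= p_tail * 1.2
        assert observed >= p_tail * 0.2
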