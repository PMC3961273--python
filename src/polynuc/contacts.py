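"""Nuclear-envelope contact statistics.

A bead contacts the NE when the gap between its surface and the envelope
is at most ``ne_contact_distance`` (1 um by default, so a touching bead's
center lies within one bead radius plus 1 um of the envelope).  Averaging
the 0/1 contact indicator over the nuclei of one tracing experiment gives
a per-bead contact-frequency profile; repeating the experiment many times
gives per-bead means and standard deviations, from which global mean +/- 2
sigma thresholds for calling contacts and anti-contacts are derived.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .ensemble import generate_filtered_ensemble
from .nucleus import NucleusModel
from .params import ARM_IDS, ModelParams

__all__ = [
    "ContactProfile",
    "TracingStats",
    "PeakCall",
    "bead_ne_contact",
    "ne_contact_mask",
    "locus_locus_contacts",
    "contact_profile",
    "profiles_for_ensemble",
    "simulate_tracing",
    "fraction_above_threshold",
    "call_peaks",
]


@dataclass
class ContactProfile:
    """Per-bead NE-contact frequency of one arm over one set of nuclei."""

    arm_id: str
    frequencies: np.ndarray
    n_nuclei: int
    contour_positions: np.ndarray  # bead index * bond length, um

    def __post_init__(self):
        self.frequencies = np.asarray(self.frequencies, dtype=float)
        self.contour_positions = np.asarray(self.contour_positions, dtype=float)
        if len(self.frequencies) != len(self.contour_positions):
            raise ValueError("frequencies and contour_positions differ in length")


@dataclass
class TracingStats:
    """Per-bead mean/SD of contact frequency over replicate experiments,
    plus the global contact and anti-contact thresholds."""

    arm_ids: np.ndarray  # arm label per bead (flattened canonical order)
    bead_index: np.ndarray  # bead index within its arm
    mean: np.ndarray
    sd: np.ndarray
    upper_threshold: float
    lower_threshold: float
    n_replicates: int
    sigma_multiplier: float = 2.0
    profiles: list = field(default_factory=list, repr=False)  # per replicate: {arm: ContactProfile}

    def arm_slice(self, arm_id: str) -> np.ndarray:
        return np.flatnonzero(self.arm_ids == arm_id)


@dataclass(frozen=True)
class PeakCall:
    arm_id: str
    bead_index: int
    contour_position: float
    frequency: float
    call_type: str  # "contact" | "anti_contact"


def bead_ne_contact(center, params: ModelParams) -> bool:
    """Whether a bead at ``center`` contacts the nuclear envelope.

    True when the surface-to-envelope gap is at most
    ``ne_contact_distance`` (boundary inclusive).
    """
    center = np.asarray(center, dtype=float)
    r = float(np.linalg.norm(center))
    R, r_b = params.nucleus_radius, params.bead_radius
    if r > R - r_b + 1e-6:
        raise ValueError(f"bead center at radius {r:.3f} lies outside the allowed region")
    return R - (r + r_b) <= params.ne_contact_distance + 1e-12


def ne_contact_mask(centers: np.ndarray, params: ModelParams) -> np.ndarray:
    """Vectorized 0/1 NE-contact indicator for an array of bead centers."""
    r = np.linalg.norm(np.asarray(centers, dtype=float), axis=-1)
    gap = params.nucleus_radius - (r + params.bead_radius)
    return gap <= params.ne_contact_distance + 1e-12


def locus_locus_contacts(nucleus: NucleusModel, params: ModelParams) -> list[tuple]:
    """All unordered non-adjacent bead pairs whose surface gap is at most
    ``locus_contact_distance``.

    Pairs are reported as ``((arm_i, index_i), (arm_j, index_j))`` in
    canonical order.
    """
    from scipy.spatial.distance import pdist, squareform

    beads = nucleus.all_beads()
    arm_idx = nucleus.bead_arm_index()
    pos_in_arm = np.concatenate([np.arange(len(nucleus.chains[a])) for a in ARM_IDS])
    d = squareform(pdist(beads))
    cutoff = 2.0 * params.bead_radius + params.locus_contact_distance + 1e-12
    ii, jj = np.nonzero(np.triu(d <= cutoff, k=1))
    out = []
    for i, j in zip(ii, jj):
        if arm_idx[i] == arm_idx[j] and abs(int(pos_in_arm[i]) - int(pos_in_arm[j])) == 1:
            continue  # bonded neighbours are not locus-locus contacts
        out.append(
            (
                (ARM_IDS[arm_idx[i]], int(pos_in_arm[i])),
                (ARM_IDS[arm_idx[j]], int(pos_in_arm[j])),
            )
        )
    return out


def contact_profile(nuclei: list[NucleusModel], arm_id: str, params: ModelParams) -> ContactProfile:
    """Mean 0/1 NE-contact indicator per bead of one arm across nuclei."""
    if not nuclei:
        raise ValueError("empty nucleus list")
    n_beads = {len(n.chains[arm_id]) for n in nuclei}
    if len(n_beads) != 1:
        raise ValueError(f"nuclei disagree on bead count for arm {arm_id}")
    indic = np.stack([ne_contact_mask(n.chains[arm_id], params) for n in nuclei])
    freq = indic.mean(axis=0)
    contour = np.arange(len(freq)) * params.bond_length
    return ContactProfile(arm_id, freq, len(nuclei), contour)


def profiles_for_ensemble(nuclei: list[NucleusModel], params: ModelParams) -> dict:
    return {a: contact_profile(nuclei, a, params) for a in ARM_IDS}


def _flatten(profiles: dict) -> np.ndarray:
    return np.concatenate([profiles[a].frequencies for a in ARM_IDS])


def simulate_tracing(
    params: ModelParams,
    n_replicates: int,
    rng,
    variant: str = "fully_modified",
    exclude_first_bead: bool = True,
) -> TracingStats:
    """Replicate simulated tracing experiments and derive the thresholds.

    Generates ``n_replicates`` independent Rabl-filtered ensembles of
    ``params.nuclei_per_experiment`` nuclei, forms the per-bead contact
    frequency for each, then averages mean + sigma_multiplier * SD over
    chain beads (excluding the chromocenter-adjacent bead 0 of each arm
    when ``exclude_first_bead``) into the global contact threshold; the
    anti-contact threshold is the analogous subtraction, floored at 0.
    """
    if n_replicates < 2:
        raise ValueError("n_replicates must be >= 2")
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    all_profiles = []
    freq_rows = []
    for _ in range(n_replicates):
        ens = generate_filtered_ensemble(
            params, params.nuclei_per_experiment, rng, variant=variant
        )
        profs = profiles_for_ensemble(ens.nuclei, params)
        all_profiles.append(profs)
        freq_rows.append(_flatten(profs))
    freq = np.stack(freq_rows)  # (replicates, total beads)
    m = freq.mean(axis=0)
    s = freq.std(axis=0, ddof=1)
    arm_ids = np.concatenate(
        [np.full(params.arm_count(a), a, dtype=object) for a in ARM_IDS]
    )
    bead_index = np.concatenate([np.arange(params.arm_count(a)) for a in ARM_IDS])
    include = bead_index > 0 if exclude_first_bead else np.ones_like(bead_index, bool)
    k = params.sigma_multiplier
    upper = float((m[include] + k * s[include]).mean())
    lower = float(max(0.0, (m[include] - k * s[include]).mean()))
    return TracingStats(
        arm_ids=arm_ids,
        bead_index=bead_index,
        mean=m,
        sd=s,
        upper_threshold=upper,
        lower_threshold=lower,
        n_replicates=n_replicates,
        sigma_multiplier=k,
        profiles=all_profiles,
    )


def fraction_above_threshold(
    stats: TracingStats,
    profiles: list,
    exclude_first_bead: bool = True,
) -> float:
    """Fraction of (bead, experiment) frequencies strictly above the upper
    threshold.  ``profiles`` is a list of per-experiment profile dicts (as
    stored in ``TracingStats.profiles``) or of single ContactProfile
    objects."""
    values = []
    for item in profiles:
        if isinstance(item, ContactProfile):
            freqs = item.frequencies
            first = np.zeros(len(freqs), bool)
            first[0] = True
        else:
            freqs = _flatten(item)
            first = np.concatenate(
                [np.arange(len(item[a].frequencies)) == 0 for a in ARM_IDS]
            )
        if exclude_first_bead:
            freqs = freqs[~first]
        values.append(freqs)
    v = np.concatenate(values)
    return float((v > stats.upper_threshold).mean())


def call_peaks(
    profile: ContactProfile,
    stats: TracingStats,
    kuhn_length: float | None = None,
) -> list[PeakCall]:
    """Call contact and anti-contact positions on one profile.

    Contacts are beads with frequency strictly above the upper threshold,
    selected greedily in descending frequency (ties to the lower bead
    index); a remaining candidate within one Kuhn length of contour
    distance from an accepted call is suppressed, since positions closer
    than the Kuhn length are not independent chromosome loci.
    Anti-contacts are treated symmetrically below the lower threshold with
    ascending greedy selection.
    """
    if kuhn_length is None:
        # default to the bead spacing of the profile (bond = Kuhn length)
        diffs = np.diff(profile.contour_positions)
        kuhn_length = float(diffs[0]) if len(diffs) else 0.0
    calls: list[PeakCall] = []
    freq = profile.frequencies
    contour = profile.contour_positions

    def greedy(candidates: np.ndarray, order_key, call_type: str):
        accepted: list[int] = []
        for idx in sorted(candidates, key=order_key):
            if all(abs(contour[idx] - contour[j]) > kuhn_length + 1e-12 for j in accepted):
                accepted.append(idx)
        for idx in sorted(accepted):
            calls.append(
                PeakCall(
                    arm_id=profile.arm_id,
                    bead_index=int(idx),
                    contour_position=float(contour[idx]),
                    frequency=float(freq[idx]),
                    call_type=call_type,
                )
            )

    above = np.flatnonzero(freq > stats.upper_threshold)
    greedy(above, lambda i: (-freq[i], i), "contact")
    below = np.flatnonzero(freq < stats.lower_threshold)
    greedy(below, lambda i: (freq[i], i), "anti_contact")
    return calls
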