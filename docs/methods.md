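# Methods

## The model

`polynuc` implements a null model of the *Drosophila melanogaster* salivary
gland polytene nucleus with respect to chromosome–nuclear-envelope (Chr–NE)
attachment.  The five major polytene arms (X, 2L, 2R, 3L, 3R) are
freely-jointed bead–cylinder chains grown as self-avoiding walks inside a
spherical nucleus.  A chromocenter bead is anchored at the "north pole" of
the envelope; five initial beads are placed around it, each touching both
the chromocenter surface and the envelope, in a circular arrangement drawn
from a configurable weight table over the 12 distinct circular orderings of
the arms.  The arms then grow simultaneously, one bead per arm per round,
until each reaches its configured length.  Because the model contains every
geometric feature of the nucleus *except* specific Chr–NE attachments, the
distribution of its per-bead NE-contact frequencies serves as the null
against which experimentally traced contact frequencies can be judged.

All lengths are microns.  The defaults are pinned by the measured
constraints of the system rather than stored as magic numbers:

| parameter | default | rationale |
|---|---|---|
| bond length (Kuhn length) | 3.1 | one statistical segment per bond; directions decorrelate beyond it |
| bead radius | 1.0 | fiber thickness ≈ 2 µm; "within 1 µm of the NE" then describes a touching bead's center shell |
| cylinder radius | 1.0 | connector thickness equals the bead diameter |
| arm bead counts | X 45, 2L 49, 2R 47, 3L 48, 3R 59 | proportions follow relative polytene arm lengths; total 248 |
| nucleus radius | ≈ 11.434 (derived) | root of `chromatin_volume_ratio(R) = 0.30`, solved at construction time |
| chromocenter radius | 1.0 | not experimentally constrained; configurable |
| NE contact distance | 1.0 | a bead contacts the NE when its surface is within 1 µm of it |
| locus–locus contact distance | 2.0 | surface gap; equals one bead diameter |
| BT₁ / BT₂ | 2000 / 6000 | failed additions before a one-bead / one-bead-per-chain backtrack |
| chirality acceptance (R/L) | 1.0 / 0.5 | 2:1 acceptance bias toward right-handed twist, maximal acceptance rate |
| nuclei per experiment | 24 | matches the historical tracing-experiment size |
| Rabl target fraction | 0.80 | telomeres in the hemisphere opposite the chromocenter |

The chromatin volume ratio counts 248 bead spheres plus one exposed
connector cylinder per intra-arm bond (243 bonds), each of length
`bond − 2·bead_radius`; the chromocenter is excluded.  Inverting the ratio
at 0.30 fixes the nucleus radius, so the model cannot drift from the
measured packing density when any chain dimension is changed.

## Growth procedure

Each growth round proposes one uniformly random bond direction per
unfinished arm (normalized Gaussian triples, one child random stream per
nucleus).  A candidate bead must satisfy:

* confinement: center within `R − r_b` of the origin;
* sphere–sphere clearance `2·r_b` to every non-adjacent bead, and
  `r_cc + r_b` to the chromocenter;
* the cylinder-collision rule against every non-incident connector, and
  the reverse check of existing beads against the prospective connector;
* optionally, clearance to a nucleolus sphere (disabled by default: the
  nucleolus is acknowledged by the biology but its geometry is not
  constrained, so the flag documents the gap rather than guessing);
* an independent chirality acceptance draw: the sign of the scalar triple
  product of the last three bond vectors classifies the step as
  right-handed (accept probability 1.0), left-handed (0.5), or degenerate
  (1.0).

**Round semantics.**  Three readings of "the five beads are added
simultaneously" are implemented (`growth_mode`):

* `lockstep` (default): every unfinished arm redraws directions until it
  holds a valid candidate; the five beads commit together.  All arms
  advance at exactly the same rate.
* `independent`: each arm's candidate commits on its own; arms in crowded
  regions fall behind and catch up later.
* `joint`: all candidates are redrawn afresh each round and commit only
  if all pass at once.

The joint reading is retained for completeness but is computationally
intractable at the default density: the joint acceptance probability is
the product of five per-arm acceptances and collapses below 10⁻⁵ once the
nucleus is half full, so growth stalls indefinitely.  Lockstep and
independent growth sample the same per-step acceptance law and complete in
milliseconds; lockstep is the default because it preserves the symmetric,
synchronized-frontier character of the procedure.

**Backtracking.**  Two counters tally failed additions.  At BT₁ = 2000 the
last accepted bead of the arm that failed most since the last reset is
removed; at BT₂ = 6000 the last bead of *every* chain is removed (finished
arms reopen and regrow).  Counters reset on their own trigger and, by
default, on every commit, so backtracks fire only in genuine dead ends.
Both semantics (`reset_counters_on_accept`, `count_failures_per_candidate`)
are configurable.  A walk that exhausts its proposal budget
(`proposal_cap`, default 2×10⁶) in an irrecoverable trap — about 2–3% of
walks — is discarded and restarted from a fresh child stream, the standard
practice for chain-growth Monte Carlo.

**Cylinder collision rule.**  The connector cylinders contribute to the
excluded volume.  Two readings are implemented (`cylinder_collision`):
`center` (default) forbids bead centers inside the cylinder volume
(clearance = cylinder radius); `surface` forbids any bead–cylinder overlap
(clearance = bead radius + cylinder radius, applied to the exposed part of
the bond).  A packing computation shows the surface rule cannot be
satisfied by random growth at the default density: 770 µm of contour
wrapped in 2 µm-clearance capsules only fits the available 4.7×10³ µm³ of
admissible center space in near-nematic order, and growth indeed stalls at
~95% completion.  The center rule is additionally implied to be weaker
than the bead–bead constraint at the default geometry (the minimum
bead-to-bond distance compatible with bead–bead clearance is 1.26 µm >
1 µm), so under the defaults the effective excluded volume is that of the
bead spheres.  In free space, where the surface rule is feasible, it is
used for the "with cylinder" scaling variant.

## Rabl filtering and ensembles

The Rabl configuration (telomeres polarized away from the chromocenter) is
imposed a posteriori: nuclei are generated until greedily discarding those
with the fewest opposite-hemisphere telomeres (ties: the later-generated)
leaves an ensemble of the requested size whose opposite-telomere fraction
is at least the target (0.80).  Greedy discard of the worst nucleus raises
the fraction maximally per discard, so the kept set is the largest
qualifying subset.  Hemisphere membership is strict (`z < 0`); boundary
beads count as not opposite.  Raw ensembles polarize to ≈ 0.57
spontaneously, so roughly 2.5–3 nuclei are grown per kept nucleus.

The *unmodified* variant disables the chirality bias, the arrangement
weights, and the Rabl filter; it is the near-equilibrium reference used in
robustness comparisons.

## Analysis statistics

**Contact profiles and thresholds.**  A bead contacts the NE when its
surface-to-envelope gap is at most 1 µm.  One simulated tracing experiment
is a filtered ensemble of 24 nuclei; its per-bead contact frequency is the
mean 0/1 indicator.  Over `n` replicate experiments the per-bead mean
`m_b` and sample SD `s_b` (ddof = 1) are formed; the contact threshold is
the average of `m_b + 2 s_b` over chain beads — excluding bead 0 of each
arm, which touches the envelope by construction — and the anti-contact
threshold the analogous subtraction, floored at zero.  Peak calling
selects beads strictly above the threshold greedily in descending
frequency and suppresses any remaining candidate within one Kuhn length of
contour distance of an accepted call (ties to the lower bead index);
anti-contacts are treated symmetrically below the lower threshold.

**Territory index.**  For each arm, the convex hull of its bead centers is
built (Qhull) and all 248 chain-bead centers inside or on the hull
(half-space tolerance 1e−9) are counted; the index is the fraction
belonging to the arm.  The minimum possible index per arm is its bead
count over the bead capacity of the *maximal* confined hull, found by
pivot optimization: rotate a uniformly random chain suffix by a uniformly
random rotation, reject moves that break confinement or bead–bead
self-avoidance or that fail to strictly increase the hull volume, and stop
after a window of consecutive rejections.  The maximal confined hull
volume exceeds the total excluded volume of all 248 beads, so the capacity
is 248 and the minimum indices span 45/248 ≈ 0.18 to 59/248 ≈ 0.24.

**Intertwining.**  The backbone of an arm is the polyline through the
chromocenter and its bead centers.  Two backbones do not intertwine if a
rigid translation of one along some direction in a 162-vector geodesic
set (frequency-4 icosahedral subdivision), swept continuously over 35 µm
(longer than the nucleus diameter), produces no crossing.  Each
segment-pair sweep is solved exactly as a 3×3 linear system; degenerate
systems fall back to a coplanar clipping test.  The translation interval
is open at zero because all backbones share the chromocenter root point —
the initial contact is not a topological obstruction.  Directions aligned
with the centroid offset are tried first (early exit on the first
separating direction).

**Scaling checks.**  Free-space chains with the same bond length and
excluded-volume rules, no confinement and no chirality bias, are grown at
lengths 50–150 beads; the exponent ν is half the least-squares slope of
log⟨r²⟩ against log n.  A phantom chain (all excluded volume off)
reproduces ν = 1/2 to within its fit error, validating the direction
sampling and the estimator.

## Synthetic tracing data

The original experimentally traced nuclei are not digitally available, so
end-to-end tests of the peak caller run on synthetic profiles: per-bead
frequencies drawn as Binomial(24, p)/24 with p equal to a baseline rate
except at planted contact (elevated p) and anti-contact (suppressed p)
positions.  This emulates the *sampling noise* of a 24-nucleus tracing
experiment with known ground truth; it does not emulate spatial
correlation along the chromosome, tracing/digitization error, or
nucleus-to-nucleus heterogeneity beyond binomial, so caller performance on
real traces may differ.  Calls can be annotated with cytological division
labels via a band map that divides each arm's beads uniformly among its 20
divisions of the 100-division polytene nomenclature; the true
band-to-micron calibration is not machine-readable and is out of scope.

## Problem sizes and numerical choices

The packaged statistics use 24 replicate tracing experiments of 24 nuclei
(the study design uses 96), 100-nucleus ensembles for territory and
intertwining, 200 generated nuclei for the Rabl-filter check, and
2 500-proposal convergence windows for the hull optimizer; these sizes give
standard errors well below the comparison tolerances.  Clearances carry a
10⁻⁷ µm slack so exactly-touching configurations (initial beads on the
chromocenter and envelope) survive float rounding; trace files round-trip
at 10⁻⁶ µm and the post-hoc validator's bond-length tolerance admits that
precision.  The post-hoc validator is a separate brute-force code path
(full distance matrices) from the growth engine's incremental checks.

## Known limitations

Three emergent statistics fall short of their reference values, and the
gaps appear to be irreducible within the printed geometric constraints
rather than implementation artifacts:

* **Territory index** ≈ 0.59–0.61 against the reference 0.650/0.651.
* **Non-intertwining fraction** ≈ 55–60% against ≈ 95%.
* **Null exceedance tail** ≈ 5–6% against the nominal 2.5% (the per-bead
  contact-frequency profile is not flat: chain ends are entropically
  enriched at the envelope and chromocenter-proximal beads are shadowed,
  so a single global mean + 2σ threshold is exceeded more often than the
  homogeneous-normal expectation).

The root cause is scale: the nucleus radius is only ≈ 3.7 Kuhn lengths and
the chains occupy 30% of its volume, so any feasible growth reading
produces confined, partially interpenetrating coils.  Reproducing strongly
segregated, translation-separable wedge territories with a flat contact
profile would require either a different (unavailable) parameter set or
growth dynamics beyond what the model's description constrains.  The
sweep-crossing test was verified against a brute-force discretized oracle,
and systematic variation of the growth mode, the cylinder collision rule,
and the chromocenter radius moved these statistics by at most ~0.02, so
they are reported as the model's honest behavior.  The twist step ratio
stabilizes near 1.8 rather than 2.0: the 2:1 acceptance bias acts against
a negative feedback in which a right-twisted environment slightly
disfavors further right-handed steps.

The free-space scaling exponent of the bead-excluded-volume chain measures
≈ 0.54 ± 0.02 at lengths 50–150 — between the ideal 0.5 and the asymptotic
Flory value 0.588 — as expected for a thin chain (bead diameter 0.65 bond
lengths) in the finite-length crossover sampled by unweighted Rosenbluth
growth, which is known to bias toward compact configurations.
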