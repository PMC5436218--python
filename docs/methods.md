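# Methods

This note documents the models and numerical conventions behind `plqex`:
what the event definitions are, why the synthetic generator looks the way
it does, which knobs matter, and what the tests do and do not demonstrate
about real trajectories.

## Coordinate frame and units

All analyses run in a protein-fixed, right-handed frame with the membrane
normal along +z and the stromal side positive. Internal units are nm and
ns everywhere; only the statistics layer converts, reporting fluxes in
molecules ms⁻¹ per monomer and timescales in μs. Trajectories read
through MDAnalysis are converted from Å/ps on load. Ligand bead paths are
unwrapped per bead by minimum-image continuity between consecutive frames
(protein reference beads are assumed whole and never unwrapped), then
every frame is superposed onto a reference by least-squares rigid-body
fitting on the protein reference beads (scipy's SVD-based solver;
an independently coded closed-form quaternion solver serves as the test
oracle). Alignment is idempotent and rigid to 1e-9 nm on float64 inputs.

## Region model and point location

A `GeometryModel` names the volumes the event logic reasons about: a z
slab (the membrane), per-monomer exchange cavities (convex prisms), an
optional binding-site sphere union (Q_B), channels (prisms with an
oriented inner gate on the cavity boundary and an outer gate facing the
bulk), and optional protein footprints excluded from bulk. Channels are
prisms with planar gates rather than meshed protein surfaces: planar
gates make "crossed the gate" a well-defined, orientation-checkable
predicate, which is what passage counting needs.

Overlaps are resolved by fixed priority — channel > cavity > binding
site > protein footprint > bulk > off-membrane — so channel residence
dominates at gate boundaries. Leaflets are assigned by z against the
compartment midplane (a cavity may override the slab midplane); the tie
at exactly the midplane goes to the lumenal leaflet, an arbitrary but
documented and tested convention.

Channel cross-sections are measured as width = minimum inter-group bead
distance between two opposing lining groups and height = the combined
z-extent clipped to the slab. Minimum distance is one defensible
definition of "width" for a breathing protein channel; it is symmetric in
the two groups and degrades gracefully (width 0) when they touch.

For convex prisms the outside distance used by the hysteresis is the
supporting half-plane distance, which underestimates the true Euclidean
distance near corners; this only makes label changes near corners
slightly more conservative.

## State labeling with hysteresis

Raw labels flicker when a bead diffuses along a boundary. `label_trace`
applies two-threshold hysteresis: a raw label change is accepted only
once the head centroid is at least δ beyond the decision boundary
between the old and new label — penetration ≥ δ into the new region when
the new region ranks higher, distance ≥ δ beyond the old region's
boundary when it ranks lower. δ = 0 reduces exactly to raw point
location. The default δ = 0.3 nm is about one coarse-grained bead radius
and suppresses single-frame flicker at a 500 ps frame stride; it must
stay larger than the per-frame positional noise for the robustness
guarantee below to hold.

## Passage events and the cavity balance

Each ligand trace is partitioned into *side* occupancies — bulk-side
(bulk, off-membrane, protein surface) and cavity-side (cavity, binding
site) — separated by channel excursions. An excursion whose endpoints lie
on opposite sides is a **full** passage (entry or exit); same-side
excursions are **partial**; excursions cut off by the start or end of the
trace are **trapped** and excluded from flux, as ligands stuck in a
channel are bookkept separately from completed transits. A full passage
may span intermediate gate recrossings: the excursion is judged by its
endpoints, so diffusive recrossings do not fragment one transit into
many. The excursion's channel is the plurality channel label of its
frames (`None` when the trace jumps sides with no channel frame, which
can only happen when the residence was shorter than one frame).

Full passages are never filtered by dwell time. This is deliberate: it
makes the cavity balance

    Δ(cavity count) = entries − exits
                      + (trapped legs resolving into a cavity)
                      − (trapped legs leaving a cavity)

an exact telescoping identity on *any* trace, which `conservation_audit`
verifies per monomer and which doubles as an end-to-end integrity check
of the whole pipeline. The `min_dwell_ns` threshold (default 1 ns = two
frames at the 500 ps stride) only drops sub-threshold partial excursions,
so the full-event count is trivially non-increasing in it.

Orientation (head-first vs tail-first) compares the first frames at which
the head and tail centroids arrive inside the channel interior on the
relevant gate's side — the outer gate for entries, the inner gate for
exits. The search window opens 100 ns before the event, because the event
clock is driven by the head's labels: a tail that led the way crossed
before the window would otherwise open. Ties on the same frame are
undetermined, as are events without a channel or without tail beads.

Flip-flops use a per-compartment Schmitt trigger on the head z
coordinate: an event fires when z moves from beyond +δz above the
compartment midplane to beyond −δz below it (or vice versa) without the
ligand leaving the compartment; any compartment exit resets the detector.
δz defaults to 0.3 nm. The head bead alone is used: headgroup leaflet
residence is the physically meaningful marker for an amphiphile.

Unbinding uses two-threshold hysteresis on the head-to-site distance:
**full** when the distance exceeds `r_unbound` and does not return below
`r_bound` within `t_rebind`; **transient** when it does; **partial** when
the head stays bound while the tail centroid slides out of the channel
interior. The defaults (0.6 nm, 1.2 nm, 50 ns) are stated conventions
for a coarse-grained site, not fitted values.

## Statistics

Fluxes are count-based: per monomer, (number of full events of that
channel and direction) / monitored time, converted to ms⁻¹. The table
reports mean and s.e.m. **over monomer-replicates** (n = 10 by default:
five replicate runs × two monomers), never over events — replicates are
the independent units. Cavity occupancy is the per-frame count of
cavity-side ligands per monomer; the end statistic averages a trailing
window (default the final 5% of the trajectory, configurable) per
monomer, then takes mean ± s.e.m. over monomers. Timescales are
residence time / event count; with zero events the total residence time
is reported as a lower bound (a one-event-missed convention — the true
expected time could not be shorter without an event having been seen).

## The synthetic generator

Ground truth comes from a compartmental CTMC rather than Brownian
dynamics with barriers: exponential dwells and categorical jumps sampled
exactly (Gillespie) give an event log that is correct by construction at
trivial cost, which is the whole point of the generator. States are the
two bulk leaflets, three channels per monomer, two cavity leaflets per
monomer, and the Q_B site; only physically adjacent states may be
connected, and the generator matrix is validated for that.

**Rates.** The default preset targets per-monomer channel fluxes in the
ratio 10 : 1 : 8 (in) and 4 : 1 : 6 (out) molecules ms⁻¹, cavity
flip-flop at 1/100 μs⁻¹ total and bulk flip-flop at 1 μs⁻¹ total (flip
parameters are per direction, i.e. half those totals), and a channel
transit time of ~2 μs with a 70% probability of completing toward the
cavity. The study conditions are five replicates of 95 μs, two monomers,
24 bulk ligands, frames every 500 ps, giving ten monomer-replicates for
averaging. Because the run starts with every ligand in the bulk and the
cavity fills transiently, in-flux exceeding out-flux is realizable; the
absolute entry/exit rate constants are calibrated so that the *expected
realized* fluxes over the configured duration equal the targets. The
calibration iterates a damped multiplicative update against occupancy
integrals of the master equation (computed exactly via an augmented
matrix exponential) and converges below 1e-7 relative error at the study
conditions. Denser variants for detection-fidelity studies scale the
flux targets (e.g. 6×) while leaving per-event kinetics — channel and
cavity dwells — in the same regime, so per-event detection behaviour is
unchanged while events per rendered nanosecond go up.

**Rendering.** Each ligand's head bead follows a piecewise-linear anchor
path: sampled wander points inside the current state's sampling volume
(inset 0.55 nm from region boundaries), portal points on the shared gate
at each transition, plus bounded per-frame noise (truncated normal,
|noise| ≤ 0.25 nm < δ). Bulk legs are routed around the protein
footprints (rectangular obstacle avoidance with corner waypoints), so a
rendered ligand can only reach a cavity through a channel — exactly as in
the kinetic model; spurious side changes are geometrically excluded
because anchor insets plus the noise bound keep every frame at least δ
away from any region the ligand is not in. Gate crossings are rendered
briskly (a few ns) with the channel dwell spent wiggling at mid-channel:
a slow drift through the gate would bury the head/tail arrival order
under positional noise. Tail beads are a 5-bead chain replaying the
head's path with a per-bead lag (default 2 ns); whether the head or the
tail leads is scripted per ligand and recorded, which makes orientation
ground truth exact. One global seed spawns per-ligand substreams
(`SeedSequence.spawn`), so increasing the ligand count never reshuffles
existing ligands' paths, and identical configuration + seed reproduces
bit-identical coordinates.

**What the generator does not emulate.** Real trajectories have
excluded-volume interactions, force-field energetics, protein breathing
that opens and closes channels, anisotropic diffusion, and state
boundaries that are not sharp prisms. Passing the recovery tests
therefore demonstrates that the event logic is correct *given* the
region model and that detection is robust to bounded positional noise
and boundary flicker — not that the region geometry is right for any
particular protein. On real data the geometry config is the user's
scientific claim.

**Adaptive respawn.** The harness mirrors adaptive seeding of short MD
runs: each round ranks stored configurations by a pluggable progress
coordinate (the bundled selector uses directed hop distance to the
target state on the rate graph), restarts `k_select` short runs from the
best (ties broken uniformly at random), and stores time-uniform
snapshots of each run. Snapshots are time-uniform rather than per-jump
because jump-state storage over-represents short-dwell states and would
make even an uninformative selector enriched relative to plain restarts.
The baseline spends the identical budget restarting from the initial
configuration; the enrichment ratio is adaptive hits / baseline hits.
The bundled rare-binding toy (entry 0.012 μs⁻¹ into a single channel,
fast cavity decay, absorbing Q_B with binding rate 0.5 μs⁻¹ from the
stromal cavity leaflet; 8 rounds × 12 runs × 4 μs, snapshots every
0.5 μs) sits in the regime where direct runs rarely bind but
cavity-adjacent restarts often do.

## Problem sizes used by the test suite

The suite exercises the full study conditions for flux recovery (five
95 μs replicates, 24 ligands, 500 ps stride ≈ 2.3 × 10⁷ ligand-frames);
conservation over 50 independent 8 μs runs; fidelity over twenty 25 μs
runs of the 6× preset (≥ 100 pooled transits); flip-flop recovery at a
boosted cavity flip rate (0.05 μs⁻¹ per leg over 20 × 300 μs of
confined-cavity residence, ~600 expected events) so that the 3-standard-
error Poisson comparison has power at test-scale cost; and telegraph
kinetics pooled over 20 seeds against the central 95% Poisson band.
Flux-recovery tolerances compare against the *predicted* s.e.m. of the
count-based estimator under the configured kinetics, √(f/(T·n)), because
at ~1 expected channel-II event per run the sample s.e.m. is zero
whenever no event occurs and cannot calibrate a comparison.

## Known limitations

- The slab is z-aligned by construction, so `locate` covariance holds for
  translations and rotations about z, not arbitrary rotations (the
  alignment step is what puts real trajectories into this frame).
- Outside-distance for prisms is the supporting half-plane distance
  (exact inside, conservative near outside corners).
- A channel residence shorter than one frame stride cannot be assigned a
  channel; the side change is still counted (as an unassigned full
  passage), preserving the cavity balance.
- The flux calibration targets expected counts; any single realization
  fluctuates with Poisson noise, which is what the s.e.m. quantifies.
- Non-orthorhombic boxes, trajectory writing, and velocities are out of
  scope; density normalization is per frame, not per volume of water.
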