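# plqex

Quinone exchange-pathway analysis for membrane-protein molecular-dynamics
trajectories.

Photosystem II (PSII) oxidizes water and hands its electrons to the mobile
carrier plastoquinone (PLQ), which is reduced at the exchangeable Q_B site
to plastoquinol (PLQol) and must then leave the complex through narrow
channels that connect an internal, lipid-filled *exchange cavity* to the
thylakoid membrane. Quantifying that exchange from coarse-grained MD
trajectories requires turning hundreds of microseconds of bead coordinates
into discrete, countable events: which ligand entered which channel, did it
cross all the way into the cavity or retreat, did it lead with its
headgroup or its tail, how often does it flip between the stromal and
lumenal leaflets, and when does a bound PLQol actually unbind.

`plqex` is the analysis machinery for exactly this class of problem, built
for people running (or re-analyzing) coarse-grained simulations of
cofactor/lipid exchange in membrane-protein complexes:

- **trajio** — trajectory input (GRO/PDB + XTC/DCD via MDAnalysis, or a
  plain TSV dialect), role tagging (ligand head/tail beads, protein
  reference beads), per-ligand periodic unwrapping, least-squares rigid
  superposition into a protein-fixed frame, equilibration trimming.
- **geometry** — a named-region model (membrane slab, exchange cavities,
  binding-site spheres, channels with planar inner/outer gates) with
  priority-resolved point location and channel cross-section measurement.
- **events** — hysteresis-filtered state traces and typed events: channel
  passages (full / partial / trapped, with head-first vs tail-first
  orientation), leaflet flip-flops (Schmitt trigger on the head z
  coordinate), and binding-site unbinding (full / transient / partial via
  two-threshold distance hysteresis).
- **stats** — per-channel flux tables in molecules ms⁻¹ per monomer with
  s.e.m. over monomer-replicates, cavity occupancy series, per-event
  timescale estimates (residence time / event count, with a lower-bound
  convention for zero events), and an exact cavity-balance audit:
  Δ(cavity count) = full entries − full exits (+ trapped-leg corrections).
- **density** — integer 3D occupancy grids of aligned ligand positions,
  exact merging across replicates, threshold + maximum-intensity
  projection with 26-connected component counting, OpenDX export.
- **synthetic_data** — a compartmental continuous-time Markov chain
  (bulk leaflets ↔ channels ↔ cavity leaflets ↔ Q_B site) sampled exactly
  (Gillespie) and rendered into 3D bead coordinates in a toy two-monomer
  scene, so every statistic the pipeline reports has a known ground truth;
  plus an adaptive-respawn harness that restarts short runs from
  progress-ranked stored configurations and compares against an
  equal-budget plain-restart baseline.
- **pipeline / CLI** — `plqex simulate | analyze | density | report`
  orchestration with a reproducibility manifest (parameters, seed, input
  checksums).

## Worked example

Generate a small synthetic dataset with known kinetics and analyze it:

```bash
plqex simulate --out data --seed 42 --n-ligands 12 --duration-us 20 \
               --stride-ns 2 --rate-scale 6
plqex analyze --trajectory data/trajectory.tsv --geometry data/geometry.yaml \
              --role-map data/role_map.yaml --out run
plqex report --run-dir run
```

which prints (exactly this, for this seed):

```
n_full_passages: 9
n_partial_passages: 11
n_trapped: 3
n_flipflops_cavity: 0
n_flipflops_bulk: 87
cavity_occupancy_end_mean: 0.34530938123752497
cavity_occupancy_end_sem: 0.3453093812375249
flipflop_timescale_us: {'kind': 'lower_bound', 'value_us': 31.424857514248576}
mean_interevent_time_us: 4.444444444444445
conservation_ok: True
conservation_violations: []
```

Nine complete channel transits were detected (plus eleven retreats and
three ligands caught inside a channel at a trajectory boundary), the two
cavities held ~0.35 ligands on average over the trailing window, no cavity
flip-flop occurred so the reorientation timescale is reported as a lower
bound (the total cavity residence time), and the cavity balance audit is
exact. `run/flux_table_wide.tsv` holds the per-channel table
(rows: flux in / flux out; columns: channels I, II, III; cells
mean±s.e.m. in molecules ms⁻¹ per monomer — large here because this demo
deliberately runs a 6× boosted, 20 μs toy, not the full study). The same
results are available programmatically:

```python
from plqex import synthetic_data as sd, events as ev
from plqex.stats import compute_flux_table, conservation_audit

model = sd.psii_exchange_model(n_ligands=24, duration_us=95.0)  # 10:1:8 / 4:1:6 preset
sim = sd.simulate_ctmc(model, 95.0, seed=1)
traj, role_map, scene = sd.render_simulation(sim)
traces = ev.label_trace(traj, role_map, scene.model)   # hysteresis labels
passages = ev.detect_passages_all(traces)
flux = compute_flux_table(passages, {0: 95e3, 1: 95e3})
print(flux.wide())
assert conservation_audit(traces, passages).ok
```

`examples/toy_psii_geometry.yaml` is the bundled geometry config for the
two-monomer, three-channel toy scene (the schema `plqex analyze --geometry`
expects); `plqex analyze --config run.yaml` reads all parameters from one
YAML file, with command-line flags overriding individual entries.

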