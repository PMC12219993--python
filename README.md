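# edgesync

Edge time series decomposition, high-amplitude co-fluctuation **event**
detection, and inter-subject event **synchrony** analysis for multi-subject
naturalistic (movie-watching) fMRI.

## The problem

Functional connectivity (FC) between two brain parcels is the Pearson
correlation of their BOLD time series.  Writing each series as z-scores,

```
r_ij = 1/(T-1) * Σ_t  z_i(t) · z_j(t)
```

so the correlation is the temporal average of a frame-wise product.
Dropping the sum gives the **edge time series**

```
e_ij(t) = z_i(t) · z_j(t)
```

a moment-by-moment decomposition of every functional connection.  The
global co-fluctuation amplitude at a frame is the root sum of squares over
all edges,

```
RSS(t) = sqrt( Σ_{i<j} e_ij(t)² )
```

whose transient peaks define *events*.  During movie watching, events tend
to synchronize across subjects — most conspicuously just after movie-scene
endings, at the hemodynamic delay.  `edgesync` implements the full
analysis chain:

1. **Event detection** per scan: RSS is thresholded against a null built by
   independently circularly shifting each node's series (preserving
   autocorrelation, destroying inter-node alignment); each supra-threshold
   run is collapsed to its peak frame.
2. **Boundary regressors**: coded scene-ending times convolved with a
   canonical double-gamma hemodynamic response function (HRF); lagged
   correlations and peri-boundary profiles relate events to endings, and a
   windowed circular-shift test gives per-scan p-values.
3. **Group synchrony**: the per-frame fraction of subjects with an event is
   tested against a null pooled from stimulus-free rest scans, with
   Benjamini–Hochberg FDR control (q = 0.05).
4. **Tripartite classification**: significant frames within the post-ending
   window are *boundary* events, other significant frames are *movie*
   events, eventful non-significant frames are *asynchronous*, and frames
   with no events at all are *non-events*.
5. **Characterization**: amplitude by type, the (3·S)×(3·S) global
   similarity matrix of event co-fluctuation patterns, mean patterns with
   system-block spin/permutation tests, peak-locked temporal profiles, and
   edge-wise paired difference tests.
6. **Activation analysis**: per-node correlation with the boundary-event
   indicator, system-level spin tests, and inter-subject stability against
   a time-shifted null.
7. **Repeated viewings**: synchrony and pattern similarity across repeated
   presentations of the same clip, and their relationship.

A synthetic-data generator (`edgesync.simulate`) emulates the study design —
modular background connectivity, shared HRF-convolved boundary responses
(visual deactivation, control/salience activation), shared mid-movie
responses, subject-private bursts, and stimulus-free rest — so the entire
pipeline is exercised end-to-end without any dataset download.

## Worked example

```python
import collections
from edgesync import RunConfig, SimSpec, run_pipeline, simulate_group

spec = SimSpec(seed=7)              # 20 subjects, 600 frames, 60 nodes
sim = simulate_group(spec)
cfg = RunConfig(seed=7)             # alpha=0.05, n_null=100, q=0.05
res = run_pipeline(cfg, {
    "movie": sim.movie_scans,
    "rest": sim.rest_scans,
    "boundaries": sim.boundary_frames,
    "centroids": sim.centroids,
})

print("frame classes:", dict(collections.Counter(res.classification.labels)))
print("event lag peak: %.1f s" % res.lag_profile.peak_lag())
print("windowed shift test p = %.4f" % res.shift_test_p)
t, p, wi, be = res.within_between["boundary"]
print("boundary similarity within=%.3f between=%.3f (p=%.2g)" % (wi, be, p))
print("top cross-system block:", res.boundary_pattern.top_block(between_only=True))
print("activation stability: mean r=%.2f, p=%.4f" % res.stability)
```

prints

```
frame classes: {'non_event': 506, 'asynchronous': 75, 'boundary': 11, 'movie': 8}
event lag peak: 5.0 s
windowed shift test p = 0.0297
boundary similarity within=0.678 between=0.065 (p=0)
top cross-system block: ('visual', 'control')
activation stability: mean r=0.98, p=0.0099
```

Reading the output: the group event fraction is maximally correlated with
boundary impulses at a 5 s lag (the HRF peak); there are significantly more
events within ±10 s of endings than chance (p ≈ 0.03); synchronous frames
split into boundary and movie classes; boundary events are far more similar
to each other than to other event types; their mean co-fluctuation pattern
is dominated by the visual–control interaction (visual deactivation times
control activation); and the per-node activation map is highly reproducible
across subjects against a time-shifted null.

## Command line

Each stage is also a CLI subcommand over the same library code:

```bash
edgesync simulate  --seed 7 --out-dir data/            # synthetic dataset
edgesync edgets    --scan data/movie/sub000.tsv --out-dir out/
edgesync events    --scan data/movie/sub000.tsv --seed 7 --out-dir out/
edgesync synchrony --data-dir data/ --seed 7 --out-dir out/
edgesync characterize --data-dir data/ --seed 7 --out-dir out/
edgesync activation   --data-dir data/ --seed 7 --out-dir out/
edgesync simulate  --seed 7 --viewings 4 --out-dir views/
edgesync timelocked --data-dir views/ --seed 7 --out-dir out_tl/
edgesync pipeline  --data-dir data/ --seed 7 --out-dir out/   # everything
```

Inputs are TSV: time series with frames as rows and a node-label header;
boundaries as `(scan_id, time_seconds)`; system assignments as
`(node_label, system_label)`.  All outputs declare the 0-based frame
convention in a header line, and a given seed reproduces every output
byte-for-byte.

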