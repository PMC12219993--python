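# Methods notes

## Model and procedure

`edgesync` operates on parcellated BOLD scans, `T` frames by `N` nodes.
Each node's series is standardized with the *sample* standard deviation
(ddof = 1); with that convention the temporal mean of the edge product
series, divided by `T − 1`, equals the Pearson correlation exactly, and the
package treats this identity as a hard invariant (tested to 1e-10).

The co-fluctuation amplitude is computed two ways: directly from the edge
matrix, `RSS(t) = sqrt(Σ_{i<j} e_ij(t)²)`, and through the algebraic
identity `RSS(t)² = ((Σ_i z_i²)² − Σ_i z_i⁴)/2`, which needs only O(N) per
frame.  The fast form is what the circular-shift null uses internally — a
null realization only permutes each node's series, so per-node powers can
be shifted and summed without rebuilding the O(N²) edge matrix.  Agreement
of the two forms is itself a test invariant.

### Event detection

The null model circularly shifts each node's z-scored series by an
independent uniform offset, preserving each node's autocorrelation and
marginal moments while destroying inter-node temporal alignment.  All
`T × n_null` null RSS values are pooled and the detection threshold is the
`(1 − α)` percentile of the pool.  Pooling over time (rather than a
frame-wise null) is a deliberate choice: circular shifting makes frames
exchangeable, so a frame-wise null would estimate the same distribution
with far fewer samples.  Supra-threshold runs are collapsed to their
maximum frame; ties go to the earliest frame, deterministically.  No
minimum inter-event spacing is imposed, since adjacent-frame structure
around peaks is itself analysed downstream.

### Boundary regressors and lag analyses

Scene endings are encoded as unit impulses (not boxcars) and convolved with
a canonical double-gamma HRF: gamma-density difference with shapes 6 and
16, unit scale, undershoot ratio 1/6, 32 s support, sampled at the TR and
normalized to unit peak.  These parameters are the de-facto canonical
choice and are configuration-exposed; the sampled kernel peaks 5 s after
the impulse at TR = 1 s.  Rest-block onsets are treated as the same
boundary as the preceding scene ending.

Lagged correlation uses a truncation (no-wrap) convention: at lag `+k`
frames the overlap `x[:T−k]` vs `y[k:]` is correlated, so a series that
trails its driver peaks at positive lag; lags with fewer than 10
overlapping frames are dropped.  The pipeline correlates the group event
fraction against the raw boundary *impulses*: the synthetic injections are
themselves HRF-convolved, so the recovered peak lag equals the HRF peak
(5 s), mirroring the hemodynamic-delay interpretation.  The windowed test
counts events within ±10 s of any ending and compares against counts under
a shared circular shift of the window positions, with the +1-smoothed
permutation p-value `(1 + #{null ≥ obs})/(1 + n_shifts)`.

### Synchrony and classification

Per-subject binary event series (peak-frame convention) are stacked; the
per-frame fraction of subjects with an event is compared against a null of
such fractions pooled from rest scans, where any synchrony is chance.  The
permutation-style p with +1 smoothing never reaches zero; its floor is
`1/(1 + #null frames)`.  This has a practical consequence: the pooled rest
null must be larger than `m/q` (m = movie frames tested) for any frame to
survive Benjamini–Hochberg correction, which is why the default synthetic
design includes four rest sessions per subject — matching the multi-session
design of the studies this pipeline targets.  A circular-shift null on the
movie event series is available as a sensitivity mode (`null_mode="shift"`);
the rest null is the default as the more conservative choice.

Classification: a significant frame within `[ending, ending + 10 s]` of any
coded ending is a *boundary* frame (boundary takes precedence when windows
overlap movie segments); other significant frames are *movie*; eventful
non-significant frames are *asynchronous*; frames where no subject has an
event are *non-events* regardless of p.  The 10 s window covers the 5 s
hemodynamic peak plus inter-individual timing variation.

### Characterization

Each event's co-fluctuation pattern is the edge-series row at its peak
frame (peak frames only, not whole supra-threshold runs).  The global
similarity matrix aggregates pairwise pattern similarities by
(type, subject) into a `(3·S) × (3·S)` matrix; the per-pair 3×3 reduction
is asymmetric by construction and is stored exactly as computed.  Because
cell ((a,r),(b,s)) equals ((b,s),(a,r)), the within- vs between-type test
uses each unique (subject-pair, type-pair) mean once — the upper triangle
of the within block and one orientation of each cross block; using both
copies would double the apparent sample size and inflate the test (this
was measured and fixed during development).  Similarity metrics: Pearson on
vectorized upper triangles (default), Spearman, or normalized mutual
information on decile-binned values.

System-block significance of a mean pattern uses node permutations —
geometry-preserving spins (random 3-D rotations of unit-sphere centroids
with nearest-centroid reassignment) when centroids are available, otherwise
size-preserving label shuffles — with two-sided p-values centered on the
null mean and BH-FDR across blocks.  The "top block" query is restricted to
between-system blocks when asking about stimulus-driven structure, because
within-system blocks are elevated by background modularity regardless of
events.  Edge-wise type differences use within-subject difference signs and
a group paired t-test per edge, BH-FDR across edges (Bonferroni is used for
the 21 peak-locked offsets, matching the temporal-profile analysis).

### Activation and stability

The activation map correlates each node's raw activity with the binary
boundary-frame indicator (frame labels already absorb hemodynamic lag; an
HRF-convolved indicator is available for sensitivity).  System
concentration is tested with the same spin/label-permutation machinery.
Stability compares the mean pairwise correlation of subjects' maps against
maps recomputed with independently circularly shifted indicators.

## The synthetic generator

`SimSpec` defaults describe the study conditions end-to-end: 20 subjects,
TR = 1 s, 600-frame movie scans, 60 nodes in 6 systems, 4 boundary frames
(100, 220, 340, 460), 3 shared mid-movie frames (160, 280, 400), four rest
sessions per subject, Poisson(3) private bursts per scan, unit measurement
noise.

* **Background**: `x_node = sqrt(c)·latent(system) + sqrt(1−c)·private`
  with coupling `c = 0.3` — the simplest construction producing modular FC.
* **Injections** are all convolved with the same canonical HRF used by the
  regressor builder, so the planted lag equals the HRF peak lag by
  construction (internal consistency over biophysical realism).
* **Boundary response**: signed loadings (visual −1.2, control +1.0,
  salience +0.6) times `boundary_gain = 5`.  The graded magnitudes give the
  rank-1 planted pattern strictly ordered cross-system block strengths with
  visual–control strongest; with equal magnitudes the cross blocks would
  exactly tie the within blocks and the "top block" would be decided by
  noise.
* **Movie response**: one shared random unit-RMS pattern, gain 4.
* **Asynchronous bursts**: per-subject Poisson frames with freshly drawn
  unit-RMS patterns (gain 4), present in movie and rest alike; burst frames
  are kept 15 s away from shared frames so planted classes stay temporally
  unambiguous.
* **Jitter**: each subject's shared responses are shifted by ±1 frame
  (uniform) to emulate inter-individual latency variation.
* Gains are expressed in units of the noise standard deviation; they were
  chosen once so that detection operates in a regime comparable to the
  qualitative event prevalence the pipeline targets, and are
  configuration-exposed.

What the generator does **not** emulate: BOLD biophysics, physiological
noise and scanner drift, spatial autocorrelation within systems beyond the
shared latent, heavy-tailed motion artifacts, and subject-specific FC
"fingerprints" beyond private bursts.  Passing tests therefore demonstrate
statistical correctness of the machinery under the stated generative
assumptions, not performance on real data.

## Numerical choices and degenerate inputs

* Frame indices 0-based everywhere; on-disk times in seconds; conversion by
  rounding to the nearest frame (two TRs, 1.0 s and 0.813 s, share all code
  paths).
* One global seed fans out to per-stage child seeds through a CRC-derived
  `SeedSequence`, so any stage is reproducible in isolation; identical
  inputs and seed give byte-identical outputs.
* Zero-variance nodes are flagged at read time and rejected at z-scoring
  with the node named; constant indicators and single-subject group tests
  raise errors rather than returning NaN.
* TSV is the interchange format; numbers are written with 17 significant
  digits and parsed with numpy's correctly rounded reader, giving exact
  float64 round trips (pandas' fast parser is not correctly rounded and is
  used only to locate malformed cells).
* Permutation p-values use +1 smoothing throughout; two-sided permutation
  tests center on the null mean.
* Spin reassignments are not forced to be bijections (standard practice);
  nodes without centroids fall back to label permutation.

## Problem sizes

The test suite and the acceptance script size their simulations to run on
one CPU in about a minute each: 100 scans of 200×50 for exactness, 200
scans of 500×50 for detector calibration, the default 20-subject group for
recovery and characterization, 100 reduced groups (10 subjects, 300×30,
2 rest sessions) for FDR behaviour, and 500 replicates per permutation-test
calibration.

## Known limitations

* The pooled-over-time null for event detection assumes approximate
  stationarity within a scan.
* The rest-null synchrony test inherits the granularity limit described
  above; very short rest pools cannot support FDR-corrected detection.
* The asymmetric 3×3 per-pair aggregation is symmetrized only for display.
* Whether event similarity should use all supra-threshold frames rather
  than peak frames only is an open choice; peaks are used.
* Automatic peak selection for repeated-viewing discrimination uses a
  simple prominence rule; hand-picked peak lists are supported and
  preferred for irregular synchrony profiles.
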