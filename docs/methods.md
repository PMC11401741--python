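# Methods

This note documents the signal model, the algorithms and their
assumptions, the parameters that matter, and the design decisions taken
where the problem left genuine freedom.

## Signal model

A time-series SCM run is an ordered sequence of centroided MS1 scans
`(retention time, m/z array, intensity array)`. The measured signal is
modelled as three superimposed components:

* **Background contaminant ions** — a small set of m/z positions present
  in essentially every scan at a roughly constant count rate (solvent
  clusters, polysiloxanes, plasticizers).
* **Chemical noise** — sporadic low-intensity peaks at random m/z.
* **Cell transients** — when a cell is ionized, its metabolite panel
  appears for a few scans with a pulse-shaped envelope; all of a cell's
  metabolites share that envelope, scaled per metabolite.

The pipeline assumes cell transients are sparse in time (they occupy
well under half of any baseline window; see *Limitations*), that within
a run the m/z axis error is a constant shift at ppm-level scatter, and
that ionization happens one cell at a time (no coincident-cell
deconvolution is attempted).

## Stages

### m/z consolidation (resolution, default 0.01 Th)

All m/z values of the run are pooled and sorted; a new feature bin
starts wherever the gap to the previous value exceeds the resolution
(single-linkage clustering by gaps). This merges the scan-to-scan
scatter of one physical ion species without the edge-splitting a fixed
grid causes. The bin's representative m/z is the intensity-weighted mean
of its members; per-(scan, bin) intensities are summed, so total ion
intensity is conserved exactly. An independent graph-connectivity oracle
(connected components of the "within resolution" graph) pins these
semantics in the tests. Consequence of single linkage: dense chemical
noise can chain distinct species together if consecutive gaps all fall
below the resolution; the occurrence filter removes most such chains.

### Occurrence filter (min_occurrence, default 10 scans)

Bins with positive intensity in fewer than 10 distinct scans are
removed — they cannot be recurrent chemistry. This is counted over
*scans* (pre-detection); prevalence over *cells* is a separate, later
filter.

### TIC cell detection

* TIC: summed intensity per scan (computed on the consolidated,
  occurrence-filtered table by default, so sporadic chemical noise no
  longer contributes).
* Baseline: centred rolling median (window 51 scans, edge-truncated).
* Noise scale σ: 1.4826 × rolling median absolute deviation about the
  baseline, floored at the smallest positive deviation so it is never
  zero. A constant trace therefore gets the floor value.
* Candidates: local maxima of the 3-scan rolling-median smoothed TIC.
  A candidate must reach S/N ≥ 3 — `(TIC − baseline)/σ` — on **both**
  the raw and the smoothed trace. The smoothed condition is a
  persistence requirement: a genuine multi-scan transient loses little
  of its apex to a 3-point median, while a single-scan spike loses
  nearly all of it. Because a symmetric apex becomes a two-sample
  plateau after median smoothing, the accepted candidate is snapped to
  the raw-TIC maximum within the smoothing half-window before spans are
  grown (screening happens first, so spikes rejected by smoothing stay
  rejected).
* Spans grow from the apex in both directions until the TIC falls into
  the noise band (baseline + σ) or rises again past a valley, capped at
  10 scans per side; apexes closer than 2 scans keep only the higher;
  overlapping spans are split at the inter-apex valley. Spans are
  half-open `[start, end)` over 0-based scan indices.
* Noise windows: the 5 scans flanking each span on either side, minus
  any scan inside another event's span. These feed the local noise
  model.

S/N is scale-free, so detection is invariant under uniform intensity
scaling (property-tested).

### Local noise estimation and subtraction

For each cell and each feature bin, the local noise level is the median
intensity of that bin over the cell's flanking noise scans, counting
scans where the bin is absent as zero. The profile's `global_floor` —
the median of its positive per-bin levels — is the fallback noise scale
for bins with no local background, so the S/N screen never divides by
zero. With span length `L`, the entry is **valid** iff its per-scan mean
`value/L` reaches 3 × max(local noise, floor); valid entries become
`max(0, value − L × noise)`, everything else becomes zero. Output is
entrywise within `[0, input]` by construction.

The floor-based screen presumes background ions are *not* orders of
magnitude brighter than cell signals: the floor sits at the median
background level, so any metabolite whose per-scan intensity is below
three times that level is discarded as unresolvable from background.
This matches flow-injection SCM practice — cell transients must rise
well above ambient background for the experiment to work at all — and
the synthetic study conditions are set in that regime (below).

When all cells share identical noise windows the procedure reduces
exactly to global background subtraction (tested).

### Matrix filters and normalization

* Cell filter: cells with fewer than 10 nonzero features after
  denoising are dropped — this removes debris events and any spurious
  TIC detection, which carry almost no features once the background is
  subtracted.
* Prevalence filter: features nonzero in < 15 % of cells are removed
  (the practical band is 10–20 %; the default is the midpoint; a
  feature exactly at the threshold survives). Applied on the denoised
  layer, before normalization, so prevalences are not distorted by
  per-cell scaling.
* Normalization (per cell): `total` rescales each cell so its feature
  sum equals the cohort **median** row sum (not 1 — values stay on an
  interpretable intensity scale); `median` equalizes the per-cell median
  of nonzero values; `pqn` divides by the median quotient against the
  cohort-median reference profile, computed over features nonzero in
  the reference (exact on proportional data).
* Log and standardization: `log(x + 1)` (base e/2/10 selectable,
  pseudo-count 1 keeps zeros at zero), optional per-batch median
  centering of each feature on the log scale, then per-feature z-score
  across cells. A feature whose log values are numerically constant
  (sd at rounding level) is set to zero rather than divided by ~0.
* Batch centering is deliberately the simplest defensible batch-effect
  treatment (median shift on the log scale ≙ multiplicative per-batch
  factor); no empirical-Bayes correction is attempted.

Layer bookkeeping: raw → denoised → normalized → log → standardized.
Stages may be skipped but never reversed; violations raise `LayerError`.

### Annotation

Features are matched against `monoisotopic_mass + adduct shift` within a
ppm tolerance (default 10 ppm, singly charged ions). Adduct shifts are
derived from IUPAC monoisotopic element masses minus/plus the electron
mass (`[M+H]+` = +1.007276 Da, `[M+Na]+` = +22.989218 Da, `[M+K]+` =
+38.963158 Da, `[M−H]−` = −1.007276 Da). Lookup is a binary search over
the sorted theoretical masses and is property-tested against an
exhaustive scan of all (record, adduct) pairs. All hits within tolerance
are reported, ranked by |ppm error| — never auto-resolved. The bundled
25-record table is a small curated list of central-carbon metabolites
whose masses are computed from their formulas; any TSV with columns
`id, name, formula, monoisotopic_mass` (e.g. an HMDB export) works.

### Downstream statistics

Differential testing uses Welch's two-sample t-test per feature on the
log layer (pre-standardization, so fold changes are interpretable), with
Benjamini–Hochberg adjustment across features; log2 fold change is the
difference of group means converted to base 2 using the matrix's stored
log base. The test choice is a default, not a claim of optimality.
Embeddings (PCA, kernel-PCA, t-SNE, UMAP) require the standardized
layer; stochastic methods are seeded and reproducible. Heat-map data
selects the top-k features by variance and orders cells and features by
average-linkage Euclidean hierarchical clustering.

## Synthetic study conditions

The generator's defaults define the validation conditions:

| parameter | default | note |
|---|---|---|
| scans / spacing | 3000 × 0.2 s | 10 min run |
| cells | 50, apexes in [100 s, 500 s] | rejection-sampled, ≥ 4·pulse_sigma apart |
| pulse shape | Gaussian, σ = 1.5 scans | closed-form integral for oracles |
| background | 8 bins, 40–150 counts/scan (Σ ≈ 625) | Poisson per scan; 445.1200 Th doubles as lock mass |
| chemical noise | 5 peaks/scan, Exp(100), uniform m/z in [60, 600] | right-skewed TIC noise |
| cell types | 2 × 12 metabolites, 6 shared | amplitudes 1800–3200 counts/scan at apex |
| amplitude scatter | lognormal σ 0.3 per metabolite, 0.25 per cell | mean-preserving |
| m/z jitter | N(0, 0.001 Th) per centroid | ppm-level, Orbitrap-like |

Cell TIC transients are then ~50–90× the background TIC noise scale, the
regime in which transient-based single-cell MS operates. What the
generator does **not** model — isotope envelopes, charge states,
saturation, peak asymmetry, retention-dependent matrix effects — bounds
what passing tests show: they validate the processing arithmetic and its
statistical behaviour, not instrument physics.

Ground truth records every apex, span, per-metabolite emitted integrated
intensity, background level and the injected drift, enabling
recall/precision scoring (greedy one-to-one matching by span overlap)
and entrywise recovery errors.

## Numerical choices and degenerate inputs

* Intensities are double precision throughout; no integerization.
* Retention times are seconds (mzML minute units converted on read).
* Consolidation ties: exact duplicate m/z within one scan are merged by
  summing before spectra are built, keeping m/z strictly increasing.
* σ floor: smallest positive |TIC − baseline|, or 1.0 if the trace is
  exactly constant.
* Zero-noise bins with zero floor: entries are kept and nothing is
  subtracted (a positive signal over no background is valid evidence).
* Empty noise windows fall back to run-wide per-bin medians with a
  logged warning.
* All-zero cells are dropped at normalization with a warning; an
  all-zero cohort is an error.
* Replay: every stage is deterministic, so replaying a params log
  reproduces the matrix bit for bit; the contract allows 1e-9 float
  tolerance should a stochastic stage ever be added.

## Limitations

* The rolling-median baseline biases upward where transients occupy a
  substantial fraction of a window (at the default density the bias is
  conservative — it raises the S/N bar rather than inventing peaks —
  and background *recovery* within 5 % holds only at low occupancy or
  wider windows).
* Single-linkage consolidation can chain features through dense noise;
  raising the resolution never increases the bin count, but the
  occurrence filter is the real guard.
* Detection at 3× S/N admits occasional background crossings
  (~1–3 per 3000 scans before the persistence condition; near zero
  after); survivors are removed by the cell-feature filter.
* Vendor RAW/WIFF files are not read; convert to mzML or register a
  reader plugin for the extension (`scmpipe.msio.register_reader`).
* No isotope/adduct collapsing of features, no MS/MS evidence, no
  retention-time prediction in annotation.
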