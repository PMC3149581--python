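# Methods

## Model and assumptions

The pipeline treats a high-resolution LC-MS experiment as a cloud of
centroid observations *(sample, scan, rt, m/z, intensity)* in which the
*m/z* coordinate of a true ion is stable to a few ppm across scans and
samples, while intensity and retention time are not. Under that
assumption, clustering pooled *m/z* values is simultaneously peak picking
and cross-sample alignment, and retention-time alignment is deliberately
absent: per-sample chromatograms are extracted on each sample's own scan
grid, and no warping or matching in the time dimension is ever performed.
The assumption holds for orbitrap-class instruments with stable
calibration; it fails for drifting calibration or for *m/z* regions dense
enough that distinct ions sit within the closeness tolerance (true
isobars are inherently merged and must be separated chromatographically
upstream, or not at all).

## Pipeline parameters

| parameter | default | unit | meaning |
|---|---|---|---|
| `top_fraction` | 0.01 | — | per-sample fraction of points collected, by count |
| `closeness_ppm` | 5 | ppm | adjacent-gap threshold for single-linkage grouping |
| `eic_tol_ppm` | 5 | ppm | half-width of the extracted-chromatogram window |
| `sn_cutoff` | 3 | — | S/N multiple a smoothed scan must exceed to count as peak |
| `gaussian_sigma_scans` | 3 | scans | smoothing kernel width |
| `min_region_scans` | 3 | scans | shortest accepted peak region |
| `stretch_fraction` | 0.8 | — | above-threshold fraction that flags "stretched" |
| `annotation_tol_ppm` | 5 | ppm | database-match window, default adduct [M+H]+ |

The first three defaults are the method's canonical settings. The
quantification constants (noise estimator, cutoff, kernel width, minimum
region length, stretch fraction) are conventional chromatography choices
made here because the selection rule behind an "S/N-gated peak area" is
otherwise underdetermined; all are exposed in `PipelineConfig`.

## Definitions pinned for reproducibility

Several small conventions materially affect results and are fixed:

- **Collection is by count, per sample.** `k = ceil(top_fraction · N)`
  points are kept; ties at the threshold intensity are all retained, so
  the result is order-independent (and may slightly exceed *k*).
  Scaling one sample's intensities by any positive constant leaves its
  selection unchanged.
- **Gap denominator** in the ppm predicate is the lower *m/z* of the
  adjacent pair. At ≤5 ppm the difference from using the mean is
  negligible, but it must be fixed.
- **Median with even counts** is the mean of the two central values.
- **Window ends are inclusive** on both sides; half-open windows would
  drop boundary centroids nondeterministically under float rounding.
- **Variance explained** is computed against the global mean: with μ the
  mean of all intensities, the top set's share is
  `Σ_top (x−μ)² / Σ_all (x−μ)²`. A constant vector returns 100 by
  convention, with a warning.
- **Smoothing never rescales quantities.** Peak regions are found on the
  Gaussian-filtered trace (kernel truncated at ±4σ, renormalized to unit
  mass including at the edges), but both reported quantities sum *raw*
  intensities, so `sn_area ≤ eic_sum` identically.
- **Noise estimate** is `1.4826 · MAD`. When the MAD is zero (a majority
  of identical scans, typically a zero baseline) the estimator falls back
  to the smallest positive intensity as a quantization-floor proxy —
  unless that value *is* the trace maximum (an isolated spike or a
  constant trace carries no baseline information), in which case the
  noise level defaults to 1.0.

## Synthetic data: what it emulates, and what it does not

`simdata` generates centroid runs with known ground truth: each compound
contributes a Gaussian elution profile (one or two apices; two apices
reproduce the real phenomenon of a single authentic compound eluting
twice) whose observations carry multiplicative Gaussian *m/z* jitter in
ppm, over a noise floor that is uniform in *m/z* across the instrument
range [70, 1500] and exponential in intensity. The default scenario —
20 compounds pairwise separated by >20 ppm, 1 ppm jitter, σ(rt) 0.25 min,
apices 10⁵–10⁶ counts, 1000 scans over 45 min, 900 noise points per scan
at scale 50 — reproduces the regime of real orbitrap data in which ~99 %
of points are noise-like by count and the top 1 % of points carries
>95 % of intensity variance.

One structural property of real data is *not* reproduced: real detected
ions persist across many scans, so the top 1 % of a real run clusters
into a few hundred groups. Uniform synthetic noise instead scatters, so
the collected set (which by count is mostly bright noise tails) adds many
singleton groups around the 20 compound groups. Recovery is therefore
measured by matching: exactly one group within the closeness window of
each true *m/z*, median within 1 ppm, S/N-gated area within 5 % of the
injected ion count. Passing these tests demonstrates the pooling,
grouping, extraction and quantification machinery; it does not
demonstrate robustness to correlated noise, isotope envelopes, adducts or
calibration drift, none of which are generated.

The generator is seeded everywhere and touches no global random state;
the same scenario and seed give bit-identical runs and byte-identical
mzML files.

## Numerical and design choices

- Grouping is implemented as sorted adjacent-gap splitting; a test oracle
  verifies it equals connected components of the all-pairs ppm graph on
  random instances.
- Chromatogram extraction uses one *m/z*-sorted index per run shared
  across windows, so profiling thousands of groups stays O(log N) per
  window.
- The mass calculus uses a packaged atomic-mass table (H, C, N, O, S, P,
  Na, K, Cl, F; IUPAC/CODATA monoisotopic values) and charge-aware adduct
  deltas ([M+H]+ adds 1.00727646 Da, the proton mass, not the hydrogen
  atom mass). "Closest tool" in the accuracy comparison means *strictly*
  smallest |ppm|; ties award no tool. m/z values are printed to 5
  decimals and ppm errors to 2.
- A known limit of the packaged reference comparison: its observed *m/z*
  values are quantized at 5 decimals, which caps the precision at which
  any ppm error can be recomputed from them at roughly 0.02–0.05 ppm;
  the acceptance test for the error columns therefore asserts agreement
  within exactly that propagated bound.
- mzML reading is a small lxml-based parser covering the subset consumed
  here (MS1 centroid spectra, 32/64-bit float arrays, zlib or raw);
  profile-mode spectra are a hard error by design, and retention times
  are normalized to minutes whatever the file's unit. The writer emits
  schema-conformant centroid mzML (64-bit, zlib) that round-trips through
  the reader and is readable by independent mzML tooling.

## Known limitations

- No isotope-pattern handling: a compound's ¹³C satellites appear as
  separate groups.
- True isobars and chained calibration drift merge into single groups;
  the closeness sweep (`sweep_closeness`) is the diagnostic.
- Reliability flagging is a heuristic stand-in for expert review of
  chromatogram quality; its two rules (stretched signal, noisy baseline
  without a qualifying peak) are intentionally simple and conservative.
- Quantities are not normalized across samples; cross-sample comparison
  of absolute areas assumes comparable injection and ionization.
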