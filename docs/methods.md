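# Methods

`focigap` implements the quantitative analysis chain for two kinds of
single-molecule fluorescence experiments on bacterial DNA replication:
(i) two-color focus imaging in live cells (replisome markers vs a repair
protein such as RecF), and (ii) flow-stretched rolling-circle DNA stained
for dsDNA, in which single-stranded gaps appear as dark runs.  Every
stage is paired with a synthetic-data generator that plants known ground
truth, so each estimator can be validated by recovery rather than by eye.

## Coordinate and unit conventions

All pixel coordinates are 0-based with the center of pixel `(0, 0)` at
coordinate `(0.0, 0.0)`; `x` runs along columns.  The generator samples
PSFs at pixel centers under the same convention the fitter assumes, so
localization tests are meaningful at the 0.01-px level.  Physical
thresholds are stored in nanometres and converted through the pixel size:
the classification distance is a physical quantity (218 nm), not a pixel
count, because the two imaging regimes use different pixel sizes
(109 nm/px in cells, 160 nm/px in vitro).  ImageJ ROI files store
integer, corner-based coordinates; the reader/writer applies the
half-pixel shift and documents that fractional vertices only survive the
CSV route.

## Synthetic scenes

Cells are spherocylinders placed without overlap by rejection sampling;
lengths are uniform in 2–4 µm, width 1 µm, matching exponentially growing
E. coli.  Focus counts per cell and channel are Poisson with default
means 1.7 (channel A, replisome-like) and 0.66 (channel B, RecF-like) —
the per-cell focus numbers typical of such strains.  A planted fraction
(default 0.4) of B foci is placed at an A position plus isotropic
Gaussian jitter (50 nm SD, a realistic two-color localization scatter);
the rest are uniform within their cell.  Rendering sums isotropic
Gaussian PSFs (sigma 1.0 px) with a per-focus photon budget (default
2000), adds background photons inside cells (100/px), applies Poisson
shot noise, multiplies by the EM gain (30) and adds Gaussian read noise
(10 counts).  EMCCD excess noise is *not* modelled: the gain is a pure
multiplier, which is sufficient for testing detection and statistics and
is a documented limitation.  The inter-channel offset is a constant
translation applied at render time only, so truth stays in the channel-A
frame and offset estimation can be tested against it.

A second mode (`mode="surface"`) scatters foci uniformly over the whole
field with uniform background — the in vitro slide/flow-cell regime.  A
`shot_noise` switch permits fully noiseless renders for localization
floor tests.

What the generator does not emulate: fluorophore maturation and
photobleaching kinetics, 3-D PSFs, cell-cycle structure, spectral
bleed-through, and non-uniform illumination beyond what `flatten`
removes.  Passing recovery tests therefore demonstrate correctness of
the estimators under the stated noise model, not robustness to every
artefact of real microscopy.

## Focus detection

`flatten` subtracts a grey-scale morphological opening (disk radius 15 px,
several spot diameters) and clips at zero; it is approximately idempotent
and preserves spot amplitude on smooth gradients to within a few percent.
The discoidal averaging filter is a difference of means — inner disk of
radius 1 (inclusive Euclidean pixel-center distance) minus the annulus out
to radius 4 in cells (radius 3 for the in vitro settings) — with
reflection padding; the kernel sums to zero, making the response invariant
to constant offsets.  The exact kernel of the original Fiji plugin is not
published; this difference-of-means definition is normative for this
package and is validated against a brute-force double-loop oracle.

Thresholding uses the Yen criterion on a 256-bin histogram of the
filtered image.  Pure Yen has no notion of "nothing is there": on a
blank noise field it lands inside the noise distribution.  The effective
peak threshold is therefore `max(yen, 5 * robust_sigma)` where
`robust_sigma` is the MAD-based scale of the filtered image — the classic
n-sigma spot-detection floor (disable with `noise_floor_nsigma=0`, or
override with an absolute threshold, the equivalent of the manually "set
threshold" used in practice for in-cell data, where the filter also
responds to cell boundaries).

Candidate maxima must be pairwise at least `min_separation_px` (default
3 px) apart; higher filtered intensity wins, remaining ties break
row-major.  Sub-pixel refinement fits an isotropic 2-D Gaussian with free
offset by least squares inside a 9×9 window (4-px fit radius, the
published in vitro settings); non-convergent fits fall back to an
intensity-weighted centroid and are flagged, as are foci whose window is
truncated by the image border.  The fit is single-emitter: pairs closer
than the separation floor are merged by design, and localization accuracy
is specified for isolated emitters (no neighbour inside the fit window).
Measured on surface-mode scenes: recall and precision > 0.99 at peak
SNR ≈ 7, localization RMSE ≈ 0.14 px with noise and ≈ 1e-4 px noiseless.

Particle analysis (extended features rather than spots) labels
8-connected components of the thresholded mask, discards areas < 3 px²,
and measures mean intensity on the original flattened image.

## Colocalization statistics

A focus is colocalized when its nearest neighbour in the other channel
lies within 218 nm (2 px at 109 nm/px).  Classification is per focus, not
a one-to-one matching: the frequency in each direction is the fraction of
that channel's foci with at least one partner, which stays well defined
when channel counts differ.  Frequencies on an empty channel are reported
as missing (NaN), never as zero.  The inter-channel offset is estimated
as the modal bin (0.25-px bins) of all pairwise displacement vectors
within a search radius, refined by the in-bin mean — exact for a rigid
shift and robust to unrelated pairs.

The coincidental colocalization level is `C = A_R * n / A_ref` with
`A_R = pi * r^2` (r defaulting to the classification distance).  Two
choices deserve comment:

* **Reference area.**  For surface assays the foci occupy the whole
  field and `A_ref` is the FOV area.  For in-cell imaging the foci are
  confined to cells, and the relevant CSR null is uniform placement
  *within cells*; `full_report` therefore accepts a `reference_area_px2`
  (total cell area).  At the default densities this puts the chance
  level near 9% — the familiar ~10% of two-color controls.
* **Which n.**  The printed convention counts foci of both channels and
  is reported as `chance_C`.  For correcting a *directional* frequency,
  the partner-channel count is the statistically consistent choice (the
  probability that one focus of channel B coincidentally meets an A
  focus involves only the A density); using the pooled count would
  overcorrect by roughly a factor of two at equal densities.  The report
  carries both, and `corrected_frequency = (f - C)/(1 - C)` (clipped to
  [0, 1]) uses the per-direction values by default.  With this choice the
  planted fractions 0, 0.2, 0.5 and 0.8 are recovered to within ±0.02 at
  default densities; residual bias comes from cell-edge geometry (a
  focus near the cell pole has fewer possible partners than the uniform
  formula assumes).

Distance histograms are binned by equal-area shells, `r_k =
r_max * sqrt(k/K)`: annuli of equal area remove the geometric growth of
sampled area with radius, so CSR gives flat counts.  Conventions: a
distance of exactly 0 falls in shell 1, exactly `r_max` in shell K;
larger distances are excluded and counted.

## Gap calling and gaps per µm

Profiles are median-smoothed (window 3 px).  The threshold is relative to
the molecule's own dsDNA level, estimated robustly in one re-weighting
pass: global median → provisional gaps → median of the remaining stained
pixels; the default threshold fraction is 0.5.  No numeric rule is
published for this step; the relative-with-reweighting scheme is this
package's choice because it is invariant to stain and illumination
variation between molecules, and an absolute override is provided.  A gap
is a maximal run of at least `min_gap_px = 2` sub-threshold pixels
(0.32 µm at 0.16 µm/px — the documented detection floor) not touching
either molecule end, since a dark end is indistinguishable from the
terminus.  Fully dark molecules are flagged unstained and excluded from
rate denominators.

The headline statistic, gaps per µm of synthesized DNA, is the pooled
ratio of total calls to total analyzed length (the mean of per-molecule
rates is reported alongside; the pooled ratio weights molecules by
length and is the default).  Uncertainty is a molecule-level bootstrap
(1000 resamples, seeded).  Rate-recovery studies compare the estimate
with the planted rate of *callable* gaps (at least `min_gap_px` pixel
centers, away from ends); at 5000 µm total length the estimate agrees
with that reference within two bootstrap SEs for rates from 0.02 to
0.2 per µm.  Note that a higher threshold fraction does not always
increase the number of calls — two gaps can merge across a dim
separator — but the *set of gap pixels* is monotone in the threshold.

## Per-cell statistics and assay formulas

Foci are assigned to the cell polygon containing their centroid
(boundary inclusive).  Overlapping outlines are resolved deterministically
by input order and flagged — real analyses exclude overlapping cells
upstream, so this is a guard path.  Per-cell summaries report mean ± SEM
over cells.  The assay formulas (dead-cell percentage, OD-normalized SOS
reporter signal, Tet recombination frequency with explicit per-plate
dilutions, plasmid-loss fraction with an exact Clopper–Pearson interval,
dot-blot background subtraction floored at zero) are exact arithmetic on
their inputs.

## Determinism and problem sizes

Every random step flows from a single seeded `numpy` generator per
config; identical configs give bit-identical images, tables and summary
files (ROI zip archives carry fixed timestamps for this reason).  The
bundled studies use problem sizes chosen to make the statistical
tolerances meaningful on a single CPU within minutes: 100 fields per
planted fraction for colocalization recovery, 50 noisy + 10 noiseless
fields for detection, 1e5 Monte-Carlo replicates for the chance formula,
200 replicates for shell uniformity, and ~5000 µm of DNA per gap rate.

## Known limitations

* EM-register excess noise and camera pixel non-uniformity are not
  modelled; SNR statements refer to the shot + read noise model.
* The Gaussian fit does not deblend overlapping emitters; below the
  separation floor, pairs are reported as one focus.
* Gap calling consumes already-extracted 1-D profiles; tracing curved
  molecules through 2-D images is limited to fixed-row extraction.
* The chance-colocalization formula is first-order in density; at chance
  levels approaching 1 the corrected frequency is reported as undefined.
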