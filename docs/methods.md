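# Methods

## Scope and model

The package models an endpoint digital PCR platform whose partitions are a
fixed rectangular grid of molded microwells rather than droplets. Target
molecules distribute into partitions independently, so the per-partition
copy count is Poisson with mean λ = C·v (C concentration in copies/µL, v
partition volume in µL). A partition with ≥ 1 copy amplifies to a saturated
endpoint signal; amplification efficiency below 100% per copy is out of
scope. The concentration estimator inverts the observed positive fraction
p̂ = k/n through λ̂ = −ln(1 − p̂). For p̂ ≤ 0.01 this agrees with the naive
count k/(n·v) to within 1%; at higher loads the inversion corrects for
multiple occupancy. A fully positive array (k = n) has no finite estimate
and raises a saturation error with a dilute-and-rerun message.

## Confidence intervals

k is Binomial(n, 1 − e^{−λ}) under the model, so intervals on p map
monotonically to intervals on concentration. We use exact Clopper–Pearson
endpoints (beta-quantile form, via `scipy.stats.beta`) by default: clinical
reporting favours conservative coverage, and conservativeness is exact at
every n and p. The k = 0 upper endpoint is p_u = 1 − (α/2)^{1/n}, i.e.
λ_u = −ln(α/2)/n, giving 0.357 copies/µL at n = 20,000 and v = 517.01 pL —
the bound attached to "true zero" timepoints in serial monitoring. The test
suite verifies coverage ≥ 95% by exact enumeration over the binomial pmf at
λ ∈ {0.01, 0.1, 0.5, 1, 2} rather than by simulation, and cross-checks the
endpoints against an independent implementation (statsmodels
`proportion_confint(method="beta")`).

Allele fractions are target:reference concentration ratios × 100 (not
target/(target+reference)); the fraction CI maps the target's binomial CI
through the ratio with the reference held at its point estimate, justified
because reference counts exceed target counts by 10³–10⁴ in the intended
use. Replicates sharing a partition volume are merged by pooling k and n —
equivalent to one larger array — and the per-replicate coefficient of
variation is reported alongside.

## Geometry arithmetic

Partition volume is the exact product x·y·z (µm³ → pL via 10³ µm³/pL):
65 × 82 × 97 µm gives 517.01 pL, and 20,000 wells give 10.34 µL. Worst-case
volume variation under dimensional tolerances grows/shrinks each dimension
by its full tolerance and takes the larger relative deviation of the
product; ±0.1 µm planar and ±1.0 µm height on the nominal well give +1.3098%
/ −1.3037%, reported as 1.31%. This is a first-principles propagation; the
consumable's stated ±1.5% is treated as an upper bound that the computation
satisfies, and the gap is left unexplained rather than tuned away.

Subsampling of a fixed input of m copies analyzed with fraction f is modeled
as binomial thinning: detected ~ Binomial(m, f), CV = √((1−f)/(m·f)). This
is the simplest model consistent with a fixed pre-partitioning copy number;
a Poisson-distributed input would add the Poisson CV in quadrature and is
not the default. The minimal detectable fraction uses the convention that
the expected number of target copies in the analyzed volume must reach
k_min = 3 (configurable); no universally accepted dPCR LoD rule exists, and
3 expected positives is a common working criterion.

## Synthetic data generator

The generator emulates the imaging output of the integrated instrument, not
its optics. Defaults are the platform's stated operating point: 20,000 wells
(100 × 200 grid; the physical arrangement is a package convention) of
517.01 pL at 91/107 µm pitch, 2% fill failure, a FAM target at 1006
copies/µL (λ ≈ 0.520) over an empty HEX channel, a 20% radial vignette,
16-bit images at 10 µm/pixel with a 20 px margin. Per image, filled wells
render as 7 × 9 px rectangular patches: ROX at its loaded level pre and
post; probe channels at the negative level pre and at the positive level
post only where the truth holds ≥ 1 copy. The whole frame is multiplied by
the illumination field (flat, planar gradient ±a, or radial vignette falling
to 1 − a at the corners), then i.i.d. Gaussian pixel noise is added and
values are clipped and quantized. Class separation is enforced at
construction (positive mean > negative mean + 6 noise sd), matching a
well-optimized assay.

Occupancy and rendering draw from independent seed streams, so a truth can
be re-rendered under different imaging settings; everything is bit-identical
given (seed, config). What the generator deliberately omits: point-spread
blur, photon-shot (signal-dependent) noise, well-edge artifacts, partial
amplification ("rain"), spectral crosstalk between dyes, and real-instrument
vignetting calibration. Passing tests therefore demonstrate that the
pipeline is correct under an idealized but fully controlled imaging model —
they do not certify performance on real instrument images, where threshold
placement and QC would face rain and crosstalk this model excludes.

## Image analysis

Grid location cross-correlates the ROX post image with the ideal binary well
template over all integer translations via FFT; the normalized peak must
exceed 0.1 (a blank or gridless image fails loudly), and the offset is
quantized to whole pixels so patch windows align exactly with the pixel
raster (a sub-pixel refinement is kept as a diagnostic). The ROX *post*
image anchors both grid location and QC; pre would serve equally in this
model, and the choice is a convention.

Illumination is estimated by fitting a degree-2 bivariate polynomial to the
per-partition ROX trimmed means of loaded partitions, normalized to unit
mean over partition centres; degree 2 exactly captures the generator's
planar and radial fields and tracks smooth real-world vignetting. Loaded
partitions are selected by a two-class intensity split: Otsu initialization
refined by isodata iteration (threshold → midpoint of class means), which is
robust to the 50:1 class imbalance a 2% fill-failure rate produces — plain
Otsu mis-places the threshold when the empty class is a few wells. The split
counts as bimodal only if the class means are ≥ 4× the summed within-class
spreads apart; otherwise QC falls back to 5× the off-patch image background
(all-loaded arrays reject nothing; all-empty arrays already fail grid
location).

Patch intensities are central-80% trimmed means (robust to edge bleed; the
plain mean is a parameter), divided by the fitted field at the patch centre;
the analysis statistic is delta = corrected post − corrected pre, a
per-partition background subtraction. Positivity thresholds come from a
no-template control: mean + 5 sd of the QC-passing NTC deltas per channel.
Five sd keeps the expected false-positive count per 20,000 partitions ≪ 1
under Gaussian noise while remaining far below the positive-class delta; an
NTC partition above mean + 10 sd triggers a contamination warning. A
partition is called positive iff it passes ROX QC and its delta exceeds the
threshold; rejected partitions are excluded from numerator and denominator
alike, since they hold no analyzable reagent.

## Problem sizes and numerical choices

Unit and invariant tests run on a 500-well (20 × 25) array with the same
well physics, which exercises every code path in seconds; full-scale
20,000-well arrays are used where the claim concerns the operating point:
estimator calibration (200 occupancy simulations at λ = 0.5), end-to-end
image-pipeline recovery (10 arrays in the test suite, 3 in the acceptance
script), cross-channel specificity, rare-target detection (20 arrays at a
1:10,000 fraction), and serial monitoring. Statistical studies that do not
exercise the imaging stage use the occupancy generator directly through an
idealized caller (`partition_table_from_truth`); studies of detection and
specificity run the full image pipeline. The serial-monitoring and
calibration studies simulate with zero fill failure so the quantification
claims attach to exactly n = 20,000 valid partitions.

The end-to-end recovery check asserts zero discordant partition calls on
every simulated array and asserts CI recovery on the replicate-pooled
estimate (a single nominal-95% event) rather than demanding that ten
independent 95% intervals all cover — a conjunction that would fail about a
third of the time by construction even for a perfect estimator.

## Known limitations

Real-image ingestion is limited to the package's own TIFF/CSV conventions;
there is no droplet-image support, no rotation or scale estimation in grid
location (molded arrays are mechanically registered; only translation is
searched), no rain/crosstalk handling in thresholding, and no
international-scale conversion for fusion-transcript reporting. The ratio
CI ignores reference-count uncertainty by design; for targets and references
of comparable abundance it understates the interval.
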