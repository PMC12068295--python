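# Methods

## The assay and its statistics

The toolkit assay reads anti-apoptotic dependencies on *living* cells:
instead of permeabilizing cells and measuring cytochrome-c release against
BH3 peptides, intact cells are exposed for 4 h to specific BH3 mimetics and
early apoptosis is read as Annexin V single-positivity. Because late
apoptotic/dead events (any 7AAD⁺) can arise from causes other than the
mimetic — membrane damage, thawing stress — only the Annexin V⁺/7AAD⁻
fraction is counted, and every treated condition is referenced to its
vehicle control:

    ∆AnnexinV(drug, dose) = %early(treated) − %early(vehicle)   [pp]

Dependency scores normalize the 1 µM ∆ of a sample to the matched
internal-control line acquired in the same run:

    score_target = 100 · ∆_sample(1 µM) / ∆_control(1 µM)

so a sample responding like the control scores 100. The MCL-1 control
(JJN3, ∆ ≈ 55 pp) responds far less than OCI-Ly1 or HEL; to keep the three
radar axes comparable the MCL-1 denominator is replaced by a fixed weight
(default 30). Both variants are implemented — "B" (fixed weight, default)
and "A" (plain control ratio) — and the variant plus weight are stamped into
every profile, since the exact published weighting convention is ambiguous.
Negative sample ∆ values clip to score 0 (a radar axis cannot be negative);
dynamic-shift tables keep their sign. Navitoclax, a BCL-2/BCL-XL/BCL-W
pan-inhibitor, is annotated as an overall-priming proxy and never scored.

Dynamic profiling adds a 20 h pre-treatment (vehicle vs drug of interest)
before the 4 h toolkit; the readout is the per-(drug, dose) shift
∆(pre-treated) − ∆(vehicle), which may be negative.

## Gating model

Classification order per event: (1) bead if the bead channel exceeds the
bead gate (counting beads are bright in every fluorescence channel);
(2) debris if outside the scatter gate; (3) dead if 7AAD > threshold,
regardless of Annexin V; (4) early-apoptotic if Annexin V > threshold;
(5) alive otherwise. Ties (value exactly at a threshold) are negative, which
makes classification deterministic across platforms. Fractions are reported
over the intact-cell denominator (alive + early + dead) by default;
`denominator="live_plus_early"` excludes dead cells for users who prefer the
living-cells convention. The choice changes %early by the dead fraction, so
it is a config field recorded with results rather than a silent default.

Fluorescence is transformed as arcsinh(x/150) (cofactor configurable;
`log10`/`none` available — note `log10` uses log10(1 + x/c) and is not
invertible for negative raw values). Scatter stays linear.

**Automatic thresholds.** With `threshold_source="quantile_from_vehicle"`,
the Annexin V and 7AAD cutoffs are derived from pooled, scatter-gated,
bead-excluded vehicle events. The default estimator is the q = 0.995
quantile of the *negative mode*, computed robustly as
median + z_q·1.4826·MAD. A plain empirical quantile (`robust=False`) is
provided but not the default: real vehicle wells always carry a baseline
apoptotic subpopulation (≈5–10% after thawing), and the empirical 0.995
quantile of such a mixture lands inside the positive cluster, destroying the
∆ statistic. The robust form reduces to the same answer on clean negatives
(constant input → that constant; q = 0.5 → the median) while tolerating
contamination. By construction ~(1−q) of true negatives sit above each
cutoff; this small, dose-independent misclassification largely cancels in ∆.

The debris gate defaults to explicit FSC bounds (lower bound 20,000 on the
generator's scatter scale, matching a conventional lymphocyte gate). If the
bounds are left unset, `fit_thresholds` falls back to excluding the lowest
2% of vehicle FSC — a blunt rule that misassigns debris whenever the true
debris load differs from 2%, hence not the default.

## Synthetic data generator

Each well is a mixture over five classes. Per class, fluorescence is
Gaussian in arcsinh space (location/spread per channel; negatives at 0.8,
positives at 4.5, beads at 7.5, SD 0.35 by default — roughly two decades of
separation, as on a well-compensated conventional cytometer) and scatter is
truncated-Gaussian in linear units. Every event keeps its class as a hidden
label; labels are written only to CSV sidecars, never into FCS files.

The early-apoptotic fraction follows either explicit per-dose values on the
{0, 10, 100, 1000} nM grid (the default, since published responses are
per-dose) or a Hill curve (baseline + ∆max·d^h/(EC50^h + d^h)). On the plate
acquired 24 h after the first, a per-sample `progression_rate` (default 0.8)
moves early-apoptotic cells to dead, and `attrition_24h` scales the total
cell number (untreated thawed cells decline slowly, ≈0.84 over 24 h in the
motivating data; default 1.0). Nuisance variability acts on the *induced*
response in percentage points: between-replicate SD, a batch-level shift
keyed on plate id, and an additive fresh/frozen offset applied to frozen
material. Fractions pushed outside [0, 1] are clipped with a logged warning.

Counting beads are Poisson-sampled with mean `beads_added × f`, where f is
the same acquisition fraction applied to cells — the property that makes
`n_class · beads_added / beads_observed` an unbiased estimate of absolute
per-well counts. Default 20,000 non-bead events per well mirrors the seeding
density of 20,000 cells/well (acquisition settings are not part of the
published protocol); default beads_added is the bead-lot concentration × the
5 µL spike, and the lot concentration has **no default** — it must be given.

What the generator does *not* emulate: spectral spillover/compensation,
doublets, acquisition-time drift, debris heterogeneity, or correlations
between channels within a class. Passing recovery tests therefore shows the
*analysis* is correct and unbiased under idealized optics, not that gating
is robust to compensation artifacts on a particular instrument.

Determinism: every well's RNG is derived from
SeedSequence([seed, crc32(plate:well)]), so identical inputs give
bit-identical event tables and byte-identical CSV output, independent of
well order.

## Statistics

Replicate tables crossed by condition × dose are fit with a two-way
fixed-effects ANOVA with interaction (type-II sums of squares; a warning is
raised on unbalanced designs). Each treated cell is contrasted against the
control condition at the same dose using the model's pooled residual
variance; p-values are Šídák-corrected over the dose contrasts within each
condition (configurable: none/sidak/holm — the published analyses name only
"two-way ANOVA", so the post-hoc correction is this package's declared
default). Stars: * ≤ 0.05, ** ≤ 0.01, *** ≤ 0.001, **** ≤ 0.0001.

Control-batch QC passes iff ≥2 vials were measured and the batch mean lies
in the closed interval reference_mean ± k·SD (k = 2 by default; boundary
passes). With ≥2 batches, inter/intra-batch SDs come from the one-way
random-effects method of moments (negative between-batch variance estimates
truncate to zero).

Renderers pin matplotlib's SVG hash salt and strip timestamps, so charts are
byte-identical across reruns; every chart emits its numbers as a CSV sidecar.

## Validation workflows and problem sizes

`bh3kit.validation` contains the package's positive controls, used by both
the test suite and `scripts/acceptance.py`: recovery of the three control
lines' 1 µM responses (3 treated/vehicle pairs, 20,000 events/well),
thaw-reproducibility SD (12 independent thaw pairs, 5.0 pp injected),
dynamic shifts (+9.9 and +32.83 pp, 3 pairs per arm), absolute-count
recovery (a 17,153-live-cell well against a clean gating companion well),
and per-event gating agreement pooled over 100 wells spanning all preset
conditions. These sizes are the assay's own (one plate row per condition,
20,000 cells seeded per well). Note the 12-thaw SD is itself a 12-sample
statistic with sampling SD ≈ 1.1 pp around 5.0 — single runs scatter
accordingly; that spread is a property of the experiment size, not of the
estimator.

Where only the 1 µM response of a control line is published, mid-dose truth
values in `presets` are plausible monotone fills chosen once; no validation
quantity depends on them. The dynamic-arm baselines (vehicle-arm ∆ of 8.0 pp
for the azacytidine experiment, 10.0 pp for ironomycin) are likewise fixed
choices consistent with the reported low-dose behavior; only the *difference*
between arms is a published quantity.

## Known limitations

- No compensation/spillover handling: inputs are assumed compensated.
- No doublet discrimination and no clustering-based auto-gating.
- The MCL-1 weighting convention is implemented in two variants because the
  exact published formula is not fully specified; outputs carry the variant.
- CTG viability assumes one dose-0 control row per (sample, pre-treatment)
  stratum; plate-position effects are not modeled.
- The FCS reader covers list-mode float data (the subset this package
  writes); integer-mode or multi-dataset FCS files from instruments are out
  of scope.
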