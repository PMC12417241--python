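# Methods

## Measurement model

A lesion's contrast on a recombined view is `CE = (Sa − Sb)/Sb` with `Sa`
the lesion-ROI maximum and `Sb` the background-ROI mean. Using the maximum
rather than the lesion mean makes the statistic independent of ROI placement
and lesion shape, at the cost of an upward noise bias (the expectation of a
maximum over n noisy pixels exceeds the noise-free peak). The two-timepoint
kinetic statistic `%RSD = 100 × (CE_late − CE_early)/CE_early` is
thresholded at ±10 % into progressive / plateau / wash-out, with the plateau
band closed on both ends. When `CE_early = 0` the ratio is undefined and the
lesion is recorded as non-enhancing (`pattern = none`) rather than given an
arbitrary kinetic value; negative CE (lesion maximum below the background
mean) is allowed and propagates, since noise can produce it. Reader
averaging operates on the derived CE values per view, not on raw Sa/Sb.

## Image phantoms

Phantoms are 16-bit early/late image pairs with a radially smoothed plateau
lesion: pixels inside the core radius sit exactly at
`sb_level · (1 + peak)`, a raised-cosine taper returns to background, and
additive Gaussian noise with scale `noise_scale · sb_level` is clipped to
[0, 65535] and quantized. The plateau profile is deliberate: it makes
noise-free recovery *exact* (the ROI maximum equals the programmed peak),
so the whole measurement chain has a zero-tolerance reference point. The
background mask excludes a dilation margin around the lesion, emulating a
reader placing the background ROI on non-enhancing fatty tissue. Defaults:
256×256 pixels, background 1000, core radius 12 px, outer radius 24 px.
Pixel convention is row-major, 0-based; masks are inclusion masks
(PNG 0/255). No dual-energy recombination physics, anatomical texture or
view-projection geometry is modeled: the phantoms validate the measurement
arithmetic, not detector physics.

The noisy-recovery tolerance is not a closed form. The reference value in
the tests comes from a brute-force simulation: noise is drawn directly over
the noise-free image, quantized identically, and max/mean are taken with
plain array operations; measured and simulated means must agree within
three combined Monte-Carlo standard errors.

## Cohort simulator

Lesions are drawn independently (no per-patient correlation; the analysis
is lesion-level) from five histology classes with prevalences matching the
reference cohort fractions (BPE 48/143, benign 34/143, B3 4/143, invasive
49/143, non-invasive 8/143). Per class:

* **CE_early** is log-normal — strictly positive and right-skewed, the
  shape seen in published scatter plots. Locations order
  BPE ≈ benign < malignant (shared σ = 0.5; benign/BPE median 0.04). The
  malignant location offset 0.6746 comes from the equal-σ log-normal
  identity `AUC = Φ(Δμ/(σ√2))`, targeting AUC 0.83 for CE_early before
  reader noise. No invasive/non-invasive or BPE/benign location difference
  is modeled, mirroring the reported non-significant contrasts.
* **%RSD** is drawn uniformly within the pattern band selected by a
  per-class mixture (benign/BPE ≈ 71 % progressive; invasive predominantly
  plateau/wash-out; non-invasive progressive), with bands (10, 60],
  [−10, 10] and [−60, −10).
* A per-class **non-enhancement** probability (benign 6/34, B3 1/2,
  invasive 1/49, non-invasive 1/8, BPE 0) produces `pattern = none`
  records.
* **Readers**: each of three readers applies one multiplicative log-normal
  factor (σ_r = 0.2) to both views. Sharing the factor across views encodes
  that a reader's dominant error source — their background-ROI choice —
  is drawn once per examination; it keeps every reader's %RSD equal to the
  lesion's true %RSD, so the recorded pattern is classified from the
  averaged measurements without boundary artifacts, while CE_early still
  carries realistic inter-reader scatter (diluting the design AUC to
  ≈ 0.82). A reader's conspicuity grade thresholds the lesion-to-BPE CE
  ratio at (1.5, 3.0) — configurable constants operationalising the verbal
  low/moderate/high scale, not published values. Enhancing lesions are
  floored at `low` (an enhancing lesion is by definition at least as
  conspicuous as BPE).

The simulator's record fields are exactly the downstream pipeline's inputs,
so generator/classifier consistency (`classify_pattern(rsd) == pattern`) is
testable on every draw. What passing simulations do **not** show: behaviour
under real recombination artifacts, BPE spatial heterogeneity, reader
errors that differ between views, or correlated multi-lesion patients.

## Deterministic count fixture

`build_paper_fixture` assembles 143 records whose histology, conspicuity
and pattern margins — and every published joint count — match the reference
study. The published joints pin most of the conspicuity × histology table;
the remaining free cells are filled by a fixed allocation table documented
in `cohort.py` (e.g. BPE low/moderate = 30/18). Pattern arithmetic forces
the rest: with malignant progressive = 17 and normal/benign progressive
= 54, the two enhancing B3 lesions must split 1 progressive / 1 plateau to
hit the progressive margin of 72. Numeric CE values are assigned
deterministically, ordered by conspicuity grade (distinct within grade via
small index offsets), and %RSD values sit strictly inside each pattern's
band. One published inconsistency is resolved in favour of the Results
counts: a Discussion figure of 56 % progressive non-invasive cancers cannot
coexist with the printed malignant plateau/wash-out total of 38; the
fixture uses 7/8 non-invasive progressive (one non-enhancing). The fixture
carries labels and synthetic CE values, not the original measurement data,
so published AUC/threshold values are deliberately out of scope for it.

## Diagnostic evaluation

AUC is the Mann–Whitney probability estimate (ties ½). Direction is
normalized so higher scores indicate malignancy; %RSD is negated
(malignancy shows lower %RSD). Candidate Youden thresholds are midpoints
between adjacent distinct scores plus ±∞; classification is
`score ≥ threshold`; J-ties resolve to the lowest qualifying threshold
(favouring sensitivity). The AUC CI is a stratified percentile bootstrap
(default 2000 resamples, seeded; degenerate all-tied resamples score 0.5).
Fagan pre-test probability defaults to the malignant prevalence of the
comparison subset; a perfectly specific test yields an infinite LR+ and a
post-test probability of 100 %. Cohort evaluation excludes non-enhancing
and B3 lesions, leaving 28 benign + 55 malignant and 48 BPE + 55 malignant
in the two comparisons of the deterministic fixture. Ordinal descriptors
enter as ranks (low < moderate < high; progressive < plateau < wash-out).

## Statistics

All tests are two-sided. Mann–Whitney uses exact enumeration when
`n_x · n_y ≤ 400` and the pooled sample is tie-free, otherwise the
tie-corrected normal approximation; Kruskal–Wallis and χ² use their
standard asymptotics (χ² without continuity correction); Kendall's W uses
the tie-corrected concordance formula and is the one statistic implemented
directly rather than delegated, since none of the installed statistical
libraries exposes it. Holm adjustment is the step-down procedure, returned
in input order. Degenerate inputs (empty samples, zero variance, constant
ratings, single-class labels, zero margins) raise typed errors rather than
returning NaN.

## Problem sizes and reproducibility

Defaults used by the test suite and acceptance script: simulated cohorts of
600–2000 lesions, 1500–2000 Monte-Carlo replicates for the phantom-bias
oracle and the type-I-error check, bootstrap sizes 250–2000, phantoms of
160×160–256×256 pixels. These sizes put Monte-Carlo standard errors well
inside the tolerances being checked while keeping a full run inexpensive.
Every stochastic path takes an explicit integer seed (NumPy
`default_rng`); identical config + seed reproduce outputs byte-for-byte,
and manifest CSVs round-trip floats exactly (shortest-repr writing,
round-trip parsing).

## Known limitations

* The phantom is a single smooth lesion on a flat background; conclusions
  about segmentation, multi-focal disease or BPE mimics are out of reach.
* The conspicuity-ratio thresholds and the CEM-vs-MRI agreement example are
  simulator conventions; only their machinery (κ, W) is validated, not
  their clinical values.
* CE is treated as a unitless ratio throughout. Published classification
  thresholds quoted on a ~100× scale (percent-style CE) must be divided by
  100 before comparison with this package's outputs.
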