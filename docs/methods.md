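# Methods

This note documents the models and conventions behind `edascreen`, the
defaults and why they were chosen, what the synthetic studies emulate,
and the known limits of both.

## Chemistry layer

Isotope masses and abundances are pinned in `edascreen/_isotopes.py`
(IUPAC/CIAAW values) so patterns and fit scores are bit-stable across
environments and library upgrades. Supported elements are C, H, N, O, S,
P, F, Cl, Br, I, Na, K plus the pure labels `D` (2H) and `[13C]`, which
model isotope-labeled internal standards as fully labeled at the
substituted positions. Monoisotopic mass is the sum of lightest-isotope
masses (for these elements the lightest isotope is also the most
abundant); average mass uses the 2021 standard atomic weights
(conventional value where IUPAC publishes an interval).

Isotopologue distributions are computed exactly: a multinomial expansion
per element, convolved across elements, with an absolute abundance floor
of 1e-16 and a size cap (20 000 terms) beyond which intermediates are
pre-merged at one tenth of the resolution bin. Final peaks are merged
within `resolution_bin` (default 0.01 Da, a QTOF-realistic centroiding
width) by abundance-weighted centroid and pruned below `prune` (default
1e-4) of the base peak. The test suite verifies the convolution against
an independent brute-force enumeration over every atom's isotope choice
for ≤12-atom molecules to 1e-9.

**Isotopic fit (mSigma-style).** The vendor formula is proprietary; we
define the score as 1000 × RMS of base-normalized intensity residuals
over the theoretical peaks, pairing each theoretical peak with the
nearest measured peak within a ppm tolerance and charging unmatched
theoretical peaks their full intensity. This matches the published
verbal definition ("relative mean square difference of a measured and
theoretical isotopic pattern"), is zero for a perfect fit, and grows
monotonically with any single residual. The familiar 25/100 thresholds
are retained as defaults *on this scale*; they may correspond to a
different constant on the vendor's scale, so users comparing against
vendor output should recalibrate the two cutoffs (`Thresholds`).

**Adducts** are singly charged ([M+H]+, [M+Na]+, [M+K]+, [M+NH4]+,
[M−H]−, [M+Cl]−, [M+HCOO]−), with shifts that include the electron mass;
m/z = M + 1.0072765 for protonation. Multiply charged species are out of
scope because the screening targets small molecules.

## Spectra

The library similarity score is 1000 × cosine on square-root-transformed
intensities over an injective greedy peak pairing (best mass agreement
first, symmetric tolerance on the pair mean). It is symmetric,
scale-invariant, bounded in [0, 1000], and cross-checked in the tests
against matchms' greedy cosine. Whether the original platform's ≥600
threshold referred to a forward, reverse, or composite score is unknown;
both the metric and the threshold are configuration. Fragment matching
first discards peaks at ≤1% of the base peak (strictly "higher than 1%"
is kept), then pairs each remaining peak with at most one candidate
fragment within 5 ppm.

MGF files go through pyteomics. MSP support is a minimal line-oriented
reader/writer of our own because the contract requires unknown headers to
survive a round-trip verbatim, which metadata-harmonizing importers do
not guarantee.

## Feature tables and inclusion filters

Retention times are seconds internally; CSV readers convert from minutes
on request, and user-facing thresholds keep the units they are
conventionally quoted in (ppm, minutes for annotation; seconds for
fractions). Replicate grouping across injections is a greedy
nearest-neighbor match within 10 ppm / 6 s — upstream software is assumed
to have aligned retention times already (the LOESS alignment step is out
of scope), so tolerance matching suffices; merged features carry a
per-injection intensity vector with zeros where a feature was missed.

The blank filter passes when the across-injection *mean* intensity is
≥3× the procedure-blank intensity (aggregation is configurable to `max`;
the original description does not say which aggregate was used). The CV
filter uses the sample (n−1) standard deviation over the *nonzero*
injections and is not evaluable with fewer than two, which is how
single-injection studies are handled. Both filters are tri-state
(pass/fail/not-evaluable) and feed the last two TAQ symbols; they do not
gate annotation.

## TAQ code and confidence levels

The six TAQ symbols are, in order: mass, RT, isotope fit, MS/MS, blank
ratio, CV. Tiers: mass 2/1/0 at ≤5/≤10 ppm; RT at ≤0.1/≤0.2 min; isotope
fit at ≤25/≤100; MS/MS 2 when recorded with a library score ≥600, 1 when
recorded without a qualifying match, 0 when not recorded; blank and CV
binary with `-` when not evaluable. The TAQ→level mapping:

| rule (first match wins)                              | level |
|------------------------------------------------------|-------|
| AL+ ∧ mass≥1 ∧ RT≥1 ∧ isotope≥1 ∧ MS/MS=2            | 1     |
| AL+ ∧ mass≥1 ∧ RT≥1 ∧ isotope≥1                      | 2b    |
| SL ∧ mass≥1 ∧ MS/MS=2                                | 2a    |
| mass≥1 ∧ isotope≥1 ∧ MS/MS∈{1,2}                     | 4\*   |
| mass≥1 ∧ isotope≥1                                   | 4     |
| otherwise                                            | 5     |

Failing RT or isotope evidence demotes a standard to the generic rules
rather than rejecting the match outright — negative evidence should
lower, not erase, an annotation. Level 3 is reachable only through
boosting (box-1 retention prediction + ≥2 matched in-silico fragments);
no direct evidence rule produces it. The mapping is enumerated in the
tests to be monotone: upgrading any single symbol never lowers the level.
Equal-level candidates for one feature are ordered by a composite
evidence score (|ppm|/10 + RTdev/0.2 + mSigma/100 − score/1000), then
lexicographically, making primary-candidate selection deterministic and
independent of list input order.

## Plates and dose-response

Fraction wells are A3–H12, numbered row-major from A3 (A3→1, …, H12→80);
the collector's actual filling order is not documented, so this is a
convention and overridable at the mapping function. The growth-assay
threshold uses the mean and sample SD of the 80 single-measurement
procedure-blank fractions; a fraction is a hit when the *mean* of its
three replicates falls below it (an all-replicates-below variant can be
composed from the returned per-replicate data). Because the triplicate
mean has SD σ/√3, the false-positive rate per fraction is ≈Φ(−3√3) ≈
1e-7 — effectively zero — while a single-replicate readout against a
known-parameter threshold fires at Φ(−3) = 0.00135, which is what the
Monte-Carlo test verifies.

Dose-response uses the standard 4PL,
`bottom + (top − bottom) / (1 + (x/IC50)^slope)`, fitted by
Levenberg–Marquardt from data-driven starts (response extremes, geometric
mid concentration, slope 1). A fit is *flagged*, never silently
defaulted, when the optimizer fails, the covariance is not finite, the
IC50 is non-positive, or its standard error exceeds the estimate —
the last catches plateau-free monotone data.

## Windows and prioritization

Fraction *i* covers [(i−1)·13.5, i·13.5] s; selection windows add a 6.5 s
margin per side (26.5 s), clipped at the run bounds (0–1080 s by
default) rather than allowed to go negative. Membership is
closed-interval, so a boundary feature belongs to both adjacent windows —
prioritization must not drop edge cases, and a compound eluting across a
fraction boundary is expected to appear under both fractions. A `t0`
offset is available because fraction collectors can run a few seconds
behind the detector; the margin is the default mitigation. Reports count
features per fraction and level, sum possible-isomer counts for 4\*/4
annotations, and flag features whose measured isotope envelope has a
non-monoisotopic base peak (≥2 Br/Cl-rich compounds), since formula
assignment from the wrong monoisotopic mass is a known failure mode for
multihalogenated compounds.

## Synthetic studies

The generator mirrors the study design: 3 technical injections × 2 ion
modes, 80 × 13.5 s fractions, a triplicate sample plate and a
single-measurement procedure blank. Unstated quantities were fixed once
at field-realistic values: background intensities lognormal
(ln-mean 11, ln-SD 1.2 counts), replicate noise multiplicative Gaussian
at 10% CV, retention times uniform over the run, plate noise Gaussian at
3% of the control response, 10% of background features blank-
contaminated, and MS/MS recorded DDA-style for the 40 most intense
features per mode. Spiked standards (defaults: three isotope-labeled
antibiotics at 130/210/370 s) get exact adduct masses ±1 ppm, low-noise
isotope envelopes, blank zero, and a plate effect of 10 noise-SD in the
fraction containing their retention time.

What passing end-to-end tests therefore show: the plumbing — filters,
matching, TAQ/level logic, hit-calling, window arithmetic, selection —
is correct under honest noise. What they do not show: robustness to
chromatographic peak-shape distortion, co-elution and ion suppression,
retention-time drift beyond the margin, isotope-envelope interference
from overlapping features, or mixture effects in the assays, none of
which are simulated.

## Problem sizes

Default test studies use ~150 background features per mode (1000 for the
noise-calibration check), 150 seeds for the plate false-positive survey,
and 1e5 simulated plates (8×10^6 responses) for the type-I-rate check —
sizes at which every statistical assertion has comfortable Monte-Carlo
headroom while the suite stays interactive.
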