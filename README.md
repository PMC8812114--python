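# edascreen

Effect-directed analysis (EDA) couples high-resolution mass spectrometry
with in vitro toxicity testing: a sample extract is separated by liquid
chromatography, the eluate is collected into 80 micro-fractions on a
96-well bioassay plate, and only the chemical features that co-elute with
bioactive fractions are prioritized for identification. `edascreen`
implements the data-processing side of that workflow for LC-HRMS suspect
screening of chemicals of emerging concern in environmental and human
samples (wastewater effluent, house dust, serum): it is aimed at
analytical chemists and toxicologists who already have aligned feature
tables and plate readouts and need a reproducible, scriptable path from
raw tables to a ranked list of candidate toxicants.

## What it computes

**Annotation.** Every feature (accurate mass *m/z*, retention time *t*R,
per-injection intensities) is matched against a hierarchy of suspect
lists — spectral libraries (SL), analyte suspect lists (AL), and in-house
standards with recorded retention times (AL+) — using mass deviation
(≤10 ppm), retention-time deviation (≤0.2 min), isotopic-pattern fit, and
a spectral-library score (0–1000, match at ≥600). The isotopic fit is an
mSigma-style score

> mSigma = 1000 · RMS(measured − theoretical relative isotopologue
> intensities),

computed from an exact per-element isotopologue convolution (0 = perfect
fit; ≤25 strict, ≤100 acceptable). Each annotation gets a six-symbol
**total annotation quality (TAQ) code** — one symbol per criterion (mass,
RT, isotope fit, MS/MS, blank ratio ≥3×, replicate CV ≤20%), each `2`
strict pass / `1` loose pass / `0` fail / `-` not evaluable — which maps
to an identification confidence level 1 > 2a > 2b > 3 > 4\* > 4 > 5
(confirmed structure → exact mass only; 4\* = molecular formula with
MS/MS recorded).

**Hit-calling.** Plate readouts are normalized to % viability (growth
assay) or % inhibition (binding assay). A growth-assay fraction is
bioactive when its mean response falls below the procedure-blank mean
minus 3× the procedure-blank SD across all 80 fractions; a binding-assay
fraction at ≥20% inhibition. Contiguous hits form active regions.

**Prioritization.** Each bioactive fraction *i* corresponds to the
chromatogram slice [(i−1)·13.5 s, i·13.5 s], widened by a 6.5 s error
margin on both sides (26.5 s selection window). Annotated features inside
the windows are ranked by confidence level and intensity. Level-4\*
candidates can be *boosted* to level 3 using externally predicted
retention times (applicability-domain boxes 1–4; box-1 candidates kept,
reduction = 1 − |box 1| / (|isomers| − |box 4|)) plus MetFrag-style
in-silico fragment matching at 5 ppm.

A synthetic-study generator (`edascreen.synth`) produces complete studies
— feature tables, suspect lists, spectra, plates, box assignments — with
known ground truth for end-to-end validation.

## Worked example

```sh
edascreen simulate   --seed 7 --out study/
edascreen annotate   --study study/ --out study/annotations.csv
edascreen hits       --plate study/plate_growth.csv --pb study/plate_growth_pb.csv \
                     --assay growth --out study/
edascreen windows    --regions study/active_regions.csv --out study/windows.csv
edascreen prioritize --annotations study/annotations.csv \
                     --windows study/windows.csv --out study/report.csv
```

The simulated study spikes three isotope-labeled antibiotics into a
background of ~150 features per ion mode. `hits` finds exactly the three
spiked fractions (mean viabilities 70.7/69.6/69.7% against a
procedure-blank threshold near 90%), `windows` converts them into 26.5 s
selection windows (e.g. fraction 10 → 115.0–141.5 s), and the report
recovers each spike by name at confidence level 2b:

```
fraction,n,...,level_2b_n,level_2b_names,...
10,14,...,1,ciprofloxacin-d8,...
16,14,...,1,azithromycin-13Cd3,...
28,6,...,1,clarithromycin-13Cd3,...
```

Level 2b is expected: the standards list carries exact mass, retention
time and isotope-fit evidence (TAQ `222122`) but no library MS/MS
spectra, so a level-1 confirmation is not reachable. The remaining `n`
per fraction are unannotated level-5 features — the candidate pool a
nontarget follow-up would dig into. Adding
`edascreen boost --study study/ --annotations study/annotations.csv --out study/boosted.csv`
upgrades the planted box-1 database candidate from 4\* to 3 (its two most
intense fragments match the in-silico list).

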