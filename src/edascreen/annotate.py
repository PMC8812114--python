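"""Hierarchical suspect annotation, TAQ codes, and confidence levels.

Every feature is matched against every suspect list in a configured
hierarchy. A match produces evidence (mass error, retention-time deviation,
isotopic fit, library MS/MS score) which is summarized in a six-symbol
total annotation quality (TAQ) code and mapped to an identification
confidence level on the Schymanski scale:

==== =======================================================
1    confirmed structure (standard: mass + RT + isotope fit + library MS/MS)
2a   probable structure by spectral-library match
2b   probable structure by diagnostic evidence (standard without MS/MS match)
3    tentative candidate (reached only by post-hoc boosting)
4*   unequivocal molecular formula, MS/MS recorded
4    unequivocal molecular formula, no MS/MS recorded
5    exact mass only
==== =======================================================

The TAQ code has one symbol per criterion in fixed order (mass, RT,
isotope fit, MS/MS, blank ratio, replicate CV), each ``2`` (strict pass),
``1`` (loose pass), ``0`` (fail) or ``-`` (not evaluable). Both the tier
boundaries and the TAQ-to-level mapping are conventions of this package,
constrained by the published criteria (10 ppm / 0.2 min / 100 mSigma / 600
MS/MS score loose; 5 ppm / 0.1 min / 25 mSigma strict), and are
table-driven so alternative mappings can be swapped in.

Level 4*/4 candidates drawn from large structure databases can be narrowed
with externally predicted retention times: candidates whose prediction
falls in applicability-domain box 1 are kept, box 4 outliers are set aside
for reconsideration, and a 4* annotation is *boosted* to level 3 when it is
in box 1 and at least two of its measured fragments match in-silico
predicted fragments.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd

from .chem import (
    ElementComposition,
    MassTolerance,
    adduct_mz,
    adduct_polarity,
    isotope_pattern,
    monoisotopic_is_base,
    msigma,
    ppm_error,
)
from .features import (
    Feature,
    FeatureTable,
    SuspectEntry,
    SuspectList,
    blank_ratio_pass,
    cv_pass,
)
from .spectra import FragmentMatchResult, spectral_match_score

__all__ = [
    "AnnotationError",
    "Thresholds",
    "MatchEvidence",
    "ConfidenceLevel",
    "LEVEL_ORDER",
    "Annotation",
    "BoxedCandidate",
    "ReductionResult",
    "match_feature",
    "taq_code",
    "assign_level",
    "annotate_table",
    "count_isomers",
    "reduce_candidates",
    "boost_level",
    "write_annotations",
    "read_boxed_candidates",
]


class AnnotationError(ValueError):
    """Invalid annotation-stage input."""


@dataclass(frozen=True)
class Thresholds:
    """Matching and quality-tier thresholds.

    Defaults are the published workflow values: annotation acceptance at
    10 ppm / 0.2 min / 100 mSigma / MS/MS score 600, strict (TAQ symbol
    '2') tiers at 5 ppm / 0.1 min / 25 mSigma, inclusion filters at 3x
    blank and 20% CV.
    """

    ppm: float = 10.0
    ppm_strict: float = 5.0
    rt_min: float = 0.2
    rt_min_strict: float = 0.1
    msigma_max: float = 100.0
    msigma_strict: float = 25.0
    msms_score: float = 600.0
    blank_ratio: float = 3.0
    max_cv: float = 20.0


@dataclass(frozen=True)
class MatchEvidence:
    """Evidence collected for one feature x suspect pairing."""

    ppm_error: float
    adduct: str
    rt_dev: float | None = None  # minutes
    msigma: float | None = None
    msms_score: float | None = None
    msms_recorded: bool = False
    blank_pass: bool | None = None
    cv_pass: bool | None = None

    def __post_init__(self) -> None:
        if self.rt_dev is not None and self.rt_dev < 0:
            raise AnnotationError("rt_dev must be non-negative")
        if self.msms_score is not None and not self.msms_recorded:
            raise AnnotationError("msms_score requires msms_recorded")


# Confidence levels, best first. '3' outranks '4*' per the scale's total
# order 1 > 2a > 2b > 3 > 4* > 4 > 5.
LEVEL_ORDER: tuple[str, ...] = ("1", "2a", "2b", "3", "4*", "4", "5")
_LEVEL_RANK = {lvl: k for k, lvl in enumerate(LEVEL_ORDER)}


class ConfidenceLevel(str):
    """Identification confidence level; compares by scale rank."""

    def __new__(cls, value: str):
        if value not in _LEVEL_RANK:
            raise AnnotationError(f"unknown confidence level {value!r}")
        return super().__new__(cls, value)

    @property
    def rank(self) -> int:
        """0 = best (level 1) .. 6 = worst (level 5)."""
        return _LEVEL_RANK[str(self)]

    def better_than(self, other: "ConfidenceLevel | str") -> bool:
        return self.rank < _LEVEL_RANK[str(other)]


@dataclass
class Annotation:
    """A feature x suspect annotation with its evidence and level."""

    feature_id: str
    ion_mode: str
    mz: float
    rt: float  # seconds
    mean_intensity: float
    suspect: str | None
    list_name: str | None
    list_class: str | None
    evidence: MatchEvidence | None
    taq: str
    level: ConfidenceLevel
    isomer_count: int = 1
    primary: bool = False
    mono_is_base: bool | None = None  # False flags polyhalogenated risk

    def __post_init__(self) -> None:
        if self.isomer_count < 1:
            raise AnnotationError("isomer_count must be >= 1")


@dataclass(frozen=True)
class BoxedCandidate:
    """A candidate structure with its retention-prediction reliability box.

    ``box`` is 1-4 (1/2 = predicted RT consistent with measurement, 4 =
    applicability-domain outlier) or ``None`` when the external platform
    returned no prediction.
    """

    name: str
    predicted_rt: float | None = None  # seconds
    box: int | None = None

    def __post_init__(self) -> None:
        if self.box is not None and self.box not in (1, 2, 3, 4):
            raise AnnotationError(f"box must be 1-4 or None, got {self.box!r}")


@dataclass(frozen=True)
class ReductionResult:
    """Outcome of retention-prediction candidate reduction."""

    kept: tuple[BoxedCandidate, ...]
    reduction_fraction: float | None
    reconsider: tuple[BoxedCandidate, ...]  # box-4 outliers, retried if box 1 fails

    @property
    def defined(self) -> bool:
        return self.reduction_fraction is not None


# ---------------------------------------------------------------------------
# matching and scoring
# ---------------------------------------------------------------------------


def match_feature(
    feature: Feature,
    suspect: SuspectEntry,
    thresholds: Thresholds = Thresholds(),
) -> MatchEvidence | None:
    """Match one feature against one suspect; ``None`` if no adduct of the
    suspect lies within the mass tolerance.

    The best (smallest |ppm|) polarity-compatible adduct is chosen. RT
    deviation is evaluated only when the suspect has a recorded retention
    time; the isotopic fit only when the feature carries a measured
    isotope envelope; the MS/MS score (max over the suspect's library
    spectra) only when the feature has a recorded MS/MS spectrum.
    """
    sign = +1 if feature.ion_mode == "+" else -1
    best: tuple[float, str] | None = None
    for adduct in suspect.adducts:
        if adduct_polarity(adduct) != sign:
            continue
        err = ppm_error(feature.mz, adduct_mz(suspect.formula, adduct))
        if best is None or abs(err) < abs(best[0]):
            best = (err, adduct)
    if best is None or abs(best[0]) > thresholds.ppm:
        return None
    err, adduct = best
    rt_dev = (
        abs(feature.rt - suspect.expected_rt) / 60.0
        if suspect.expected_rt is not None
        else None
    )
    fit = None
    if feature.isotope_envelope is not None:
        theoretical = isotope_pattern(suspect.formula)
        fit = msigma(feature.isotope_envelope, theoretical, MassTolerance(ppm=50.0))
    score = None
    if feature.msms is not None and suspect.library_spectra:
        score = max(
            spectral_match_score(feature.msms, lib)
            for lib in suspect.library_spectra
            if lib.ion_mode == feature.ion_mode
        )
    return MatchEvidence(
        ppm_error=err,
        adduct=adduct,
        rt_dev=rt_dev,
        msigma=fit,
        msms_score=score,
        msms_recorded=feature.msms is not None,
        blank_pass=blank_ratio_pass(feature, thresholds.blank_ratio),
        cv_pass=cv_pass(feature.intensities, thresholds.max_cv),
    )


def _tier(value: float | None, strict: float, loose: float) -> str:
    if value is None:
        return "-"
    if value <= strict:
        return "2"
    if value <= loose:
        return "1"
    return "0"


def taq_code(ev: MatchEvidence, thresholds: Thresholds = Thresholds()) -> str:
    """Six-symbol total annotation quality code.

    Symbol order: mass, RT, isotope fit, MS/MS, blank ratio, CV. Tiers:
    mass 2/1/0 at 5/10 ppm; RT at 0.1/0.2 min; isotope fit at 25/100
    mSigma; MS/MS 2 if recorded with a library score >= 600, 1 if recorded
    without a qualifying match, 0 if not recorded; blank and CV are binary
    (2 pass / 0 fail) with '-' when not evaluable.
    """
    mass_sym = _tier(abs(ev.ppm_error), thresholds.ppm_strict, thresholds.ppm)
    rt_sym = _tier(ev.rt_dev, thresholds.rt_min_strict, thresholds.rt_min)
    iso_sym = _tier(ev.msigma, thresholds.msigma_strict, thresholds.msigma_max)
    if not ev.msms_recorded:
        msms_sym = "0"
    elif ev.msms_score is not None and ev.msms_score >= thresholds.msms_score:
        msms_sym = "2"
    else:
        msms_sym = "1"
    blank_sym = "-" if ev.blank_pass is None else ("2" if ev.blank_pass else "0")
    cv_sym = "-" if ev.cv_pass is None else ("2" if ev.cv_pass else "0")
    return mass_sym + rt_sym + iso_sym + msms_sym + blank_sym + cv_sym


def _ge1(sym: str) -> bool:
    return sym in "12"


def assign_level(
    taq: str,
    list_class: str,
    has_expected_rt: bool = False,
) -> ConfidenceLevel:
    """Map a TAQ code and suspect-list class to a confidence level.

    Standards (AL+) with passing mass, RT and isotope fit reach level 1
    when a library spectrum also matches (MS/MS symbol 2) and level 2b
    otherwise; spectral-library (SL) entries with passing mass and a
    matching spectrum reach 2a; any candidate with passing mass and
    isotope fit reaches 4* (MS/MS recorded) or 4; everything else is level
    5. Failing RT or isotope evidence demotes a candidate to the generic
    4/5 rules rather than rejecting it. Level 3 is reachable only through
    :func:`boost_level`.
    """
    if len(taq) != 6 or any(s not in "210-" for s in taq):
        raise AnnotationError(f"malformed TAQ code {taq!r}")
    m, rt, iso, msms, _blank, _cv = taq
    if list_class == "AL+" and _ge1(m) and _ge1(rt) and _ge1(iso):
        return ConfidenceLevel("1" if msms == "2" else "2b")
    if list_class == "SL" and _ge1(m) and msms == "2":
        return ConfidenceLevel("2a")
    if _ge1(m) and _ge1(iso):
        return ConfidenceLevel("4*" if msms in "12" else "4")
    return ConfidenceLevel("5")


def count_isomers(suspect: SuspectEntry, slist: SuspectList) -> int:
    """Number of entries in the list sharing the suspect's formula
    (including the suspect itself)."""
    if not slist.entries:
        raise AnnotationError(f"suspect list {slist.name!r} is empty")
    target = suspect.formula.hill_formula()
    return sum(1 for e in slist if e.formula.hill_formula() == target)


def _composite_score(ev: MatchEvidence, th: Thresholds) -> float:
    """Deterministic tie-break for equal-level candidates: smaller is
    better; each evidence component is scaled by its loose threshold."""
    score = abs(ev.ppm_error) / th.ppm
    if ev.rt_dev is not None:
        score += ev.rt_dev / th.rt_min
    if ev.msigma is not None:
        score += ev.msigma / th.msigma_max
    if ev.msms_score is not None:
        score -= ev.msms_score / 1000.0
    return score


def annotate_table(
    table: FeatureTable,
    hierarchy: Sequence[SuspectList],
    thresholds: Thresholds = Thresholds(),
) -> list[Annotation]:
    """Annotate every feature against every list of the hierarchy.

    Returns one record per candidate annotation plus a level-5 record for
    each unannotated feature. Per feature, the candidate with the best
    confidence level is flagged primary; ties are broken by the composite
    evidence score, then lexicographically by (suspect, list) name so the
    outcome does not depend on input order.
    """
    if not hierarchy:
        raise AnnotationError("suspect-list hierarchy is empty")
    ordered = sorted(hierarchy, key=lambda sl: sl.rank)
    out: list[Annotation] = []
    for feat in table:
        mono = (
            monoisotopic_is_base(feat.isotope_envelope)
            if feat.isotope_envelope is not None
            else None
        )
        candidates: list[Annotation] = []
        for slist in ordered:
            for entry in slist:
                ev = match_feature(feat, entry, thresholds)
                if ev is None:
                    continue
                taq = taq_code(ev, thresholds)
                level = assign_level(taq, entry.list_class, entry.expected_rt is not None)
                candidates.append(
                    Annotation(
                        feature_id=feat.feature_id,
                        ion_mode=feat.ion_mode,
                        mz=feat.mz,
                        rt=feat.rt,
                        mean_intensity=feat.mean_intensity,
                        suspect=entry.name,
                        list_name=slist.name,
                        list_class=entry.list_class,
                        evidence=ev,
                        taq=taq,
                        level=level,
                        isomer_count=count_isomers(entry, slist),
                    )
                )
        if not candidates:
            ev = MatchEvidence(
                ppm_error=0.0,
                adduct="",
                msms_recorded=feat.msms is not None,
                blank_pass=blank_ratio_pass(feat, thresholds.blank_ratio),
                cv_pass=cv_pass(feat.intensities, thresholds.max_cv),
            )
            out.append(
                Annotation(
                    feature_id=feat.feature_id,
                    ion_mode=feat.ion_mode,
                    mz=feat.mz,
                    rt=feat.rt,
                    mean_intensity=feat.mean_intensity,
                    suspect=None,
                    list_name=None,
                    list_class=None,
                    evidence=None,
                    taq=_unannotated_taq(ev),
                    level=ConfidenceLevel("5"),
                    primary=True,
                    mono_is_base=mono,
                )
            )
            continue
        candidates.sort(
            key=lambda a: (
                a.level.rank,
                _composite_score(a.evidence, thresholds),
                a.suspect or "",
                a.list_name or "",
            )
        )
        candidates[0] = replace(candidates[0], primary=True)
        for k in range(len(candidates)):
            candidates[k] = replace(candidates[k], mono_is_base=mono)
        out.extend(candidates)
    return out


def _unannotated_taq(ev: MatchEvidence) -> str:
    blank_sym = "-" if ev.blank_pass is None else ("2" if ev.blank_pass else "0")
    cv_sym = "-" if ev.cv_pass is None else ("2" if ev.cv_pass else "0")
    msms_sym = "1" if ev.msms_recorded else "0"
    return "---" + msms_sym + blank_sym + cv_sym


# ---------------------------------------------------------------------------
# retention-prediction reduction and boosting
# ---------------------------------------------------------------------------


def reduce_candidates(isomers: Sequence[BoxedCandidate]) -> ReductionResult:
    """Narrow an isomer set by retention-prediction reliability.

    Keeps box-1 candidates. The reduction fraction is
    ``1 - |box1| / (|all| - |box4|)``: box-4 outliers (whose retention
    behavior the predictor cannot estimate) are excluded from the
    denominator, while unpredicted candidates remain in it. When every
    candidate is box 4 the reduction is undefined (``None``) and all are
    flagged for reconsideration.
    """
    if not isomers:
        raise AnnotationError("candidate list is empty")
    kept = tuple(c for c in isomers if c.box == 1)
    box4 = tuple(c for c in isomers if c.box == 4)
    denom = len(isomers) - len(box4)
    reduction = None if denom == 0 else 1.0 - len(kept) / denom
    return ReductionResult(kept=kept, reduction_fraction=reduction, reconsider=box4)


def boost_level(
    annotation: Annotation,
    box: int,
    frag: FragmentMatchResult,
    min_matched: int = 2,
) -> ConfidenceLevel:
    """Upgrade a level-4* annotation to level 3 when its retention
    prediction is reliable (box 1) and at least ``min_matched`` measured
    fragments match the in-silico predicted fragments; otherwise the level
    is returned unchanged."""
    if str(annotation.level) != "4*":
        raise AnnotationError("boost_level applies only to level 4* annotations")
    if box == 1 and frag.n_matched_peaks >= min_matched:
        return ConfidenceLevel("3")
    return annotation.level


# ---------------------------------------------------------------------------
# input-output
# ---------------------------------------------------------------------------


def write_annotations(annotations: Iterable[Annotation], path: str | Path) -> None:
    rows = []
    for a in annotations:
        ev = a.evidence
        rows.append(
            {
                "feature_id": a.feature_id,
                "mode": a.ion_mode,
                "mz": a.mz,
                "rt_s": a.rt,
                "mean_intensity": a.mean_intensity,
                "suspect": a.suspect or "",
                "list": a.list_name or "",
                "list_class": a.list_class or "",
                "adduct": ev.adduct if ev else "",
                "ppm": ev.ppm_error if ev else None,
                "rt_dev_min": ev.rt_dev if ev else None,
                "msigma": ev.msigma if ev else None,
                "msms_score": ev.msms_score if ev else None,
                "taq": a.taq,
                "level": str(a.level),
                "isomer_count": a.isomer_count,
                "primary_flag": int(a.primary),
                "polyhalogen_risk": (
                    "" if a.mono_is_base is None else int(not a.mono_is_base)
                ),
            }
        )
    pd.DataFrame(rows).to_csv(path, index=False)


def read_annotations(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, keep_default_na=True)
    required = {"feature_id", "mode", "mz", "rt_s", "level", "primary_flag"}
    missing = required - set(df.columns)
    if missing:
        raise AnnotationError(
            f"annotation table {path}: missing required column(s) {sorted(missing)}"
        )
    return df


def read_boxed_candidates(path: str | Path) -> dict[str, list[BoxedCandidate]]:
    """Read an externally computed retention-prediction CSV with columns
    ``feature_id, candidate, predicted_rt_s, box`` (box empty =
    unpredicted). Returns candidates grouped per feature."""
    df = pd.read_csv(path)
    for col in ("feature_id", "candidate", "box"):
        if col not in df.columns:
            raise AnnotationError(f"boxed-candidate table {path}: missing column {col!r}")
    grouped: dict[str, list[BoxedCandidate]] = {}
    for row in df.itertuples(index=False):
        rowd = row._asdict()
        box = rowd["box"]
        rt = rowd.get("predicted_rt_s")
        grouped.setdefault(str(rowd["feature_id"]), []).append(
            BoxedCandidate(
                name=str(rowd["candidate"]),
                predicted_rt=None if rt is None or pd.isna(rt) else float(rt),
                box=None if box is None or pd.isna(box) else int(box),
            )
        )
    return grouped
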