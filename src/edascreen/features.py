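"""Feature tables, suspect lists, replicate grouping, and inclusion filters.

A *feature* is one deconvoluted accurate-mass/retention-time peak from an
aligned LC-HRMS feature table, carrying one intensity per technical
injection. The workflow's inclusion filters are applied here: the sample
intensity must be at least 3x the procedure-blank intensity, and the
coefficient of variation (CV) across injections must not exceed 20%. Both
filters are tri-state: ``True`` (pass), ``False`` (fail), ``None``
(not evaluable, e.g. no blank recorded or a single injection).

Retention times are stored in seconds throughout; the CSV reader converts
from minutes on request.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import pandas as pd

from .chem import ElementComposition, IsotopePattern, parse_formula
from .spectra import MsMsSpectrum, read_msp

__all__ = [
    "SchemaError",
    "Feature",
    "FeatureTable",
    "SuspectEntry",
    "SuspectList",
    "read_feature_table",
    "write_feature_table",
    "read_suspect_list",
    "write_suspect_list",
    "group_replicates",
    "blank_ratio_pass",
    "cv_pass",
    "replicate_cv",
]


class SchemaError(ValueError):
    """A data file does not satisfy the documented column contract."""


@dataclass
class Feature:
    """One aligned HRMS feature."""

    feature_id: str
    ion_mode: str  # '+' or '-'
    mz: float
    rt: float  # seconds
    intensities: list[float]
    blank_intensity: float | None = None
    msms: MsMsSpectrum | None = None
    isotope_envelope: IsotopePattern | None = None

    def __post_init__(self) -> None:
        if self.ion_mode not in ("+", "-"):
            raise SchemaError(f"ion_mode must be '+' or '-', got {self.ion_mode!r}")
        if not self.mz > 0:
            raise SchemaError(f"feature {self.feature_id}: m/z must be positive")
        if self.rt < 0:
            raise SchemaError(f"feature {self.feature_id}: rt must be >= 0")
        if not self.intensities or any(v < 0 for v in self.intensities):
            raise SchemaError(
                f"feature {self.feature_id}: needs >= 1 non-negative intensity"
            )

    @property
    def mean_intensity(self) -> float:
        return sum(self.intensities) / len(self.intensities)

    @property
    def msms_recorded(self) -> bool:
        return self.msms is not None


@dataclass
class FeatureTable:
    """A set of features from one matrix x ion-mode combination."""

    features: list[Feature]
    label: str = ""
    ion_mode: str = "+"
    n_injections: int = 1

    def __post_init__(self) -> None:
        ids = [f.feature_id for f in self.features]
        if len(ids) != len(set(ids)):
            dup = next(i for i in ids if ids.count(i) > 1)
            raise SchemaError(f"duplicate feature_id {dup!r} in table {self.label!r}")
        modes = {f.ion_mode for f in self.features}
        if modes - {self.ion_mode}:
            raise SchemaError(f"table {self.label!r} mixes ion modes {modes}")

    def __len__(self) -> int:
        return len(self.features)

    def __iter__(self):
        return iter(self.features)


@dataclass
class SuspectEntry:
    """One candidate compound available for matching.

    ``list_class`` follows the suspect-list hierarchy: ``"SL"`` (spectral
    library; carries library spectra), ``"AL"`` (analyte suspect list;
    exact mass + isotope fit only), ``"AL+"`` (in-house standards; may
    additionally carry a recorded retention time).
    """

    name: str
    formula: ElementComposition
    list_class: Literal["SL", "AL", "AL+"]
    expected_rt: float | None = None  # seconds
    library_spectra: list[MsMsSpectrum] = field(default_factory=list)
    adducts: list[str] = field(default_factory=lambda: ["[M+H]+", "[M-H]-"])

    def __post_init__(self) -> None:
        if self.list_class not in ("SL", "AL", "AL+"):
            raise SchemaError(f"unknown list_class {self.list_class!r}")


@dataclass
class SuspectList:
    """A named suspect list with its position in the application hierarchy."""

    name: str
    entries: list[SuspectEntry]
    rank: int = 0

    def __len__(self) -> int:
        return len(self.entries)

    def __iter__(self):
        return iter(self.entries)


# ---------------------------------------------------------------------------
# CSV input-output
# ---------------------------------------------------------------------------

_REQUIRED_FEATURE_COLS = ("feature_id", "ion_mode", "mz", "rt")


def _encode_pattern(pat: IsotopePattern | None) -> tuple[str, str]:
    if pat is None:
        return "", ""
    return (
        ";".join(f"{m:.6f}" for m, _ in pat.peaks),
        ";".join(f"{i:.6g}" for _, i in pat.peaks),
    )


def _decode_pattern(mzs: str, ints: str) -> IsotopePattern | None:
    if not mzs or not isinstance(mzs, str):
        return None
    peaks = tuple(
        (float(m), float(i)) for m, i in zip(mzs.split(";"), ints.split(";"))
    )
    return IsotopePattern(peaks)


def read_feature_table(
    path: str | Path,
    rt_unit: Literal["s", "min"] = "s",
    label: str | None = None,
) -> FeatureTable:
    """Read a feature-table CSV.

    Required columns: ``feature_id, ion_mode, mz, rt`` plus one or more
    ``intensity_<k>`` columns; optional ``blank_intensity``,
    ``isotope_mzs``/``isotope_ints`` (semicolon-joined measured envelope)
    and ``msms_recorded``. ``rt_unit`` declares the retention-time unit of
    the file; values are converted to seconds internally.
    """
    df = pd.read_csv(path)
    for col in _REQUIRED_FEATURE_COLS:
        if col not in df.columns:
            raise SchemaError(f"feature table {path}: missing required column {col!r}")
    int_cols = sorted(
        (c for c in df.columns if c.startswith("intensity_")),
        key=lambda c: int(c.split("_")[1]),
    )
    if not int_cols:
        raise SchemaError(f"feature table {path}: missing required column 'intensity_1'")
    scale = 60.0 if rt_unit == "min" else 1.0
    features = []
    for row in df.itertuples(index=False):
        rowd = row._asdict()
        blank = rowd.get("blank_intensity")
        envelope = _decode_pattern(
            rowd.get("isotope_mzs", ""), rowd.get("isotope_ints", "")
        )
        features.append(
            Feature(
                feature_id=str(rowd["feature_id"]),
                ion_mode=str(rowd["ion_mode"]),
                mz=float(rowd["mz"]),
                rt=float(rowd["rt"]) * scale,
                intensities=[float(rowd[c]) for c in int_cols],
                blank_intensity=None if blank is None or pd.isna(blank) else float(blank),
                isotope_envelope=envelope,
            )
        )
    mode = features[0].ion_mode if features else "+"
    return FeatureTable(
        features,
        label=label or Path(path).stem,
        ion_mode=mode,
        n_injections=len(int_cols),
    )


def write_feature_table(table: FeatureTable, path: str | Path) -> None:
    rows = []
    for f in table:
        mzs, ints = _encode_pattern(f.isotope_envelope)
        row = {
            "feature_id": f.feature_id,
            "ion_mode": f.ion_mode,
            "mz": f.mz,
            "rt": f.rt,
        }
        for k, v in enumerate(f.intensities, start=1):
            row[f"intensity_{k}"] = v
        row["blank_intensity"] = f.blank_intensity
        row["isotope_mzs"] = mzs
        row["isotope_ints"] = ints
        row["msms_recorded"] = int(f.msms_recorded)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


def read_suspect_list(
    path: str | Path,
    rank: int = 0,
    spectra_path: str | Path | None = None,
    name: str | None = None,
) -> SuspectList:
    """Read a suspect-list CSV (columns ``name, formula, list_class``;
    optional ``rt_min`` and ``adducts`` semicolon-separated). Library
    spectra can be linked from an MSP file whose ``Name`` headers match the
    suspect names."""
    df = pd.read_csv(path)
    for col in ("name", "formula", "list_class"):
        if col not in df.columns:
            raise SchemaError(f"suspect list {path}: missing required column {col!r}")
    by_name: dict[str, list[MsMsSpectrum]] = {}
    if spectra_path is not None:
        for spec in read_msp(spectra_path):
            key = str(spec.metadata.get("Name", spec.metadata.get("name", "")))
            by_name.setdefault(key, []).append(spec)
    entries = []
    for row in df.itertuples(index=False):
        rowd = row._asdict()
        rt_min = rowd.get("rt_min")
        adducts = rowd.get("adducts")
        entries.append(
            SuspectEntry(
                name=str(rowd["name"]),
                formula=parse_formula(str(rowd["formula"])),
                list_class=str(rowd["list_class"]),
                expected_rt=None if rt_min is None or pd.isna(rt_min) else float(rt_min) * 60.0,
                library_spectra=by_name.get(str(rowd["name"]), []),
                adducts=(
                    str(adducts).split(";")
                    if isinstance(adducts, str) and adducts
                    else ["[M+H]+", "[M-H]-"]
                ),
            )
        )
    return SuspectList(name or Path(path).stem, entries, rank=rank)


def write_suspect_list(slist: SuspectList, path: str | Path) -> None:
    rows = [
        {
            "name": e.name,
            "formula": e.formula.hill_formula(),
            "list_class": e.list_class,
            "rt_min": None if e.expected_rt is None else e.expected_rt / 60.0,
            "adducts": ";".join(e.adducts),
        }
        for e in slist
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# replicate grouping
# ---------------------------------------------------------------------------


def group_replicates(
    tables: Sequence[FeatureTable],
    mz_tol_ppm: float = 10.0,
    rt_tol: float = 6.0,
) -> FeatureTable:
    """Merge per-injection feature tables into one multi-injection table.

    Features are grouped greedily across injections by nearest neighbor
    within ``mz_tol_ppm`` and ``rt_tol`` (seconds). The merged feature
    carries a per-injection intensity vector (0 where the feature was not
    detected in an injection), the mean m/z, and the mean retention time.
    Upstream LOESS alignment is assumed to have been applied already, so a
    plain tolerance match suffices.
    """
    if not tables:
        raise SchemaError("group_replicates requires at least one table")
    modes = {t.ion_mode for t in tables}
    if len(modes) > 1:
        raise SchemaError(f"cannot group tables of mixed ion modes {modes}")
    n = len(tables)

    class _Group:
        __slots__ = ("mzs", "rts", "intensities", "proto")

        def __init__(self, feat: Feature, inj: int):
            self.mzs = [feat.mz]
            self.rts = [feat.rt]
            self.intensities = [0.0] * n
            self.intensities[inj] = feat.mean_intensity
            self.proto = feat

    groups: list[_Group] = []
    for inj, table in enumerate(tables):
        for feat in table:
            best = None
            for g in groups:
                if g.intensities[inj] > 0:
                    continue
                mz_ref = sum(g.mzs) / len(g.mzs)
                rt_ref = sum(g.rts) / len(g.rts)
                dmz_ppm = abs(feat.mz - mz_ref) / mz_ref * 1e6
                drt = abs(feat.rt - rt_ref)
                if dmz_ppm <= mz_tol_ppm and drt <= rt_tol:
                    score = dmz_ppm / mz_tol_ppm + drt / max(rt_tol, 1e-9)
                    if best is None or score < best[0]:
                        best = (score, g)
            if best is None:
                groups.append(_Group(feat, inj))
            else:
                g = best[1]
                g.mzs.append(feat.mz)
                g.rts.append(feat.rt)
                g.intensities[inj] = feat.mean_intensity
                if g.proto.msms is None and feat.msms is not None:
                    g.proto = feat
    merged = []
    for g in groups:
        proto = g.proto
        merged.append(
            Feature(
                feature_id=proto.feature_id,
                ion_mode=proto.ion_mode,
                mz=sum(g.mzs) / len(g.mzs),
                rt=sum(g.rts) / len(g.rts),
                intensities=g.intensities,
                blank_intensity=proto.blank_intensity,
                msms=proto.msms,
                isotope_envelope=proto.isotope_envelope,
            )
        )
    return FeatureTable(
        merged,
        label=tables[0].label + "_merged" if tables[0].label else "merged",
        ion_mode=tables[0].ion_mode,
        n_injections=n,
    )


# ---------------------------------------------------------------------------
# inclusion filters
# ---------------------------------------------------------------------------


def blank_ratio_pass(
    feature: Feature,
    ratio: float = 3.0,
    aggregate: Literal["mean", "max"] = "mean",
) -> bool | None:
    """Sample-vs-procedure-blank intensity filter (sample >= ratio x blank).

    Returns ``None`` when no blank intensity was recorded. A blank of zero
    passes any feature with signal. The sample intensity is aggregated over
    injections by ``aggregate`` (mean by default).
    """
    if feature.blank_intensity is None:
        return None
    agg = feature.mean_intensity if aggregate == "mean" else max(feature.intensities)
    if feature.blank_intensity == 0:
        return agg > 0
    return agg >= ratio * feature.blank_intensity


def replicate_cv(intensities: Sequence[float]) -> float | None:
    """Percent coefficient of variation over the nonzero injections.

    Sample (n-1) standard deviation. ``None`` when fewer than two nonzero
    injections are available (single-injection mode)."""
    nonzero = [v for v in intensities if v > 0]
    if len(nonzero) < 2:
        return None
    mean = statistics.fmean(nonzero)
    return statistics.stdev(nonzero) / mean * 100.0


def cv_pass(intensities: Sequence[float], max_cv: float = 20.0) -> bool | None:
    """Replicate-variability filter: CV across injections <= ``max_cv`` %.

    ``None`` (not evaluable) for single-injection data or all-zero vectors.
    """
    cv = replicate_cv(intensities)
    if cv is None:
        return None
    return cv <= max_cv
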