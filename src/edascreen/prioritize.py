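"""Bioactivity-directed feature prioritization.

Each bioactive micro-fraction maps to a retention-time window of the
chromatogram: the *core* window is the 13.5 s slice the fraction collector
actually sampled, and the *selection* window extends it by a 6.5 s error
margin on both sides (26.5 s total) to absorb the small mechanical offset
between the mass spectrometer and the fraction collector. Annotated
features whose retention time falls inside at least one selection window
are selected and ranked by identification confidence level, then mean
intensity; a feature inside two overlapping windows is listed under both
fractions. The report summarizes, per bioactive fraction, the number of
selected features at each confidence level (naming the level 1/2a/2b
identifications) and flags features with a polyhalogenated-risk isotope
envelope.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import pandas as pd

from .annotate import Annotation, LEVEL_ORDER
from .bioassay import N_FRACTIONS, PlateError

__all__ = [
    "RTWindow",
    "PrioritizedFeature",
    "fraction_window",
    "windows_for_fractions",
    "select_features",
    "build_report",
    "write_windows",
]

#: Fraction duration in seconds (one 13.5 s slice of the LC run per well).
FRACTION_DURATION_S = 13.5
#: Alignment error margin in seconds (about half a fraction).
ERROR_MARGIN_S = 6.5
#: Default LC run length covered by the 80 fractions.
RUN_END_S = N_FRACTIONS * FRACTION_DURATION_S  # 1080 s


@dataclass(frozen=True)
class RTWindow:
    """Retention-time window of one bioactive fraction (all in seconds)."""

    fraction_index: int
    core_start: float
    core_end: float
    sel_start: float
    sel_end: float

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.core_start + self.core_end)

    def contains(self, rt: float) -> bool:
        """Closed-interval membership in the selection window; boundary
        features belong to both neighboring windows."""
        return self.sel_start <= rt <= self.sel_end


@dataclass(frozen=True)
class PrioritizedFeature:
    """A selected annotation together with the windows it falls in."""

    annotation: Annotation
    fractions: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.fractions:
            raise PlateError("a prioritized feature must hit >= 1 window")


def fraction_window(
    i: int,
    duration: float = FRACTION_DURATION_S,
    margin: float = ERROR_MARGIN_S,
    t0: float = 0.0,
    run_end: float | None = None,
) -> RTWindow:
    """Retention-time window of fraction ``i`` (1-80).

    Core window: ``[t0 + (i-1) * duration, t0 + i * duration]``; the
    selection window extends it by ``margin`` on each side, clipped to
    ``[0, run_end]``. ``t0`` allows for a fractionation start offset.
    """
    if not 1 <= i <= N_FRACTIONS:
        raise PlateError(f"fraction index must lie in 1-{N_FRACTIONS}, got {i}")
    if run_end is None:
        run_end = t0 + N_FRACTIONS * duration
    core_start = t0 + (i - 1) * duration
    core_end = t0 + i * duration
    return RTWindow(
        fraction_index=i,
        core_start=core_start,
        core_end=core_end,
        sel_start=max(0.0, core_start - margin),
        sel_end=min(run_end, core_end + margin),
    )


def windows_for_fractions(
    fractions: Sequence[int],
    duration: float = FRACTION_DURATION_S,
    margin: float = ERROR_MARGIN_S,
    t0: float = 0.0,
    run_end: float | None = None,
) -> list[RTWindow]:
    """Selection windows for a list of bioactive fraction indices."""
    return [fraction_window(i, duration, margin, t0, run_end) for i in fractions]


def select_features(
    annotations: Sequence[Annotation],
    windows: Sequence[RTWindow],
) -> list[PrioritizedFeature]:
    """Select annotations whose retention time falls in >= 1 selection
    window, ranked by confidence level then mean intensity (descending)."""
    if not windows:
        return []
    out = []
    for ann in annotations:
        hit = tuple(w.fraction_index for w in windows if w.contains(ann.rt))
        if hit:
            out.append(PrioritizedFeature(ann, hit))
    out.sort(key=lambda p: (p.annotation.level.rank, -p.annotation.mean_intensity))
    # selection postcondition: every selected feature lies inside a window
    by_index = {w.fraction_index: w for w in windows}
    assert all(
        by_index[i].contains(p.annotation.rt) for p in out for i in p.fractions
    )
    return out


_NAMED_LEVELS = ("1", "2a", "2b")


def build_report(
    prioritized: Sequence[PrioritizedFeature],
    fractions: Sequence[int],
    primary_only: bool = True,
) -> pd.DataFrame:
    """Per-fraction level breakdown of the selected features.

    One row per bioactive fraction with the total feature count ``n``,
    per-level counts (``isomers`` columns sum the possible-isomer counts of
    the 4*/4 annotations), the names behind the level 1/2a/2b
    identifications, and the number of polyhalogenated-risk flags. ``n``
    equals the sum over the level counts by construction.
    """
    known = set(fractions)
    for p in prioritized:
        unknown = set(p.fractions) - known
        if unknown:
            raise PlateError(
                f"prioritized feature {p.annotation.feature_id} maps to "
                f"fraction(s) {sorted(unknown)} absent from the report"
            )
    rows = []
    for frac in sorted(known):
        sel = [
            p.annotation
            for p in prioritized
            if frac in p.fractions and (p.annotation.primary or not primary_only)
        ]
        row: dict = {"fraction": frac, "n": len(sel)}
        for level in LEVEL_ORDER:
            anns = [a for a in sel if str(a.level) == level]
            key = level.replace("*", "star")
            row[f"level_{key}_n"] = len(anns)
            if level in ("4*", "4"):
                row[f"level_{key}_isomers"] = sum(a.isomer_count for a in anns)
            if level in _NAMED_LEVELS:
                row[f"level_{key}_names"] = ";".join(
                    sorted(a.suspect or "" for a in anns)
                )
        row["polyhalogen_risk_n"] = sum(1 for a in sel if a.mono_is_base is False)
        rows.append(row)
    return pd.DataFrame(rows)


def write_windows(windows: Sequence[RTWindow], path: str | Path) -> None:
    pd.DataFrame(
        [
            {
                "fraction": w.fraction_index,
                "core_start_s": w.core_start,
                "core_end_s": w.core_end,
                "sel_start_s": w.sel_start,
                "sel_end_s": w.sel_end,
            }
            for w in windows
        ]
    ).to_csv(path, index=False)


def read_windows(path: str | Path) -> list[RTWindow]:
    df = pd.read_csv(path)
    required = {"fraction", "core_start_s", "core_end_s", "sel_start_s", "sel_end_s"}
    missing = required - set(df.columns)
    if missing:
        raise PlateError(f"windows file {path}: missing column(s) {sorted(missing)}")
    return [
        RTWindow(
            int(r.fraction),
            float(r.core_start_s),
            float(r.core_end_s),
            float(r.sel_start_s),
            float(r.sel_end_s),
        )
        for r in df.itertuples(index=False)
    ]
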