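"""96-well micro-fraction plate processing and dose-response fitting.

Post-column, an LC run is fractionated into 80 micro-fractions collected in
wells A3-H12 of a 96-well plate (columns 1-2 hold controls and blanks);
each fraction spans 13.5 s of the chromatogram. Two assay types are
supported:

* ``growth`` — a bacterial growth-inhibition (antibiotics) assay read out
  as % viability relative to the solvent control; a fraction is a hit when
  its mean viability falls below the procedure-blank response minus three
  standard deviations of the procedure-blank responses across all 80
  fractions.
* ``binding`` — a competitive-binding assay (e.g. transthyretin/FITC-T4)
  read out as % inhibition, 100 x (1 - signal/control); a fraction is a
  hit at >= 20% inhibition.

Contiguous hit fractions are grouped into *active regions*. Dose-response
data from unfractionated extracts are fitted with a four-parameter
logistic to recover IC50 values, which can be translated back to minimum
sample concentrations through the enrichment factor of the fractionated
plate.
"""

from __future__ import annotations

import statistics
from dataclasses import dataclass, field
from pathlib import Path
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "PlateError",
    "N_FRACTIONS",
    "well_to_fraction",
    "fraction_to_well",
    "FractionResult",
    "read_plate",
    "write_plate",
    "normalize",
    "antibiotic_hit_threshold",
    "growth_hit_mask",
    "call_hits",
    "null_hit_rate",
    "Ic50Fit",
    "fit_ic50",
    "min_sample_conc",
    "spike_concentration",
]


class PlateError(ValueError):
    """Invalid plate data or well address."""


_ROWS = "ABCDEFGH"
_FRACTION_COLS = tuple(range(3, 13))  # columns 3..12
N_FRACTIONS = len(_ROWS) * len(_FRACTION_COLS)  # 80


def well_to_fraction(well: str) -> int:
    """Map a fraction well (A3-H12) to its fraction index 1-80.

    Ordering is row-major from A3: A3 -> 1, A12 -> 10, B3 -> 11, H12 -> 80.
    Columns 1-2 hold controls/blanks and are rejected.
    """
    well = well.strip().upper()
    if len(well) < 2 or well[0] not in _ROWS or not well[1:].isdigit():
        raise PlateError(f"malformed well address {well!r}")
    row, col = _ROWS.index(well[0]), int(well[1:])
    if col not in _FRACTION_COLS:
        raise PlateError(f"{well} is not a fraction well (columns 3-12)")
    return row * len(_FRACTION_COLS) + (col - _FRACTION_COLS[0]) + 1


def fraction_to_well(index: int) -> str:
    """Inverse of :func:`well_to_fraction`."""
    if not 1 <= index <= N_FRACTIONS:
        raise PlateError(f"fraction index must lie in 1-{N_FRACTIONS}, got {index}")
    row, offset = divmod(index - 1, len(_FRACTION_COLS))
    return f"{_ROWS[row]}{_FRACTION_COLS[0] + offset}"


@dataclass
class FractionResult:
    """Normalized per-replicate responses of one micro-fraction."""

    fraction_index: int
    responses: list[float]
    is_hit: bool | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.fraction_index <= N_FRACTIONS:
            raise PlateError(f"fraction index out of range: {self.fraction_index}")
        if not self.responses:
            raise PlateError("a fraction needs at least one replicate response")

    @property
    def mean_response(self) -> float:
        return statistics.fmean(self.responses)


# ---------------------------------------------------------------------------
# plate input-output and normalization
# ---------------------------------------------------------------------------

_PLATE_COLS = ("well", "role", "replicate", "raw_response")
_ROLES = ("fraction", "pb_fraction", "solvent_control", "assay_control")


def read_plate(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(_PLATE_COLS) - set(df.columns)
    if missing:
        raise PlateError(f"plate file {path}: missing column(s) {sorted(missing)}")
    bad = set(df["role"]) - set(_ROLES)
    if bad:
        raise PlateError(f"plate file {path}: unknown role(s) {sorted(bad)}")
    return df


def write_plate(df: pd.DataFrame, path: str | Path) -> None:
    df.to_csv(path, index=False)


def normalize(
    raw: pd.DataFrame,
    assay: Literal["growth", "binding"],
    fraction_role: str = "fraction",
    control_role: str = "solvent_control",
) -> list[FractionResult]:
    """Normalize raw plate responses against the solvent-control mean.

    growth assay: % viability = 100 x raw / control mean;
    binding assay: % inhibition = 100 x (1 - raw / control mean).
    Scaling every raw value and control by the same gain leaves the
    normalized responses unchanged.
    """
    controls = raw.loc[raw["role"] == control_role, "raw_response"]
    if controls.empty:
        raise PlateError(f"no wells with control role {control_role!r}")
    c = float(controls.mean())
    if c == 0:
        raise PlateError("control mean is zero; cannot normalize")
    frac = raw[raw["role"] == fraction_role]
    results = []
    for well, grp in frac.groupby("well", sort=False):
        idx = well_to_fraction(str(well))
        vals = grp.sort_values("replicate")["raw_response"].astype(float)
        if assay == "growth":
            resp = (100.0 * vals / c).tolist()
        elif assay == "binding":
            resp = (100.0 * (1.0 - vals / c)).tolist()
        else:
            raise PlateError(f"unknown assay type {assay!r}")
        results.append(FractionResult(idx, resp))
    results.sort(key=lambda r: r.fraction_index)
    return results


# ---------------------------------------------------------------------------
# hit calling
# ---------------------------------------------------------------------------


def antibiotic_hit_threshold(pb_responses: Sequence[float]) -> float:
    """Growth-assay hit threshold: procedure-blank mean minus 3x the sample
    standard deviation of the procedure-blank responses over all fractions."""
    if len(pb_responses) < 3:
        raise PlateError("need >= 3 procedure-blank responses for a threshold")
    mean = statistics.fmean(pb_responses)
    sd = statistics.stdev(pb_responses)
    return mean - 3.0 * sd


def growth_hit_mask(mean_responses: np.ndarray, threshold: float) -> np.ndarray:
    """Hit rule of the growth assay: mean response strictly below threshold."""
    return np.asarray(mean_responses) < threshold


def call_hits(
    results: Sequence[FractionResult],
    assay: Literal["growth", "binding"],
    threshold: float = 20.0,
) -> tuple[list[FractionResult], list[tuple[int, int]]]:
    """Flag bioactive fractions and group them into active regions.

    growth: hit iff the replicate-mean response is below ``threshold``
    (from :func:`antibiotic_hit_threshold`); binding: hit iff the mean
    inhibition is >= ``threshold`` (default 20%). Returns the results with
    ``is_hit`` set plus a list of ``(first, last)`` fraction-index pairs of
    contiguous hit runs.
    """
    flagged = []
    for r in results:
        if assay == "growth":
            hit = bool(growth_hit_mask(np.array([r.mean_response]), threshold)[0])
        elif assay == "binding":
            hit = r.mean_response >= threshold
        else:
            raise PlateError(f"unknown assay type {assay!r}")
        flagged.append(FractionResult(r.fraction_index, list(r.responses), hit))
    hits = sorted(r.fraction_index for r in flagged if r.is_hit)
    regions: list[tuple[int, int]] = []
    for idx in hits:
        if regions and idx == regions[-1][1] + 1:
            regions[-1] = (regions[-1][0], idx)
        else:
            regions.append((idx, idx))
    return flagged, regions


def null_hit_rate(
    n_plates: int,
    seed: int,
    n_fractions: int = N_FRACTIONS,
    mean: float = 100.0,
    sd: float = 5.0,
    n_sd: float = 3.0,
) -> float:
    """Monte-Carlo false-positive rate of the growth-assay hit rule under a
    Gaussian null with known parameters.

    Responses are N(mean, sd) with no actives and the threshold is the true
    ``mean - n_sd x sd``; the expected per-fraction rate is Phi(-n_sd)
    (0.00135 at 3 SD).
    """
    rng = np.random.default_rng(seed)
    responses = rng.normal(mean, sd, size=(n_plates, n_fractions))
    hits = growth_hit_mask(responses, mean - n_sd * sd)
    return float(hits.mean())


# ---------------------------------------------------------------------------
# dose-response
# ---------------------------------------------------------------------------


@dataclass
class Ic50Fit:
    """Four-parameter logistic fit result."""

    ic50: float | None
    top: float | None = None
    bottom: float | None = None
    slope: float | None = None
    converged: bool = False
    message: str = ""
    concentrations: list[float] = field(default_factory=list)
    responses: list[float] = field(default_factory=list)


def _four_pl(x, bottom, top, ic50, slope):
    # the optimizer may probe negative ic50/extreme slopes on degenerate data
    with np.errstate(invalid="ignore", over="ignore"):
        return bottom + (top - bottom) / (1.0 + (x / ic50) ** slope)


def fit_ic50(
    concentrations: Sequence[float],
    responses: Sequence[float],
) -> Ic50Fit:
    """Least-squares four-parameter logistic fit.

    ``response = bottom + (top - bottom) / (1 + (x / IC50)^slope)``.
    Initialized from the response extremes and the geometric mid
    concentration. A fit is flagged unconverged (never silently defaulted)
    when the optimizer fails, the covariance is not finite, the IC50 is
    non-positive, or its standard error exceeds the estimate itself
    (degenerate, e.g. plateau-free monotone data).
    """
    x = np.asarray(concentrations, dtype=float)
    y = np.asarray(responses, dtype=float)
    if len(np.unique(x)) < 4:
        raise PlateError("need >= 4 distinct concentrations for a 4PL fit")
    if np.any(x <= 0):
        raise PlateError("concentrations must be positive")
    p0 = [
        float(y.min()),
        float(y.max()),
        float(np.exp(np.mean(np.log(x)))),
        1.0,
    ]
    try:
        popt, pcov = curve_fit(_four_pl, x, y, p0=p0, maxfev=20000)
    except (RuntimeError, ValueError) as exc:
        return Ic50Fit(None, converged=False, message=str(exc),
                       concentrations=list(x), responses=list(y))
    bottom, top, ic50, slope = (float(v) for v in popt)
    perr = np.sqrt(np.diag(pcov))
    ok = (
        np.all(np.isfinite(perr))
        and ic50 > 0
        and float(perr[2]) <= abs(ic50)
    )
    return Ic50Fit(
        ic50=ic50 if ok else None,
        top=top,
        bottom=bottom,
        slope=slope,
        converged=bool(ok),
        message="" if ok else "degenerate fit: IC50 unresolved",
        concentrations=list(x),
        responses=list(y),
    )


# ---------------------------------------------------------------------------
# enrichment arithmetic
# ---------------------------------------------------------------------------


def min_sample_conc(ic50_mass: float, enrichment_factor: float) -> float:
    """Minimum concentration in the original sample (ug/L) needed to reach
    an IC50-level response in a fraction enriched ``enrichment_factor``-fold."""
    if enrichment_factor <= 0:
        raise PlateError("enrichment factor must be positive")
    return ic50_mass / enrichment_factor


def spike_concentration(amount_ug: float, volume_ml: float) -> float:
    """Concentration (ug/L) resulting from spiking ``amount_ug`` into a
    sample of ``volume_ml`` milliliters."""
    if volume_ml <= 0:
        raise PlateError("sample volume must be positive")
    if amount_ug < 0:
        raise PlateError("spiked amount must be non-negative")
    return amount_ug / (volume_ml / 1000.0)
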