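"""Molecular-formula arithmetic, adduct m/z, and isotope-pattern simulation.

This module provides the small-molecule chemistry layer of the screening
workflow: Hill-notation formula parsing (with support for the deuterium
label ``D`` and the carbon-13 label ``[13C]`` carried by isotope-labeled
internal standards), monoisotopic and average masses, electrospray adduct
m/z values, isotopologue distributions by per-element convolution, and an
isotopic-fit score in the style of mSigma (lower = better agreement between
a measured and a theoretical isotope pattern).

The exact formula behind the vendor mSigma score is proprietary; here the
score is defined as ``1000 * RMS`` of the base-peak-normalized intensity
residuals over the theoretical peaks, which is zero for a perfect fit and
grows with any intensity deviation. Thresholds (25 strict / 100 loose) are
interpreted on this scale.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from typing import Iterator, Literal

from ._isotopes import (
    AVERAGE_MASS,
    ELECTRON_MASS,
    ISOTOPES,
    PROTON_MASS,
    SUPPORTED_ELEMENTS,
)

__all__ = [
    "ChemError",
    "FormulaError",
    "ElementComposition",
    "IsotopePattern",
    "MassTolerance",
    "parse_formula",
    "mass",
    "adduct_mz",
    "ADDUCTS",
    "ppm_error",
    "isotope_pattern",
    "msigma",
    "monoisotopic_is_base",
    "micromolar_to_mass_conc",
    "mass_conc_to_micromolar",
]


class ChemError(ValueError):
    """Invalid chemistry input (empty composition, unknown adduct, ...)."""


class FormulaError(ChemError):
    """Malformed or unsupported molecular-formula string."""


# ---------------------------------------------------------------------------
# compositions and formulas
# ---------------------------------------------------------------------------

# Hill order: C, then H, then everything else alphabetically; pure-label
# symbols sort directly after their parent element.
_HILL_KEY = {"C": (0, 0), "[13C]": (0, 1), "H": (1, 0), "D": (1, 1)}


@dataclass(frozen=True)
class ElementComposition:
    """Element counts of a molecule, isotope-label aware.

    ``counts`` maps an element symbol (``"C"``, ``"Cl"``, ...) or a pure
    isotope label (``"D"``, ``"[13C]"``) to a positive integer count.
    """

    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        clean: dict[str, int] = {}
        for sym, n in self.counts.items():
            if sym not in SUPPORTED_ELEMENTS:
                raise FormulaError(f"unsupported element symbol: {sym!r}")
            if not isinstance(n, int) or n < 0:
                raise FormulaError(f"count for {sym} must be a non-negative integer")
            if n:
                clean[sym] = n
        object.__setattr__(self, "counts", clean)

    def __bool__(self) -> bool:
        return bool(self.counts)

    def __getitem__(self, sym: str) -> int:
        return self.counts.get(sym, 0)

    def items(self) -> Iterator[tuple[str, int]]:
        def key(sym: str):
            return _HILL_KEY.get(sym, (2, 0)), sym

        for sym in sorted(self.counts, key=key):
            yield sym, self.counts[sym]

    def n_atoms(self) -> int:
        return sum(self.counts.values())

    def hill_formula(self) -> str:
        """Canonical Hill-notation string; round-trips through parse_formula."""
        parts = []
        for sym, n in self.items():
            parts.append(sym if n == 1 else f"{sym}{n}")
        return "".join(parts)

    def __str__(self) -> str:  # pragma: no cover - convenience
        return self.hill_formula()


_FORMULA_TOKEN = re.compile(r"\[13C\]|[A-Z][a-z]?|\d+")


def parse_formula(formula_text: str) -> ElementComposition:
    """Parse a Hill-style formula string such as ``"C17H10D8FN3O3"``.

    Counts for repeated symbols accumulate. Unknown symbols or stray
    characters raise :class:`FormulaError` naming the offending token.
    """
    if not isinstance(formula_text, str) or not formula_text.strip():
        raise FormulaError("empty formula string")
    text = formula_text.strip()
    counts: dict[str, int] = {}
    pos = 0
    pending: str | None = None
    while pos < len(text):
        m = _FORMULA_TOKEN.match(text, pos)
        if m is None:
            raise FormulaError(f"unexpected character {text[pos]!r} in {text!r}")
        tok = m.group(0)
        pos = m.end()
        if tok.isdigit():
            if pending is None:
                raise FormulaError(f"count {tok!r} without preceding element in {text!r}")
            counts[pending] = counts.get(pending, 0) + int(tok)
            pending = None
        else:
            if pending is not None:
                counts[pending] = counts.get(pending, 0) + 1
            if tok not in SUPPORTED_ELEMENTS:
                raise FormulaError(f"unknown element symbol {tok!r} in {text!r}")
            pending = tok
    if pending is not None:
        counts[pending] = counts.get(pending, 0) + 1
    return ElementComposition(counts)


def mass(
    comp: ElementComposition,
    kind: Literal["monoisotopic", "average"] = "monoisotopic",
) -> float:
    """Monoisotopic (lightest-isotope) or average (atomic-weight) mass in Da."""
    if not comp:
        raise ChemError("cannot compute the mass of an empty composition")
    if kind == "monoisotopic":
        return sum(n * ISOTOPES[sym][0][0] for sym, n in comp.counts.items())
    if kind == "average":
        return sum(n * AVERAGE_MASS[sym] for sym, n in comp.counts.items())
    raise ChemError(f"unknown mass kind: {kind!r}")


# ---------------------------------------------------------------------------
# adducts
# ---------------------------------------------------------------------------

# Singly charged ESI adducts: id -> (mass shift added to M, charge sign).
# Shifts include the electron, so m/z = M + shift directly.
ADDUCTS: dict[str, tuple[float, int]] = {
    "[M+H]+": (PROTON_MASS, +1),
    "[M+Na]+": (ISOTOPES["Na"][0][0] - ELECTRON_MASS, +1),
    "[M+K]+": (ISOTOPES["K"][0][0] - ELECTRON_MASS, +1),
    "[M+NH4]+": (
        ISOTOPES["N"][0][0] + 4 * ISOTOPES["H"][0][0] - ELECTRON_MASS,
        +1,
    ),
    "[M-H]-": (-PROTON_MASS, -1),
    "[M+Cl]-": (ISOTOPES["Cl"][0][0] + ELECTRON_MASS, -1),
    "[M+HCOO]-": (
        ISOTOPES["H"][0][0]
        + ISOTOPES["C"][0][0]
        + 2 * ISOTOPES["O"][0][0]
        + ELECTRON_MASS,
        -1,
    ),
}


def _canonical_adduct(adduct: str) -> str:
    # tolerate the typographic minus sign used in print
    return adduct.replace("−", "-").replace(" ", "")


def adduct_mz(
    comp: ElementComposition,
    adduct: str,
    charge_sign: int | None = None,
) -> float:
    """m/z of a singly charged ESI adduct of the neutral composition.

    ``charge_sign``, if given, is validated against the adduct's own
    polarity (+1 or -1).
    """
    key = _canonical_adduct(adduct)
    if key not in ADDUCTS:
        raise ChemError(f"unknown adduct: {adduct!r}")
    shift, sign = ADDUCTS[key]
    if charge_sign is not None and charge_sign != sign:
        raise ChemError(f"adduct {adduct!r} has charge sign {sign:+d}, not {charge_sign:+d}")
    return mass(comp, "monoisotopic") + shift


def adduct_polarity(adduct: str) -> int:
    """Charge sign (+1/-1) of a configured adduct id."""
    key = _canonical_adduct(adduct)
    if key not in ADDUCTS:
        raise ChemError(f"unknown adduct: {adduct!r}")
    return ADDUCTS[key][1]


def ppm_error(measured_mz: float, theoretical_mz: float) -> float:
    """Signed relative mass error in parts per million."""
    if theoretical_mz <= 0:
        raise ChemError("theoretical m/z must be positive")
    return (measured_mz - theoretical_mz) / theoretical_mz * 1e6


# ---------------------------------------------------------------------------
# isotope patterns
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class MassTolerance:
    """Relative mass-matching tolerance in parts per million."""

    ppm: float

    def __post_init__(self) -> None:
        if not self.ppm > 0:
            raise ChemError("ppm tolerance must be > 0")

    def matches(self, measured_mz: float, theoretical_mz: float) -> bool:
        return abs(ppm_error(measured_mz, theoretical_mz)) <= self.ppm


@dataclass(frozen=True)
class IsotopePattern:
    """Centroided isotopologue distribution, base peak normalized to 1.

    ``peaks`` is a mass-ascending tuple of ``(mz, rel_intensity)`` with
    exactly one peak at intensity 1 and all others in (0, 1].
    """

    peaks: tuple[tuple[float, float], ...]
    resolution_bin: float = 0.01

    def __post_init__(self) -> None:
        if not self.peaks:
            raise ChemError("isotope pattern must contain at least one peak")
        pk = tuple((float(m), float(i)) for m, i in self.peaks)
        if any(pk[k][0] >= pk[k + 1][0] for k in range(len(pk) - 1)):
            raise ChemError("isotope pattern peaks must be strictly mass-ascending")
        if any(not 0 < i <= 1 for _, i in pk):
            raise ChemError("isotope pattern intensities must lie in (0, 1]")
        if sum(1 for _, i in pk if i == 1.0) != 1:
            raise ChemError("isotope pattern must have exactly one base peak")
        object.__setattr__(self, "peaks", pk)

    @property
    def base_mz(self) -> float:
        return max(self.peaks, key=lambda p: p[1])[0]


def _compositions(total: int, k: int) -> Iterator[tuple[int, ...]]:
    """All k-tuples of non-negative integers summing to total."""
    if k == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in _compositions(total - first, k - 1):
            yield (first, *rest)


def _element_distribution(sym: str, n: int, floor: float) -> list[tuple[float, float]]:
    """Exact isotopologue distribution of ``n`` atoms of one element."""
    isotopes = ISOTOPES[sym]
    if len(isotopes) == 1:
        return [(n * isotopes[0][0], 1.0)]
    out: list[tuple[float, float]] = []
    for counts in _compositions(n, len(isotopes)):
        p = math.factorial(n)
        m = 0.0
        for c, (iso_m, iso_a) in zip(counts, isotopes):
            p = p // math.factorial(c)
            m += c * iso_m
        prob = float(p)
        for c, (_, iso_a) in zip(counts, isotopes):
            prob *= iso_a**c
        if prob > floor:
            out.append((m, prob))
    return out


def _merge_within(
    peaks: list[tuple[float, float]], bin_width: float
) -> list[tuple[float, float]]:
    """Greedy mass-ascending clustering: a peak joins the open cluster while
    it lies within ``bin_width`` of the cluster's first member; the cluster
    is centroided by abundance weight."""
    peaks = sorted(peaks)
    merged: list[tuple[float, float]] = []
    cluster: list[tuple[float, float]] = []
    for m, a in peaks:
        if cluster and m - cluster[0][0] > bin_width:
            tot = sum(x[1] for x in cluster)
            merged.append((sum(x[0] * x[1] for x in cluster) / tot, tot))
            cluster = []
        cluster.append((m, a))
    if cluster:
        tot = sum(x[1] for x in cluster)
        merged.append((sum(x[0] * x[1] for x in cluster) / tot, tot))
    return merged


_ABUNDANCE_FLOOR = 1e-16
_CONVOLUTION_CAP = 20000


def isotope_pattern(
    comp: ElementComposition,
    resolution_bin: float = 0.01,
    prune: float = 1e-4,
) -> IsotopePattern:
    """Full isotopologue distribution of a neutral composition.

    Per-element distributions (exact multinomial over the pinned isotope
    table) are convolved across elements; isotopologues are merged within
    ``resolution_bin`` Da by abundance-weighted centroiding, peaks below
    ``prune`` x base abundance are removed, and intensities renormalized so
    the base peak is 1. Defaults (0.01 Da bin, 1e-4 prune) reflect QTOF
    resolution and dynamic range.
    """
    if not comp:
        raise ChemError("cannot simulate the isotope pattern of an empty composition")
    if not 0 < prune < 1:
        raise ChemError("prune must lie in (0, 1)")
    if resolution_bin <= 0:
        raise ChemError("resolution_bin must be positive")
    dist: list[tuple[float, float]] = [(0.0, 1.0)]
    for sym, n in comp.items():
        elem = _element_distribution(sym, n, _ABUNDANCE_FLOOR)
        nxt = [
            (m1 + m2, a1 * a2)
            for m1, a1 in dist
            for m2, a2 in elem
            if a1 * a2 > _ABUNDANCE_FLOOR
        ]
        if len(nxt) > _CONVOLUTION_CAP:
            nxt = _merge_within(nxt, resolution_bin / 10.0)
        dist = nxt
    merged = _merge_within(dist, resolution_bin)
    base = max(a for _, a in merged)
    kept = [(m, a / base) for m, a in merged if a / base >= prune]
    return IsotopePattern(tuple(sorted(kept)), resolution_bin=resolution_bin)


def msigma(
    measured: IsotopePattern,
    theoretical: IsotopePattern,
    match_tol: MassTolerance = MassTolerance(ppm=10.0),
) -> float:
    """Isotopic-fit score: 1000 x RMS intensity residual over theoretical peaks.

    Each theoretical peak is paired with the nearest measured peak within
    the mass tolerance; an unmatched theoretical peak contributes its full
    intensity as residual. 0 means a perfect fit; the workflow's default
    acceptance thresholds are 25 (strict) and 100 (loose) on this scale.
    """
    if not theoretical.peaks:
        raise ChemError("theoretical pattern has no peaks")
    residuals = []
    for t_mz, t_int in theoretical.peaks:
        best_dist: float | None = None
        best_int = 0.0
        for m_mz, m_int in measured.peaks:
            if match_tol.matches(m_mz, t_mz):
                dist = abs(m_mz - t_mz)
                if best_dist is None or dist < best_dist:
                    best_dist, best_int = dist, m_int
        residuals.append((best_int - t_int) if best_dist is not None else t_int)
    return 1000.0 * math.sqrt(sum(r * r for r in residuals) / len(residuals))


def monoisotopic_is_base(pattern: IsotopePattern) -> bool:
    """True iff the lowest-mass peak is the base peak.

    ``False`` indicates a pattern whose most intense isotopologue is not the
    monoisotopic one — typical of multihalogenated (>= 2 Br/Cl-rich)
    compounds, where deconvolution software may report the wrong m/z as the
    monoisotopic mass. Reports flag such features as polyhalogenated risk.
    """
    return pattern.peaks[0][1] >= 1.0 - 1e-12


# ---------------------------------------------------------------------------
# concentration conversions
# ---------------------------------------------------------------------------


def micromolar_to_mass_conc(conc_um: float, comp: ElementComposition) -> float:
    """Convert a micromolar concentration to ug/L via the average mass."""
    if not comp:
        raise ChemError("composition required for concentration conversion")
    if conc_um < 0:
        raise ChemError("concentration must be non-negative")
    return conc_um * mass(comp, "average")


def mass_conc_to_micromolar(conc_ug_per_l: float, comp: ElementComposition) -> float:
    """Inverse of :func:`micromolar_to_mass_conc`."""
    if not comp:
        raise ChemError("composition required for concentration conversion")
    return conc_ug_per_l / mass(comp, "average")
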