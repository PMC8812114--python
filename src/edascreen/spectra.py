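"""MS/MS spectrum handling: filtering, library similarity, fragment matching.

The library similarity score is a greedy-pair cosine on square-root
transformed intensities, scaled to 0-1000 (1000 = identical). A score >= 600
against a spectral-library entry counts as a library match in the annotation
workflow. In-silico fragment matching follows the MetFrag-style convention:
peaks above 1% of the base peak are matched against candidate fragment
masses within 5 ppm, each peak pairing with at most one fragment.
"""

from __future__ import annotations

import math
import re
from dataclasses import dataclass, field
from pathlib import Path

from pyteomics import mgf as _mgf

from .chem import MassTolerance

__all__ = [
    "SpectrumError",
    "MsMsSpectrum",
    "FragmentMatchResult",
    "relative_intensity_filter",
    "spectral_match_score",
    "fragment_match",
    "read_mgf",
    "write_mgf",
    "read_msp",
    "write_msp",
]


class SpectrumError(ValueError):
    """Invalid spectrum input."""


@dataclass(frozen=True)
class MsMsSpectrum:
    """A centroided MS/MS spectrum.

    ``peaks`` are mass-ascending ``(mz, intensity)`` pairs with arbitrary
    intensity units; ``ion_mode`` is ``"+"`` or ``"-"``; ``metadata`` keeps
    any file headers (title, name, ...) for lossless round-trips.
    """

    precursor_mz: float
    peaks: tuple[tuple[float, float], ...]
    ion_mode: str = "+"
    metadata: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.ion_mode not in ("+", "-"):
            raise SpectrumError(f"ion_mode must be '+' or '-', got {self.ion_mode!r}")
        if not self.peaks:
            raise SpectrumError("spectrum must contain at least one peak")
        pk = tuple(sorted((float(m), float(i)) for m, i in self.peaks))
        if any(i < 0 for _, i in pk):
            raise SpectrumError("peak intensities must be non-negative")
        object.__setattr__(self, "peaks", pk)

    @property
    def base_intensity(self) -> float:
        return max(i for _, i in self.peaks)

    def mzs(self) -> list[float]:
        return [m for m, _ in self.peaks]

    def intensities(self) -> list[float]:
        return [i for _, i in self.peaks]


@dataclass(frozen=True)
class FragmentMatchResult:
    """Outcome of matching in-silico fragments against a measured spectrum."""

    n_candidate_fragments: int
    n_matched_peaks: int
    matched_pairs: tuple[tuple[float, float, float], ...]  # (measured, fragment, ppm)
    matched_intensity_fraction: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.matched_intensity_fraction <= 1.0:
            raise SpectrumError("matched_intensity_fraction must lie in [0, 1]")


def relative_intensity_filter(spec: MsMsSpectrum, rel_threshold: float) -> MsMsSpectrum:
    """Keep peaks with intensity strictly above ``rel_threshold`` x base peak.

    With the default workflow threshold of 0.01 this retains the peaks with
    relative abundance higher than 1% of the base peak. Threshold 0 keeps
    all nonzero peaks. Idempotent.
    """
    if not 0 <= rel_threshold < 1:
        raise SpectrumError("rel_threshold must lie in [0, 1)")
    cut = rel_threshold * spec.base_intensity
    kept = tuple((m, i) for m, i in spec.peaks if i > cut)
    if not kept:
        raise SpectrumError("relative-intensity filter removed every peak")
    return MsMsSpectrum(spec.precursor_mz, kept, spec.ion_mode, dict(spec.metadata))


def _greedy_pairs(
    mzs_a: list[float], mzs_b: list[float], tol: MassTolerance
) -> list[tuple[int, int, float]]:
    """Injective greedy matching of two mass lists, best (smallest relative
    error) pairs first. Returns (index_a, index_b, signed_ppm) triples."""
    candidates = []
    for ia, ma in enumerate(mzs_a):
        for ib, mb in enumerate(mzs_b):
            mid = 0.5 * (ma + mb)
            err_ppm = (ma - mb) / mid * 1e6 if mid > 0 else 0.0
            if abs(err_ppm) <= tol.ppm:
                candidates.append((abs(err_ppm), ia, ib, err_ppm))
    candidates.sort()
    used_a: set[int] = set()
    used_b: set[int] = set()
    pairs = []
    for _, ia, ib, err in candidates:
        if ia in used_a or ib in used_b:
            continue
        used_a.add(ia)
        used_b.add(ib)
        pairs.append((ia, ib, err))
    return pairs


def spectral_match_score(
    query: MsMsSpectrum,
    library: MsMsSpectrum,
    match_tol: MassTolerance = MassTolerance(ppm=10.0),
) -> float:
    """Greedy-cosine similarity on sqrt intensities, scaled to [0, 1000].

    Peaks are paired injectively within the relative mass tolerance; the
    score is 1000 x the cosine of the sqrt-transformed intensity vectors
    over those pairs. Symmetric in its arguments and invariant to uniform
    intensity scaling of either spectrum.
    """
    if query.ion_mode != library.ion_mode:
        raise SpectrumError("cannot match spectra of different ion modes")
    pairs = _greedy_pairs(query.mzs(), library.mzs(), match_tol)
    if not pairs:
        return 0.0
    qi = query.intensities()
    li = library.intensities()
    dot = sum(math.sqrt(qi[ia]) * math.sqrt(li[ib]) for ia, ib, _ in pairs)
    norm_q = math.sqrt(sum(qi))
    norm_l = math.sqrt(sum(li))
    if norm_q == 0 or norm_l == 0:
        return 0.0
    return 1000.0 * dot / (norm_q * norm_l)


def fragment_match(
    spec: MsMsSpectrum,
    candidate_fragments: list[float],
    tol_ppm: float = 5.0,
    rel_threshold: float = 0.01,
) -> FragmentMatchResult:
    """Match in-silico candidate fragment masses to the measured spectrum.

    The spectrum is first reduced to peaks above ``rel_threshold`` of the
    base peak, then each retained peak is paired with at most one fragment
    (nearest within ``tol_ppm``). Adding a candidate fragment can never
    decrease the number of matched peaks.
    """
    if not candidate_fragments:
        raise SpectrumError("candidate fragment list is empty")
    filtered = relative_intensity_filter(spec, rel_threshold)
    tol = MassTolerance(ppm=tol_ppm)
    pairs = _greedy_pairs(filtered.mzs(), list(candidate_fragments), tol)
    mzs = filtered.mzs()
    ints = filtered.intensities()
    matched = tuple(
        sorted((mzs[ia], candidate_fragments[ib], err) for ia, ib, err in pairs)
    )
    total = sum(ints)
    explained = sum(ints[ia] for ia, _, _ in pairs)
    return FragmentMatchResult(
        n_candidate_fragments=len(candidate_fragments),
        n_matched_peaks=len(pairs),
        matched_pairs=matched,
        matched_intensity_fraction=explained / total if total > 0 else 0.0,
    )


# ---------------------------------------------------------------------------
# MGF / MSP input-output
# ---------------------------------------------------------------------------


def _mode_from_charge(charge) -> str:
    try:
        first = charge[0]
    except (TypeError, IndexError):
        first = charge
    return "-" if first is not None and int(first) < 0 else "+"


def read_mgf(path: str | Path) -> list[MsMsSpectrum]:
    """Read an MGF file into spectra; ion mode is taken from the CHARGE sign
    (default positive). All other parameters land in ``metadata``."""
    spectra = []
    with _mgf.MGF(str(path)) as reader:
        for entry in reader:
            params = dict(entry["params"])
            pep = params.pop("pepmass", (0.0,))
            precursor = float(pep[0]) if isinstance(pep, (tuple, list)) else float(pep)
            mode = _mode_from_charge(params.get("charge"))
            params.pop("charge", None)
            peaks = tuple(zip(entry["m/z array"].tolist(), entry["intensity array"].tolist()))
            spectra.append(MsMsSpectrum(precursor, peaks, mode, params))
    return spectra


def write_mgf(spectra: list[MsMsSpectrum], path: str | Path) -> None:
    entries = []
    for s in spectra:
        params = dict(s.metadata)
        params["pepmass"] = s.precursor_mz
        params["charge"] = "1+" if s.ion_mode == "+" else "1-"
        entries.append(
            {
                "params": params,
                "m/z array": s.mzs(),
                "intensity array": s.intensities(),
            }
        )
    _mgf.write(entries, str(path), file_mode="w")


_MSP_HEADER = re.compile(r"^([^:]+):\s*(.*)$")


def read_msp(path: str | Path) -> list[MsMsSpectrum]:
    """Read a NIST-style MSP file.

    Recognized headers: ``Name``, ``PrecursorMZ`` (or ``PRECURSORMZ``),
    ``Ion_mode``/``Ionmode`` (P/N or +/-), ``Num Peaks``. Unrecognized
    headers are preserved verbatim in ``metadata`` and written back by
    :func:`write_msp`.
    """
    spectra = []
    meta: dict = {}
    peaks: list[tuple[float, float]] = []
    expecting_peaks = 0

    def flush() -> None:
        nonlocal meta, peaks, expecting_peaks
        if peaks:
            precursor = float(meta.pop("precursormz", 0.0) or 0.0)
            mode_raw = str(meta.pop("ion_mode", meta.pop("ionmode", "P"))).upper()
            mode = "-" if mode_raw in ("N", "-", "NEGATIVE") else "+"
            spectra.append(MsMsSpectrum(precursor, tuple(peaks), mode, meta))
        meta, peaks, expecting_peaks = {}, [], 0

    for raw in Path(path).read_text().splitlines():
        line = raw.strip()
        if not line:
            flush()
            continue
        m = _MSP_HEADER.match(line)
        if m and not expecting_peaks:
            key, value = m.group(1).strip(), m.group(2).strip()
            lkey = key.lower().replace(" ", "_")
            if lkey == "num_peaks":
                expecting_peaks = int(value)
            else:
                meta[lkey if lkey in ("precursormz", "ion_mode", "ionmode") else key] = value
        else:
            parts = line.replace(",", " ").split()
            peaks.append((float(parts[0]), float(parts[1])))
            expecting_peaks = max(0, expecting_peaks - 1)
    flush()
    return spectra


def write_msp(spectra: list[MsMsSpectrum], path: str | Path) -> None:
    lines = []
    for s in spectra:
        meta = dict(s.metadata)
        lines.append(f"Name: {meta.pop('Name', meta.pop('name', 'unknown'))}")
        lines.append(f"PrecursorMZ: {s.precursor_mz}")
        lines.append(f"Ion_mode: {'P' if s.ion_mode == '+' else 'N'}")
        for key, value in meta.items():
            lines.append(f"{key}: {value}")
        lines.append(f"Num Peaks: {len(s.peaks)}")
        for m, i in s.peaks:
            lines.append(f"{m} {i}")
        lines.append("")
    Path(path).write_text("\n".join(lines))
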