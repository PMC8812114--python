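"""Synthetic study generator with known ground truth.

Emulates the data products of a complete screening study — per-injection
feature tables in both ion modes, a hierarchical set of suspect lists,
library spectra, bioassay plates with a procedure blank, retention-
prediction box assignments, and in-silico fragment lists — so that the
full pipeline (inclusion filters, annotation, hit-calling, window mapping,
prioritization, boosting) can be tested end-to-end against a known answer.

Statistical structure: feature intensities are lognormal, replicate
variation is multiplicative Gaussian at a configurable CV, retention times
are uniform over the run, plate noise is additive Gaussian, and MS/MS
spectra are recorded DDA-style for the top-N most intense features only.
Spiked actives are constructed to satisfy the inclusion criteria (blank
ratio, CV) and to land in known fractions, so their ground-truth active
fractions follow directly from the fraction clock. Chromatographic peak
shape and raw-spectrum structure are not simulated.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .bioassay import N_FRACTIONS, fraction_to_well
from .chem import adduct_mz, isotope_pattern, parse_formula, IsotopePattern
from .features import Feature, FeatureTable, SuspectEntry, SuspectList
from .annotate import AnnotationError, BoxedCandidate
from .spectra import MsMsSpectrum

import pandas as pd

__all__ = [
    "SpikeSpec",
    "StudyConfig",
    "GroundTruthSpike",
    "GroundTruth",
    "SyntheticStudy",
    "generate_study",
    "make_isomer_set",
    "write_study",
]


@dataclass(frozen=True)
class SpikeSpec:
    """A compound spiked into the synthetic sample."""

    name: str
    formula: str
    rt: float  # seconds
    ion_mode: str = "+"
    effect_sd: float = 10.0  # plate effect in units of plate noise SD
    intensity: float = 5e6


def _default_spikes() -> list[SpikeSpec]:
    # isotope-labeled antibiotic standards at staggered retention times
    return [
        SpikeSpec("ciprofloxacin-d8", "C17H10D8FN3O3", rt=130.0),
        SpikeSpec("azithromycin-13Cd3", "C37H69[13C]D3N2O12", rt=210.0),
        SpikeSpec("clarithromycin-13Cd3", "C37H66[13C]D3NO13", rt=370.0),
    ]


@dataclass
class StudyConfig:
    """Knobs of the synthetic study; the defaults emulate the study design
    (3 technical injections, 2 ion modes, 80 x 13.5 s fractions, triplicate
    sample plate with a single-measurement procedure blank)."""

    seed: int = 0
    n_background_features: int = 150  # per ion mode
    spikes: list[SpikeSpec] = field(default_factory=_default_spikes)
    n_injections: int = 3
    intensity_log_mean: float = 11.0  # ln-counts
    intensity_log_sd: float = 1.2
    replicate_cv: float = 0.10  # fractional
    blank_contamination_rate: float = 0.10
    envelope_noise: float = 0.01  # relative isotope-intensity noise
    plate_noise_sd: float = 3.0  # % of control response
    plate_baseline: float = 100.0  # % viability
    control_level: float = 1000.0  # raw counts of the solvent control
    fraction_duration: float = 13.5  # s
    margin: float = 6.5  # s
    dda_top_n: int = 40  # MS/MS recorded for the N most intense features/mode

    @property
    def run_end(self) -> float:
        return N_FRACTIONS * self.fraction_duration


@dataclass
class GroundTruthSpike:
    name: str
    formula: str
    adduct: str
    rt: float
    feature_id: str
    active_fractions: list[int]
    expected_level: str


@dataclass
class GroundTruth:
    spikes: list[GroundTruthSpike]
    spike_feature_ids: list[str]
    planted_sl_feature_ids: list[str]
    boosted_feature_id: str | None


@dataclass
class SyntheticStudy:
    config: StudyConfig
    tables: dict[str, list[FeatureTable]]  # ion mode -> one table per injection
    hierarchy: list[SuspectList]
    sample_plate: pd.DataFrame
    pb_plate: pd.DataFrame
    boxed_candidates: dict[str, list[BoxedCandidate]]  # feature_id -> candidates
    fragment_lists: dict[str, list[float]]  # candidate name -> fragment m/z
    ground_truth: GroundTruth


def _noisy_envelope(
    pattern: IsotopePattern, rng: np.random.Generator, rel_noise: float
) -> IsotopePattern:
    """Theoretical pattern with multiplicative intensity noise on the
    non-base peaks (base stays exactly 1)."""
    peaks = []
    for m, i in pattern.peaks:
        if i == 1.0:
            peaks.append((m, 1.0))
        else:
            peaks.append(
                (m, float(np.clip(i * (1 + rng.normal(0, rel_noise)), 1e-6, 1 - 1e-9)))
            )
    return IsotopePattern(tuple(peaks), pattern.resolution_bin)


def _synthetic_msms(
    precursor: float, ion_mode: str, rng: np.random.Generator, n_peaks: int = 6
) -> MsMsSpectrum:
    mzs = np.sort(rng.uniform(50.0, max(60.0, precursor - 1.0), size=n_peaks))
    ints = np.sort(rng.uniform(20.0, 1000.0, size=n_peaks))[::-1]
    return MsMsSpectrum(precursor, tuple(zip(mzs.tolist(), ints.tolist())), ion_mode)


def _active_fraction(rt: float, duration: float) -> int:
    return int(rt // duration) + 1


def generate_study(cfg: StudyConfig) -> SyntheticStudy:
    """Generate a complete deterministic synthetic study from a config."""
    rng = np.random.default_rng(cfg.seed)
    for spike in cfg.spikes:
        if not 0 <= spike.rt <= cfg.run_end:
            raise AnnotationError(
                f"spike {spike.name!r} rt {spike.rt} s lies outside the run "
                f"(0-{cfg.run_end} s)"
            )

    # --- planted non-spike actives/annotatables -------------------------
    planted_sl = [
        ("benzotriazole-like", "C6H5N3", "+", 320.0),
        ("sulfonate-like", "C8H10O3S", "-", 510.0),
    ]
    planted_al = [
        ("tramadol-like-1", "C16H25NO2", "+", 640.0),
        ("tramadol-like-2", "C16H25NO2", "+", 700.0),
        ("phthalate-like", "C16H22O4", "+", 820.0),
        ("pfoa-like", "C8HF15O2", "-", 760.0),
    ]

    specials: dict[str, list[dict]] = {"+": [], "-": []}
    for spike in cfg.spikes:
        adduct = "[M+H]+" if spike.ion_mode == "+" else "[M-H]-"
        comp = parse_formula(spike.formula)
        specials[spike.ion_mode].append(
            dict(
                kind="spike",
                name=spike.name,
                comp=comp,
                adduct=adduct,
                rt=spike.rt,
                intensity=spike.intensity,
                msms=True,
            )
        )
    for name, formula, mode, rt in planted_sl:
        adduct = "[M+H]+" if mode == "+" else "[M-H]-"
        specials[mode].append(
            dict(
                kind="sl",
                name=name,
                comp=parse_formula(formula),
                adduct=adduct,
                rt=rt,
                intensity=2e6,
                msms=True,
            )
        )
    for name, formula, mode, rt in planted_al:
        adduct = "[M+H]+" if mode == "+" else "[M-H]-"
        specials[mode].append(
            dict(
                kind="al",
                name=name,
                comp=parse_formula(formula),
                adduct=adduct,
                rt=rt,
                intensity=1e6,
                msms=True,
            )
        )

    tables: dict[str, list[FeatureTable]] = {}
    spike_gt: list[GroundTruthSpike] = []
    sl_feature_ids: list[str] = []
    al_feature_ids: dict[str, str] = {}
    library_spectra: dict[str, MsMsSpectrum] = {}
    feature_counter = 0

    for mode in ("+", "-"):
        protos: list[Feature] = []
        # special (planted) features with exact chemistry
        for sp in specials[mode]:
            feature_counter += 1
            fid = f"F{feature_counter:04d}"
            theo = isotope_pattern(sp["comp"])
            mz = adduct_mz(sp["comp"], sp["adduct"]) * (1 + rng.normal(0, 1e-6))
            msms = _synthetic_msms(mz, mode, rng)
            feat = Feature(
                feature_id=fid,
                ion_mode=mode,
                mz=mz,
                rt=sp["rt"] + rng.normal(0, 0.5),
                intensities=[sp["intensity"]],
                blank_intensity=0.0,
                msms=msms,
                isotope_envelope=_noisy_envelope(theo, rng, cfg.envelope_noise),
            )
            protos.append(feat)
            if sp["kind"] == "spike":
                spike_gt.append(
                    GroundTruthSpike(
                        name=sp["name"],
                        formula=sp["comp"].hill_formula(),
                        adduct=sp["adduct"],
                        rt=sp["rt"],
                        feature_id=fid,
                        active_fractions=[
                            _active_fraction(sp["rt"], cfg.fraction_duration)
                        ],
                        expected_level="2b",
                    )
                )
            elif sp["kind"] == "sl":
                sl_feature_ids.append(fid)
                library_spectra[sp["name"]] = MsMsSpectrum(
                    msms.precursor_mz, msms.peaks, mode, {"Name": sp["name"]}
                )
            else:
                al_feature_ids[sp["name"]] = fid
        # background features
        for _ in range(cfg.n_background_features):
            feature_counter += 1
            base = float(np.exp(rng.normal(cfg.intensity_log_mean, cfg.intensity_log_sd)))
            blank = (
                base / rng.uniform(1.0, 6.0)
                if rng.random() < cfg.blank_contamination_rate
                else 0.0
            )
            protos.append(
                Feature(
                    feature_id=f"F{feature_counter:04d}",
                    ion_mode=mode,
                    mz=float(rng.uniform(100.0, 1000.0)),
                    rt=float(rng.uniform(5.0, cfg.run_end - 5.0)),
                    intensities=[base],
                    blank_intensity=blank,
                )
            )
        # DDA: MS/MS only for the top-N most intense features
        ranked = sorted(protos, key=lambda f: -f.mean_intensity)
        keep_msms = {f.feature_id for f in ranked[: cfg.dda_top_n]}
        # per-injection tables with multiplicative replicate noise
        per_injection = []
        noise = rng.normal(1.0, cfg.replicate_cv, size=(len(protos), cfg.n_injections))
        for inj in range(cfg.n_injections):
            feats = []
            for k, proto in enumerate(protos):
                scale = float(max(0.05, noise[k, inj]))
                feats.append(
                    Feature(
                        feature_id=proto.feature_id,
                        ion_mode=mode,
                        mz=proto.mz * (1 + rng.normal(0, 3e-7)),
                        rt=proto.rt + float(rng.normal(0, 0.3)),
                        intensities=[proto.mean_intensity * scale],
                        blank_intensity=proto.blank_intensity,
                        msms=proto.msms if proto.feature_id in keep_msms else None,
                        isotope_envelope=proto.isotope_envelope,
                    )
                )
            per_injection.append(
                FeatureTable(
                    feats,
                    label=f"synthetic_{mode}_inj{inj + 1}",
                    ion_mode=mode,
                    n_injections=1,
                )
            )
        tables[mode] = per_injection

    # --- suspect lists ---------------------------------------------------
    sl_entries = [
        SuspectEntry(
            name=name,
            formula=parse_formula(formula),
            list_class="SL",
            library_spectra=[library_spectra[name]],
            adducts=["[M+H]+"] if mode == "+" else ["[M-H]-"],
        )
        for (name, formula, mode, _rt) in planted_sl
    ]
    al_entries = [
        SuspectEntry(
            name=name,
            formula=parse_formula(formula),
            list_class="AL",
            adducts=["[M+H]+"] if mode == "+" else ["[M-H]-"],
        )
        for (name, formula, mode, _rt) in planted_al
    ]
    # formula-sharing decoys make isomer counting non-trivial
    al_entries.append(
        SuspectEntry(
            name="tramadol-like-3",
            formula=parse_formula("C16H25NO2"),
            list_class="AL",
            adducts=["[M+H]+"],
        )
    )
    alp_entries = [
        SuspectEntry(
            name=s.name,
            formula=parse_formula(s.formula),
            list_class="AL+",
            expected_rt=s.rt,
            adducts=["[M+H]+"] if s.ion_mode == "+" else ["[M-H]-"],
        )
        for s in cfg.spikes
    ]
    hierarchy = [
        SuspectList("spectral_library", sl_entries, rank=1),
        SuspectList("structure_database", al_entries, rank=2),
        SuspectList("standards", alp_entries, rank=3),
    ]

    # --- bioassay plates (growth assay) ----------------------------------
    active = {
        frac: max(
            s.effect_sd
            for s in cfg.spikes
            if _active_fraction(s.rt, cfg.fraction_duration) == frac
        )
        for frac in {
            _active_fraction(s.rt, cfg.fraction_duration) for s in cfg.spikes
        }
    }
    sample_rows = []
    for frac in range(1, N_FRACTIONS + 1):
        well = fraction_to_well(frac)
        for rep in (1, 2, 3):
            viability = cfg.plate_baseline + rng.normal(0, cfg.plate_noise_sd)
            if frac in active:
                viability -= active[frac] * cfg.plate_noise_sd
            sample_rows.append(
                dict(
                    well=well,
                    role="fraction",
                    replicate=rep,
                    raw_response=viability / 100.0 * cfg.control_level,
                )
            )
    for row_letter in "ABCDEFGH":
        for col, role in ((1, "solvent_control"), (2, "assay_control")):
            sample_rows.append(
                dict(
                    well=f"{row_letter}{col}",
                    role=role,
                    replicate=1,
                    raw_response=cfg.control_level * (1 + rng.normal(0, 0.01)),
                )
            )
    pb_rows = [
        dict(
            well=fraction_to_well(frac),
            role="pb_fraction",
            replicate=1,
            raw_response=(cfg.plate_baseline + rng.normal(0, cfg.plate_noise_sd))
            / 100.0
            * cfg.control_level,
        )
        for frac in range(1, N_FRACTIONS + 1)
    ]
    for row_letter in "ABCDEFGH":
        pb_rows.append(
            dict(
                well=f"{row_letter}1",
                role="solvent_control",
                replicate=1,
                raw_response=cfg.control_level * (1 + rng.normal(0, 0.01)),
            )
        )
    sample_plate = pd.DataFrame(sample_rows)
    pb_plate = pd.DataFrame(pb_rows)

    # --- retention-prediction boxes and fragment lists --------------------
    # the tramadol-like isomer trio: true candidate in box 1, decoys spread
    boosted_fid = al_feature_ids.get("tramadol-like-1")
    boxed = {}
    frag_lists: dict[str, list[float]] = {}
    if boosted_fid is not None:
        boxed[boosted_fid] = make_isomer_set(
            "C16H25NO2",
            n_isomers=3,
            n_box=(1, 1, 0, 1),
            n_unpredicted=0,
            names=["tramadol-like-1", "tramadol-like-2", "tramadol-like-3"],
            predicted_rts=[640.0, 700.0, None],
        )
        # fragments of the box-1 candidate reproduce the two most intense
        # measured MS/MS peaks; decoys get non-matching fragments
        feat = next(
            f
            for f in tables["+"][0]
            if f.feature_id == boosted_fid
        )
        assert feat.msms is not None
        top2 = sorted(feat.msms.peaks, key=lambda p: -p[1])[:2]
        frag_lists["tramadol-like-1"] = [m for m, _ in top2]
        frag_lists["tramadol-like-2"] = [m + 0.35 for m, _ in top2]
        frag_lists["tramadol-like-3"] = [m - 0.41 for m, _ in top2]

    ground_truth = GroundTruth(
        spikes=spike_gt,
        spike_feature_ids=[s.feature_id for s in spike_gt],
        planted_sl_feature_ids=sl_feature_ids,
        boosted_feature_id=boosted_fid,
    )
    return SyntheticStudy(
        config=cfg,
        tables=tables,
        hierarchy=hierarchy,
        sample_plate=sample_plate,
        pb_plate=pb_plate,
        boxed_candidates=boxed,
        fragment_lists=frag_lists,
        ground_truth=ground_truth,
    )


def make_isomer_set(
    formula: str,
    n_isomers: int,
    n_box: tuple[int, int, int, int],
    n_unpredicted: int = 0,
    names: list[str] | None = None,
    predicted_rts: list[float | None] | None = None,
) -> list[BoxedCandidate]:
    """Build a boxed-candidate list with a requested box histogram.

    ``n_box`` gives the number of candidates in boxes 1-4; together with
    ``n_unpredicted`` the counts must sum to ``n_isomers``. Used to replay
    published isomer sets and to seed synthetic studies.
    """
    if sum(n_box) + n_unpredicted != n_isomers:
        raise AnnotationError(
            f"box counts {n_box} + {n_unpredicted} unpredicted != {n_isomers} isomers"
        )
    boxes: list[int | None] = []
    for box, count in zip((1, 2, 3, 4), n_box):
        boxes.extend([box] * count)
    boxes.extend([None] * n_unpredicted)
    if names is None:
        names = [f"{formula}_iso{k + 1}" for k in range(n_isomers)]
    if predicted_rts is None:
        predicted_rts = [None if b is None else 60.0 * (k + 1) for k, b in enumerate(boxes)]
    return [
        BoxedCandidate(name=n, predicted_rt=rt, box=b)
        for n, rt, b in zip(names, predicted_rts, boxes)
    ]


# ---------------------------------------------------------------------------
# on-disk study layout
# ---------------------------------------------------------------------------


def write_study(study: SyntheticStudy, outdir: str | Path) -> None:
    """Write the study in the CSV/MGF/MSP dialects the pipeline reads,
    plus a ``study.json`` manifest with the seed and ground truth."""
    from .features import write_feature_table, write_suspect_list
    from .spectra import write_mgf, write_msp

    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    for mode, per_injection in study.tables.items():
        tag = "pos" if mode == "+" else "neg"
        for inj, table in enumerate(per_injection, start=1):
            write_feature_table(table, out / f"features_{tag}_inj{inj}.csv")
            spectra = []
            for f in table:
                if f.msms is not None:
                    meta = dict(f.msms.metadata)
                    meta["title"] = f.feature_id
                    spectra.append(
                        MsMsSpectrum(f.msms.precursor_mz, f.msms.peaks, mode, meta)
                    )
            if spectra and inj == 1:
                write_mgf(spectra, out / f"msms_{tag}.mgf")
    for slist in study.hierarchy:
        write_suspect_list(slist, out / f"suspects_{slist.name}.csv")
        spectra = [
            spec
            for entry in slist
            for spec in entry.library_spectra
        ]
        if spectra:
            write_msp(spectra, out / f"library_{slist.name}.msp")
    study.sample_plate.to_csv(out / "plate_growth.csv", index=False)
    study.pb_plate.to_csv(out / "plate_growth_pb.csv", index=False)
    if study.boxed_candidates:
        rows = [
            dict(
                feature_id=fid,
                candidate=c.name,
                predicted_rt_s=c.predicted_rt,
                box=c.box,
            )
            for fid, cands in study.boxed_candidates.items()
            for c in cands
        ]
        pd.DataFrame(rows).to_csv(out / "boxed_candidates.csv", index=False)
    if study.fragment_lists:
        rows = [
            dict(candidate=name, fragment_mz=mz)
            for name, mzs in study.fragment_lists.items()
            for mz in mzs
        ]
        pd.DataFrame(rows).to_csv(out / "fragments.csv", index=False)
    manifest = {
        "seed": study.config.seed,
        "n_injections": study.config.n_injections,
        "fraction_duration_s": study.config.fraction_duration,
        "margin_s": study.config.margin,
        "ground_truth": {
            "spikes": [asdict(s) for s in study.ground_truth.spikes],
            "spike_feature_ids": study.ground_truth.spike_feature_ids,
            "planted_sl_feature_ids": study.ground_truth.planted_sl_feature_ids,
            "boosted_feature_id": study.ground_truth.boosted_feature_id,
        },
    }
    (out / "study.json").write_text(json.dumps(manifest, indent=2))
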