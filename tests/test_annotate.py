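"""Suspect matching, TAQ codes, confidence levels, reduction, and boosting."""

import itertools

import pytest
from hypothesis import given, strategies as st

from edascreen.annotate import (
    Annotation,
    AnnotationError,
    BoxedCandidate,
    ConfidenceLevel,
    MatchEvidence,
    Thresholds,
    annotate_table,
    assign_level,
    boost_level,
    count_isomers,
    match_feature,
    reduce_candidates,
    taq_code,
)
from edascreen.chem import adduct_mz, isotope_pattern, parse_formula
from edascreen.features import Feature, FeatureTable, SuspectEntry, SuspectList
from edascreen.spectra import FragmentMatchResult, MsMsSpectrum


def evidence(ppm=3.0, rt=0.05, msig=20.0, score=None, recorded=True, blank=True, cv=True):
    return MatchEvidence(
        ppm_error=ppm,
        adduct="[M+H]+",
        rt_dev=rt,
        msigma=msig,
        msms_score=score,
        msms_recorded=recorded,
        blank_pass=blank,
        cv_pass=cv,
    )


class TestMatchFeature:
    FORMULA = parse_formula("C16H25NO2")

    def suspect(self, **kw):
        defaults = dict(
            name="s", formula=self.FORMULA, list_class="AL+",
            expected_rt=120.0, adducts=["[M+H]+"],
        )
        defaults.update(kw)
        return SuspectEntry(**defaults)

    def feature(self, ppm_off=3.0, rt=123.0):
        mz = adduct_mz(self.FORMULA, "[M+H]+") * (1 + ppm_off * 1e-6)
        return Feature("F1", "+", mz, rt, [1000.0], blank_intensity=0.0)

    def test_in_tolerance_match(self):
        ev = match_feature(self.feature(3.0, 123.0), self.suspect())
        assert ev is not None
        assert ev.ppm_error == pytest.approx(3.0, abs=0.01)
        assert ev.rt_dev == pytest.approx(3.0 / 60.0)

    def test_out_of_tolerance_no_match(self):
        assert match_feature(self.feature(15.0), self.suspect()) is None

    def test_no_expected_rt_gives_absent_rt_dev(self):
        ev = match_feature(self.feature(), self.suspect(expected_rt=None))
        assert ev is not None and ev.rt_dev is None

    def test_polarity_filter(self):
        # positive-mode feature cannot match a negative-only suspect
        assert match_feature(self.feature(), self.suspect(adducts=["[M-H]-"])) is None

    def test_msigma_computed_from_envelope(self):
        feat = self.feature()
        feat.isotope_envelope = isotope_pattern(self.FORMULA)
        ev = match_feature(feat, self.suspect())
        assert ev is not None and ev.msigma == pytest.approx(0.0, abs=1e-9)


class TestTaqCode:
    def test_strict_standard_evidence(self):
        # mass < 5 ppm, RT < 0.1 min, isotope fit < 25: strict tiers, with
        # MS/MS recorded but no library match
        assert taq_code(evidence()) == "222122"

    def test_all_strict(self):
        assert taq_code(evidence(score=800.0)) == "222222"

    def test_loose_tiers_and_not_evaluable(self):
        ev = evidence(ppm=8.0, rt=None, msig=80.0, recorded=False, blank=None, cv=None)
        assert taq_code(ev) == "1-10--"

    def test_failing_tiers(self):
        ev = evidence(ppm=12.0, rt=0.5, msig=300.0, recorded=True, blank=False, cv=False)
        assert taq_code(ev) == "000100"

    @pytest.mark.parametrize(
        "ppm, sym", [(4.99, "2"), (5.0, "2"), (5.01, "1"), (10.0, "1"), (10.01, "0")]
    )
    def test_mass_tier_boundaries(self, ppm, sym):
        assert taq_code(evidence(ppm=ppm))[0] == sym


class TestAssignLevel:
    def test_standard_without_library_spectrum_is_2b(self):
        # the spiked-antibiotic situation: strict mass/RT/isotope evidence
        # from an in-house standard whose list has no MS/MS spectra
        assert assign_level("222122", "AL+", True) == "2b"

    def test_standard_with_library_match_is_1(self):
        assert assign_level("222222", "AL+", True) == "1"

    def test_spectral_library_match_is_2a(self):
        assert assign_level("2-2222", "SL", False) == "2a"

    def test_formula_with_msms_recorded_is_4star(self):
        assert assign_level("2-2122", "AL", False) == "4*"

    def test_formula_without_msms_is_4(self):
        assert assign_level("2-2022", "AL", False) == "4"

    def test_mass_only_is_5(self):
        assert assign_level("2--0--", "AL", False) == "5"
        assert assign_level("2-00--", "AL", False) == "5"

    def test_failed_rt_demotes_standard(self):
        # negative RT evidence drops AL+ to the generic formula rules
        assert assign_level("202122", "AL+", True) == "4*"

    def test_sl_without_spectral_match_falls_through(self):
        assert assign_level("2-2122", "SL", False) == "4*"

    def test_level_ordering(self):
        order = ["1", "2a", "2b", "3", "4*", "4", "5"]
        for better, worse in zip(order, order[1:]):
            assert ConfidenceLevel(better).better_than(ConfidenceLevel(worse))

    def test_evidence_upgrade_never_lowers_level(self):
        # upgrading any single TAQ symbol (0->1->2 or '-'->2) is monotone
        upgrades = {"0": ["1", "2"], "1": ["2"], "-": ["2"]}
        symbols = "210-"
        for cls in ("SL", "AL", "AL+"):
            for code in itertools.product(symbols, repeat=4):
                taq = "".join(code) + "22"
                base = assign_level(taq, cls, True)
                for pos in range(4):
                    for up in upgrades.get(taq[pos], []):
                        upgraded = taq[:pos] + up + taq[pos + 1 :]
                        lifted = assign_level(upgraded, cls, True)
                        assert lifted.rank <= base.rank, (cls, taq, upgraded)


class TestAnnotateTable:
    FORMULA = parse_formula("C9H13NO3")

    def _table_and_lists(self):
        mz = adduct_mz(self.FORMULA, "[M+H]+")
        msms = MsMsSpectrum(mz, ((81.0, 100.0), (107.0, 40.0)), "+")
        feat = Feature(
            "F1", "+", mz, 300.0, [1000.0, 990.0, 1010.0],
            blank_intensity=0.0, msms=msms,
            isotope_envelope=isotope_pattern(self.FORMULA),
        )
        table = FeatureTable([feat], ion_mode="+", n_injections=3)
        sl = SuspectList(
            "library",
            [SuspectEntry("libA", self.FORMULA, "SL",
                          library_spectra=[msms], adducts=["[M+H]+"])],
            rank=1,
        )
        al = SuspectList(
            "database",
            [SuspectEntry("dbA", self.FORMULA, "AL", adducts=["[M+H]+"])],
            rank=2,
        )
        return table, [sl, al]

    def test_primary_is_best_level(self):
        table, lists = self._table_and_lists()
        anns = annotate_table(table, lists)
        primary = [a for a in anns if a.primary]
        assert len(primary) == 1
        assert primary[0].level == "2a" and primary[0].suspect == "libA"
        alternates = [a for a in anns if not a.primary]
        assert {a.level for a in alternates} == {"4*"}

    def test_unmatched_feature_is_level_5(self):
        table, _ = self._table_and_lists()
        decoy = SuspectList(
            "decoys", [SuspectEntry("far", parse_formula("C40H80O2"), "AL")], rank=1
        )
        anns = annotate_table(table, [decoy])
        assert len(anns) == 1
        assert anns[0].level == "5" and anns[0].suspect is None and anns[0].primary

    def test_hierarchy_order_invariance(self):
        table, lists = self._table_and_lists()
        a = annotate_table(table, lists)
        b = annotate_table(table, list(reversed(lists)))
        assert [(x.suspect, x.level, x.primary) for x in a] == [
            (x.suspect, x.level, x.primary) for x in b
        ]

    def test_tightening_thresholds_never_adds_annotations(self, study, merged_tables):
        loose = Thresholds()
        tight = Thresholds(ppm=5.0, rt_min=0.1, msigma_max=25.0, msms_score=800.0)
        for table in merged_tables.values():
            n_loose = sum(
                1 for a in annotate_table(table, study.hierarchy, loose) if a.suspect
            )
            n_tight = sum(
                1 for a in annotate_table(table, study.hierarchy, tight) if a.suspect
            )
            assert n_tight <= n_loose


class TestCountIsomers:
    def test_counts(self):
        f1 = parse_formula("C9H13NO3")
        f2 = parse_formula("C8H10O3S")
        entries = [
            SuspectEntry("a", f1, "AL"),
            SuspectEntry("b", f1, "AL"),
            SuspectEntry("c", f1, "AL"),
            SuspectEntry("d", f2, "AL"),
        ]
        slist = SuspectList("db", entries)
        assert count_isomers(entries[0], slist) == 3
        assert count_isomers(entries[3], slist) == 1

    def test_empty_list_rejected(self):
        with pytest.raises(AnnotationError):
            count_isomers(
                SuspectEntry("x", parse_formula("CH4"), "AL"),
                SuspectList("empty", []),
            )


class TestReduceCandidates:
    @staticmethod
    def boxed(n_box, n_unpredicted=0):
        out = []
        k = 0
        for box, count in zip((1, 2, 3, 4), n_box):
            for _ in range(count):
                k += 1
                out.append(BoxedCandidate(f"c{k}", 60.0 * k, box))
        for _ in range(n_unpredicted):
            k += 1
            out.append(BoxedCandidate(f"c{k}", None, None))
        return out

    def test_quarter_reduction(self):
        # 8 isomers, 6 in box 1, none in box 4 -> 1 - 6/8
        r = reduce_candidates(self.boxed((6, 2, 0, 0)))
        assert r.reduction_fraction == pytest.approx(0.25)
        assert len(r.kept) == 6

    def test_full_reduction(self):
        # 10 isomers, none in box 1, one box-4 outlier -> 1 - 0/9
        r = reduce_candidates(self.boxed((0, 5, 4, 1)))
        assert r.reduction_fraction == pytest.approx(1.0)
        assert len(r.reconsider) == 1

    def test_unpredicted_stay_in_denominator(self):
        r = reduce_candidates(self.boxed((3, 4, 1, 7), n_unpredicted=0))
        assert r.reduction_fraction == pytest.approx(1 - 3 / 8)
        r2 = reduce_candidates(self.boxed((4, 3, 0, 1), n_unpredicted=2))
        assert r2.reduction_fraction == pytest.approx(1 - 4 / 9)

    def test_all_box4_undefined(self):
        r = reduce_candidates(self.boxed((0, 0, 0, 3)))
        assert r.reduction_fraction is None and not r.defined
        assert len(r.reconsider) == 3

    def test_empty_rejected(self):
        with pytest.raises(AnnotationError):
            reduce_candidates([])


class TestBoostLevel:
    @staticmethod
    def annotation(level="4*"):
        return Annotation(
            feature_id="F1", ion_mode="+", mz=250.18, rt=120.0,
            mean_intensity=1e5, suspect="cand", list_name="db", list_class="AL",
            evidence=evidence(), taq="2-2122", level=ConfidenceLevel(level),
        )

    @staticmethod
    def frag(n):
        return FragmentMatchResult(5, n, (), 0.5 if n else 0.0)

    def test_box1_with_two_fragments_boosts(self):
        assert boost_level(self.annotation(), 1, self.frag(2)) == "3"

    def test_wrong_box_unchanged(self):
        assert boost_level(self.annotation(), 3, self.frag(5)) == "4*"

    def test_no_fragments_unchanged(self):
        assert boost_level(self.annotation(), 1, self.frag(0)) == "4*"

    def test_non_4star_rejected(self):
        with pytest.raises(AnnotationError):
            boost_level(self.annotation("4"), 1, self.frag(2))


@given(
    ppm=st.floats(-10, 10),
    rt=st.one_of(st.none(), st.floats(0, 0.3)),
    msig=st.one_of(st.none(), st.floats(0, 150)),
)
def test_taq_alphabet_and_length(ppm, rt, msig):
    code = taq_code(evidence(ppm=ppm, rt=rt, msig=msig))
    assert len(code) == 6
    assert set(code) <= set("210-")
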