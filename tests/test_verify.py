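"""Score/presence filtering and the diagnostic-ion rule engine."""

import pytest

from conftest import make_candidate, make_spectrum

from glycoforms import masscalc
from glycoforms.glycospace import parse_composition
from glycoforms.verify import (
    IdentifiedGlycopeptide,
    MissingSpectrumError,
    Ms2Spectrum,
    ToleranceConfig,
    filter_by_score_and_presence,
    read_ids_tsv,
    read_mgf,
    run_verification,
    surrogate_score,
    verify_diagnostic_ions,
)


def _id(sample, injection, score, comp="HexNAc(4)Hex(3)Fuc(1)", spec_id="x"):
    return IdentifiedGlycopeptide(
        sample_id=sample,
        injection_id=injection,
        peptide=make_candidate("EDYNSTIR"),
        comp=parse_composition(comp),
        score=score,
        spectrum_id=spec_id,
    )


class TestScorePresenceFilter:
    def test_one_qualifying_injection_retains_all_observations(self):
        ids = [_id("s1", 1, 310.0), _id("s1", 2, 120.0)]
        kept = filter_by_score_and_presence(ids, threshold=300, min_injections=1)
        assert len(kept) == 2  # low-score observation kept for quantitation

    def test_threshold_is_strict(self):
        ids = [_id("s1", 1, 300.0)]
        assert filter_by_score_and_presence(ids, threshold=300) == []
        assert len(filter_by_score_and_presence(ids, threshold=299.999)) == 1

    def test_min_injections_counts_distinct_injections(self):
        ids = [_id("s1", 1, 400.0), _id("s1", 1, 410.0), _id("s1", 2, 100.0)]
        assert filter_by_score_and_presence(ids, 300, min_injections=2) == []
        ids.append(_id("s1", 2, 350.0))
        assert len(filter_by_score_and_presence(ids, 300, min_injections=2)) == 4

    def test_samples_filtered_independently(self):
        ids = [_id("s1", 1, 400.0), _id("s2", 1, 100.0)]
        kept = filter_by_score_and_presence(ids, 300)
        assert {g.sample_id for g in kept} == {"s1"}

    def test_empty_input(self):
        assert filter_by_score_and_presence([], 300) == []


class TestDiagnosticIons:
    def test_clean_fucosylated_passes(self):
        gp, spec = make_spectrum("EDYNSTIR", "HexNAc(4)Hex(3)Fuc(1)")
        report = verify_diagnostic_ions(gp, spec)
        assert report.verdict and report.failed_rules == ()

    def test_missing_neu5gc_pair_member_fails_with_rule_named(self):
        gp, spec = make_spectrum(
            "EDYNSTIR",
            "HexNAc(4)Hex(5)Fuc(1)NeuGc(1)",
            drop_ions=("neu5gc_oxonium",),  # 308 absent, 290 present
        )
        report = verify_diagnostic_ions(gp, spec)
        assert not report.verdict
        assert report.failed_rules == ("neu5gc_pair",)

    def test_neu5ac_needs_both_oxonium_ions(self):
        gp, spec = make_spectrum(
            "EDYNSTIR",
            "HexNAc(4)Hex(5)NeuAc(1)",
            drop_ions=("neu5ac_oxonium_minus_water",),
        )
        assert verify_diagnostic_ions(gp, spec).failed_rules == ("neu5ac_pair",)

    def test_antenna_fucose_ion_substitutes_for_core(self):
        antenna = masscalc.diagnostic_ion_mz("antenna_fuc")
        gp, spec = make_spectrum(
            "EDYNSTIR",
            "HexNAc(4)Hex(3)Fuc(1)",
            drop_ions=("Y1_fuc",),
            extra_peaks=((antenna, 500.0),),
        )
        assert verify_diagnostic_ions(gp, spec).verdict

    def test_fucosylated_without_any_fucose_ion_fails(self):
        gp, spec = make_spectrum(
            "EDYNSTIR", "HexNAc(4)Hex(3)Fuc(1)", drop_ions=("Y1_fuc",)
        )
        assert verify_diagnostic_ions(gp, spec).failed_rules == ("fucose",)

    def test_asialo_afucosyl_needs_only_y1(self):
        gp, spec = make_spectrum("EDYNSTIR", "HexNAc(4)Hex(3)")
        report = verify_diagnostic_ions(gp, spec)
        assert report.verdict
        assert [c.rule for c in report.rules_checked] == ["Y1"]

    def test_missing_y1_always_fails(self):
        gp, spec = make_spectrum("EDYNSTIR", "HexNAc(4)Hex(3)", drop_ions=("Y1",))
        assert verify_diagnostic_ions(gp, spec).failed_rules == ("Y1",)

    def test_y1_matched_at_charge_two(self):
        pep_mass = masscalc.peptide_mass(
            "EDYNSTIR", masscalc.ModificationSet.default()
        )
        y1_z2 = (pep_mass + masscalc._DEFAULT_SUGARS["HexNAc"] + 2 * masscalc.PROTON) / 2
        gp, spec = make_spectrum(
            "EDYNSTIR",
            "HexNAc(4)Hex(3)",
            drop_ions=("Y1",),
            extra_peaks=((y1_z2, 900.0),),
        )
        report = verify_diagnostic_ions(gp, spec)
        assert report.verdict
        assert report.rules_checked[0].charge == 2

    def test_verdict_invariant_under_intensity_rescaling(self):
        gp, spec = make_spectrum("EDYNSTIR", "HexNAc(4)Hex(5)Fuc(1)NeuGc(2)")
        scaled = Ms2Spectrum(
            spectrum_id=spec.spectrum_id,
            precursor_mz=spec.precursor_mz,
            precursor_charge=spec.precursor_charge,
            peaks=tuple((mz, i * 1e4) for mz, i in spec.peaks),
        )
        assert (
            verify_diagnostic_ions(gp, spec).verdict
            == verify_diagnostic_ions(gp, scaled).verdict
        )

    def test_tightening_tolerance_never_rescues_a_fail(self):
        gp, spec = make_spectrum(
            "EDYNSTIR", "HexNAc(4)Hex(5)Fuc(1)NeuGc(1)", drop_ions=("neu5gc_oxonium",)
        )
        for ppm in (100.0, 30.0, 10.0, 1.0):
            tol = ToleranceConfig(tol_ppm=ppm, abs_floor_da=1e-4)
            assert not verify_diagnostic_ions(gp, spec, tol).verdict

    def test_spectrum_mismatch_is_an_error_not_a_fail(self):
        gp, spec = make_spectrum("EDYNSTIR", "HexNAc(4)Hex(3)")
        wrong = Ms2Spectrum(
            spectrum_id="other",
            precursor_mz=spec.precursor_mz,
            precursor_charge=2,
            peaks=spec.peaks,
        )
        with pytest.raises(MissingSpectrumError):
            verify_diagnostic_ions(gp, wrong)


class TestRunVerification:
    def test_all_clean_batch_passes_unchanged(self):
        pairs = [
            make_spectrum("EDYNSTIR", c, spectrum_id=f"s{i}")
            for i, c in enumerate(
                ["HexNAc(4)Hex(3)Fuc(1)", "HexNAc(4)Hex(5)Fuc(1)NeuGc(2)", "HexNAc(4)Hex(4)"]
            )
        ]
        ids = [gp for gp, _ in pairs]
        spectra = {s.spectrum_id: s for _, s in pairs}
        accepted, audit = run_verification(ids, spectra, score_min=300)
        assert len(accepted) == 3 and audit == []

    def test_targeted_ion_deletion_rejects_exactly_that_id(self):
        ok, ok_spec = make_spectrum(
            "EDYNSTIR", "HexNAc(4)Hex(5)Fuc(1)NeuGc(1)", spectrum_id="ok"
        )
        bad, bad_spec = make_spectrum(
            "EDYNSTIR",
            "HexNAc(4)Hex(5)NeuAc(1)",
            spectrum_id="bad",
            drop_ions=("neu5ac_oxonium",),  # 292.10 stripped
        )
        accepted, audit = run_verification([ok, bad], [ok_spec, bad_spec])
        assert [g.spectrum_id for g in accepted] == ["ok"]
        assert len(audit) == 1
        assert audit[0]["reason"] == "diagnostic_ion"
        assert audit[0]["failed_rules"] == ["neu5ac_pair"]

    def test_order_independence(self):
        pairs = [
            make_spectrum("EDYNSTIR", "HexNAc(4)Hex(3)Fuc(1)", spectrum_id=f"s{i}")
            for i in range(5)
        ]
        ids = [gp for gp, _ in pairs]
        spectra = {s.spectrum_id: s for _, s in pairs}
        fwd, _ = run_verification(ids, spectra)
        rev, _ = run_verification(ids[::-1], spectra)
        assert fwd == rev

    def test_dangling_spectrum_enumerated_run_continues(self):
        gp1, spec1 = make_spectrum("EDYNSTIR", "HexNAc(4)Hex(3)", spectrum_id="a")
        gp2, _ = make_spectrum("EDYNSTIR", "HexNAc(4)Hex(4)", spectrum_id="gone")
        accepted, audit = run_verification([gp1, gp2], [spec1])
        assert [g.spectrum_id for g in accepted] == ["a"]
        assert audit[0]["reason"] == "missing_spectrum"

    def test_score_rejections_audited(self, tmp_path):
        gp, spec = make_spectrum("EDYNSTIR", "HexNAc(4)Hex(3)")
        low = IdentifiedGlycopeptide(
            sample_id="s",
            injection_id=1,
            peptide=gp.peptide,
            comp=gp.comp,
            score=10.0,
            spectrum_id=spec.spectrum_id,
        )
        path = tmp_path / "audit.jsonl"
        accepted, audit = run_verification([low], [spec], audit_path=path)
        assert accepted == []
        assert audit[0]["reason"] == "score_or_presence"
        assert path.read_text().count("\n") == 1


class TestSurrogateScore:
    def test_ladder_rich_spectrum_outscores_sparse(self, edynstir_mass):
        proton = masscalc.PROTON
        hexnac = masscalc._DEFAULT_SUGARS["HexNAc"]
        hexose = masscalc._DEFAULT_SUGARS["Hex"]
        comp = parse_composition("HexNAc(4)Hex(3)")
        ladder = [edynstir_mass + proton, edynstir_mass + hexnac + proton]
        acc = edynstir_mass + 2 * hexnac
        for _ in range(3):
            acc += hexose
            ladder.append(acc + proton)
        rich = Ms2Spectrum("r", 1200.0, 2, tuple((m, 100.0) for m in sorted(ladder)))
        sparse = Ms2Spectrum("r", 1200.0, 2, ((ladder[1], 100.0),))
        s_rich = surrogate_score("EDYNSTIR", comp, rich)
        s_sparse = surrogate_score("EDYNSTIR", comp, sparse)
        assert s_rich > s_sparse > 0

    def test_no_matches_scores_zero(self):
        spec = Ms2Spectrum("z", 1200.0, 2, ((400.0, 10.0), (401.0, 5.0)))
        assert surrogate_score("EDYNSTIR", parse_composition("HexNAc(4)Hex(3)"), spec) == 0.0


class TestIO:
    def test_mgf_roundtrip(self, tmp_path):
        from glycoforms.synthetic import write_mgf

        _, spec = make_spectrum("EDYNSTIR", "HexNAc(4)Hex(3)Fuc(1)", spectrum_id="rt1")
        path = tmp_path / "one.mgf"
        write_mgf([spec], path)
        back = read_mgf(path)
        assert len(back) == 1
        assert back[0].spectrum_id == "rt1"
        assert back[0].precursor_charge == spec.precursor_charge
        assert back[0].precursor_mz == pytest.approx(spec.precursor_mz, abs=1e-5)
        assert len(back[0].peaks) == len(spec.peaks)

    def test_ids_tsv_import(self, tmp_path):
        path = tmp_path / "ids.tsv"
        path.write_text(
            "sample\tinjection\tpeptide\tcomposition\tscore\tspectrum_id\tintensity\n"
            "s1\t1\tEDYNSTIR\tHexNAc(4)Hex(3)Fuc(1)\t350.5\tspec1\t1e5\n"
        )
        ids = read_ids_tsv(path)
        assert len(ids) == 1
        assert ids[0].comp.fuc == 1 and ids[0].score == 350.5
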