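"""MS1 matching, intensity filtering and MS/MS validation rules."""
import pytest

from polarlipid.annotation import (MS1Feature, MS2Spectrum, RTWindow,
                                   assemble_identifications,
                                   expected_fragments, filter_features,
                                   match_ms1, ms2_channels, ppm_error,
                                   validate_hits, validate_ms2)
from polarlipid.chem import (ATOMIC_MASS, ELECTRON_MASS, AcylChain, adduct_mz,
                             make_species, monoisotopic_mass)


def _feat(mz, rt=18.0, area=1e6, intensity=1e5, sample="CM_1"):
    return MS1Feature(mz=mz, rt=rt, area=area, raw_intensity=intensity,
                      sample_id=sample)


@pytest.mark.parametrize("obs, theo, expected", [
    (500.0025, 500.0, 5.0),
    (123.456, 123.456, 0.0),
    (759.998, 760.0, -2.6316),
])
def test_ppm_error(obs, theo, expected):
    assert ppm_error(obs, theo) == pytest.approx(expected, abs=1e-3)


def test_intensity_floor_boundary_kept():
    feats = [_feat(500.0, intensity=i) for i in (9999, 10000, 10001)]
    kept = filter_features(feats, 1e4)
    assert [f.raw_intensity for f in kept] == [10000, 10001]
    assert filter_features(feats, 0) == feats
    assert filter_features([], 1e4) == []


class TestMatchMS1:
    def test_single_match_inside_window(self, rt_windows):
        sp = make_species("MGDG", chains=[AcylChain(20, 5), AcylChain(20, 5)])
        hits = match_ms1([_feat(sp.quant_mz(), rt=2.1)], [sp],
                         rt_windows=rt_windows)
        assert len(hits) == 1
        assert hits[0].adduct == "[M+NH4]+"
        assert abs(hits[0].ppm_error) < 1e-9

    def test_rt_outside_window_excluded(self, rt_windows):
        sp = make_species("MGDG", chains=[AcylChain(20, 5), AcylChain(20, 5)])
        assert match_ms1([_feat(sp.quant_mz(), rt=7.0)], [sp],
                         rt_windows=rt_windows) == []

    def test_isobars_both_kept(self, rt_windows):
        # PC 34:1 via two different chain pairs: identical mass, same window
        a = make_species("PC", chains=[AcylChain(16, 0), AcylChain(18, 1)])
        b = make_species("PC", chains=[AcylChain(14, 0), AcylChain(20, 1)])
        hits = match_ms1([_feat(a.quant_mz(), rt=24.0)], [a, b],
                         rt_windows=rt_windows)
        assert {h.species.name for h in hits} == {a.name, b.name}

    def test_missing_window_names_class(self):
        sp = make_species("PG", chains=[AcylChain(16, 0), AcylChain(20, 5)])
        with pytest.raises(ValueError, match="PG"):
            match_ms1([_feat(sp.quant_mz())], [sp], rt_windows={})

    def test_shrinking_tolerance_never_adds_hits(self, library, rt_windows):
        feats = [_feat(sp.quant_mz() * (1 + 3e-6),
                       rt=rt_windows[sp.class_code].center)
                 for sp in library[::5]]
        counts = [len(match_ms1(feats, library, tol, rt_windows))
                  for tol in (5.0, 3.5, 2.0, 1.0)]
        assert counts == sorted(counts, reverse=True)


class TestExpectedFragments:
    def test_epa_carboxylate(self):
        sp = make_species("PG", chains=[AcylChain(16, 0), AcylChain(20, 5)])
        frags = {f.label: f for f in expected_fragments(sp)}
        assert frags["RCOO- 20:5"].value == pytest.approx(301.2173, abs=5e-4)
        assert not frags["RCOO- 20:5"].is_neutral_loss

    def test_ketene_loss_16_0(self):
        sp = make_species("DGTS", chains=[AcylChain(16, 0), AcylChain(20, 5)])
        frags = {f.label: f for f in expected_fragments(sp)}
        ket = frags["ketene loss 16:0"]
        assert ket.is_neutral_loss
        assert ket.value == pytest.approx(256.24023 - 18.010565, abs=5e-4)

    def test_acylium_plus_74_14_0(self):
        sp = make_species("MGDG", chains=[AcylChain(14, 0), AcylChain(20, 5)])
        frags = {f.label: f for f in expected_fragments(sp)}
        # independent summation: acylium = FA - OH - e; increment = C3H6O2
        fa = monoisotopic_mass("C14H28O2")
        expected = (fa - monoisotopic_mass("OH") - ELECTRON_MASS
                    + monoisotopic_mass("C3H6O2"))
        assert frags["[RCO+74]+ 14:0"].value == pytest.approx(expected,
                                                              abs=5e-4)

    def test_picer_has_no_chain_requirement(self):
        sp = make_species("PI-Cer", chains=[AcylChain(16, 0)])
        groups = {f.group for f in expected_fragments(sp)}
        assert groups == {"headgroup"}


def _spectrum_for(species, parts=("headgroup", "chains"), polarity=None,
                  adduct=None, extra=(), drop=()):
    """Build a synthetic MS2 spectrum carrying the species' diagnostics."""
    channels = ms2_channels(species)
    part0 = parts[0]
    add, pol = channels[part0]
    if adduct:
        add = adduct
    if polarity:
        pol = polarity
    prec = adduct_mz(species.neutral_mass, add)
    peaks = list(extra)
    for f in expected_fragments(species):
        part = "headgroup" if f.group == "headgroup" else "chains"
        if part not in parts or f.label in drop:
            continue
        mz = prec - f.value if f.is_neutral_loss else f.value
        peaks.append((mz, 1e4))
    return MS2Spectrum(precursor_mz=prec, rt=18.0,
                       peaks=tuple(sorted(peaks)), polarity=pol)


class TestValidateMS2:
    @pytest.fixture()
    def pg(self):
        return make_species("PG", chains=[AcylChain(16, 0), AcylChain(20, 5)])

    def _hit(self, sp):
        return match_ms1([_feat(sp.quant_mz(), rt=18.0)], [sp],
                         rt_windows={"PG": RTWindow("PG", 18.0, 1.0)})[0]

    def test_full_spectrum_confirms_both(self, pg):
        hit = validate_ms2(self._hit(pg), _spectrum_for(pg))
        assert hit.ms2_status == "confirmed_both"

    def test_chains_only(self, pg):
        hit = validate_ms2(self._hit(pg), _spectrum_for(pg, parts=("chains",)))
        assert hit.ms2_status == "confirmed_chains"

    def test_headgroup_only(self, pg):
        hit = validate_ms2(self._hit(pg),
                           _spectrum_for(pg, parts=("headgroup",)))
        assert hit.ms2_status == "confirmed_headgroup"

    def test_empty_spectrum_leaves_ms1_only(self, pg):
        empty = MS2Spectrum(precursor_mz=pg.quant_mz(), rt=18.0, peaks=(),
                            polarity="-")
        assert validate_ms2(self._hit(pg), empty).ms2_status == "ms1_only"

    def test_polarity_mismatch_ignored(self, pg):
        wrong = _spectrum_for(pg, polarity="+")
        hit = validate_ms2(self._hit(pg), wrong)
        assert hit.ms2_status == "ms1_only"
        assert not hit.ms2_seen

    def test_one_chain_missing_blocks_chain_confirmation(self, pg):
        spec = _spectrum_for(pg, drop=("RCOO- 16:0",))
        assert validate_ms2(self._hit(pg), spec).ms2_status \
            == "confirmed_headgroup"

    def test_pc_chains_only_from_acetate_channel(self):
        pc = make_species("PC", chains=[AcylChain(16, 0), AcylChain(20, 5)])
        hit = match_ms1([_feat(pc.quant_mz(), rt=24.0)], [pc],
                        rt_windows={"PC": RTWindow("PC", 24.0, 1.0)})[0]
        # carboxylate peaks planted into the positive headgroup channel
        pos = _spectrum_for(pc, parts=("headgroup",),
                            extra=[(f.value, 1e4)
                                   for f in expected_fragments(pc)
                                   if f.group != "headgroup"])
        assert validate_ms2(hit, pos).ms2_status == "confirmed_headgroup"
        neg = _spectrum_for(pc, parts=("chains",))
        hit = validate_ms2(hit, pos)
        hit = validate_ms2(hit, neg)
        assert hit.ms2_status == "confirmed_both"


class TestAssemble:
    def test_tiebreak_smallest_ppm_wins(self, rt_windows):
        sp = make_species("PG", chains=[AcylChain(16, 0), AcylChain(20, 5)])
        mz = sp.quant_mz()
        feats = [_feat(mz * (1 - 1.2e-6), rt=18.0),
                 _feat(mz * (1 + 3.4e-6), rt=18.0)]
        hits = match_ms1(feats, [sp], rt_windows=rt_windows)
        table = assemble_identifications(hits, rt_windows, require_ms2=False)
        assert len(table) == 1
        assert table["ppm_error"].iloc[0] == pytest.approx(-1.2, abs=1e-6)

    def test_all_decoys_yield_empty_table(self, library, rt_windows):
        decoys = [_feat(sp.quant_mz() * (1 + 40e-6),
                        rt=rt_windows[sp.class_code].center)
                  for sp in library[:30]]
        hits = match_ms1(decoys, library, rt_windows=rt_windows)
        assert hits == []
        assert assemble_identifications(hits, rt_windows).empty

    def test_species_with_ms2_must_be_fully_confirmed(self, rt_windows):
        sp = make_species("PG", chains=[AcylChain(16, 0), AcylChain(20, 5)])
        hits = match_ms1([_feat(sp.quant_mz(), rt=18.0)], [sp],
                         rt_windows=rt_windows)
        partial = _spectrum_for(sp, parts=("headgroup",))
        validated = validate_hits(hits, [partial])
        assert assemble_identifications(validated, rt_windows).empty
        full = _spectrum_for(sp)
        validated = validate_hits(hits, [full])
        table = assemble_identifications(validated, rt_windows)
        assert table["species"].tolist() == [sp.name]
        assert table["ms2_status"].tolist() == ["confirmed_both"]


def test_identifications_respect_tolerance_and_windows(default_run):
    ids = default_run["identifications"]
    assert (ids["ppm_error"].abs() <= 5.0).all()
    from polarlipid.simulate import CLASS_RT_CENTERS
    centers = ids["class_code"].map(CLASS_RT_CENTERS)
    assert ((ids["rt"] - centers).abs() <= 1.0).all()


def test_identification_tables_are_deterministic(library):
    from polarlipid import simulate
    from polarlipid.workflow import annotate_dataset
    design = simulate.default_design(seed=7)
    f1, s1, _ = simulate.simulate_lcms(design, library)
    f2, s2, _ = simulate.simulate_lcms(design, library)
    t1 = annotate_dataset(f1, s1, library)
    t2 = annotate_dataset(f2, s2, library)
    assert t1.equals(t2)
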