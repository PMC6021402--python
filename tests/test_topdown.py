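"""Top-down identification: ladders, matching, truncation and PTM localization."""

import numpy as np
import pytest
from hypothesis import given, strategies as st
from pyteomics import mass as pyt_mass
from scipy import stats

from riboforma import (
    PROTON_MASS,
    ProteinSequence,
    Proteoform,
    SearchParams,
    Spectrum,
    absolute_mass_search,
    decoy_fdr,
    generate_ladders,
    infer_terminal_processing,
    localize_unit_shifts,
    match_fragments,
    proteoform_mass,
    proteoform_report,
    shuffle_database,
    zscore_intensities,
)
from riboforma.simulate import (
    SimulationConfig,
    make_fixture_database,
    simulate_fragment_spectrum,
)
from riboforma.topdown import PrSM

from conftest import random_protein


def spectrum_from_ions(ions, intensity=100.0):
    return Spectrum.from_peaks(
        [(ion.theoretical_mz, intensity) for ion in ions], ms_level=2,
        resolution_mode="high",
    )


class TestLadders:
    def test_dipeptide_b1_y1(self, ga_proteoform):
        ions = {(i.series, i.index): i for i in generate_ladders(ga_proteoform)}
        assert ions[("b", 1)].theoretical_mz == pytest.approx(58.02874, abs=1e-3)
        assert ions[("y", 1)].theoretical_mz == pytest.approx(90.05494, abs=1e-3)

    def test_complementarity_identity_dipeptide(self, ga_proteoform):
        ions = {(i.series, i.index): i for i in generate_ladders(ga_proteoform)}
        total = ions[("b", 1)].theoretical_mz + ions[("y", 1)].theoretical_mz
        assert total == pytest.approx(148.08368, abs=1e-3)

    @given(st.text(alphabet="ACDEFGHIKLMNPQRSTVWY", min_size=2, max_size=40))
    def test_complementarity_property(self, seq):
        """b_i + y_{n−i} at 1+ always reconstructs M + 2 protons."""
        p = Proteoform(base=ProteinSequence("x", seq))
        m = proteoform_mass(p)
        ions = {(i.series, i.index): i.theoretical_mz for i in generate_ladders(p)}
        n = len(seq)
        for i in range(1, n):
            assert ions[("b", i)] + ions[("y", n - i)] == pytest.approx(
                m + 2 * PROTON_MASS, abs=1e-6
            )

    def test_localized_modification_shifts_covering_ions_only(self, registry):
        plain_form = Proteoform(base=ProteinSequence("GK", "GK"))
        modded = Proteoform(
            base=plain_form.base,
            modifications=((registry["methylation"], 2),),
        )
        plain = {(i.series, i.index): i.theoretical_mz for i in generate_ladders(plain_form)}
        mod = {(i.series, i.index): i.theoretical_mz for i in generate_ladders(modded)}
        assert mod[("b", 1)] == pytest.approx(plain[("b", 1)], abs=1e-9)
        assert mod[("y", 1)] - plain[("y", 1)] == pytest.approx(14.01565, abs=1e-6)

    def test_unlocalized_modification_leaves_ladders_unshifted(self, ga_proteoform, registry):
        modded = Proteoform(
            base=ga_proteoform.base,
            modifications=((registry["trimethylation"], None),),
        )
        plain = [i.theoretical_mz for i in generate_ladders(ga_proteoform)]
        mod = [i.theoretical_mz for i in generate_ladders(modded)]
        assert mod == pytest.approx(plain)

    def test_agrees_with_pyteomics_oracle(self, rng):
        p = Proteoform(base=random_protein(rng, 10))
        seq = p.base.residues
        ions = {(i.series, i.index): i.theoretical_mz for i in generate_ladders(p)}
        for i in range(1, 10):
            assert ions[("b", i)] == pytest.approx(
                pyt_mass.calculate_mass(sequence=seq[:i], ion_type="b", charge=1),
                abs=1e-3,
            )
            assert ions[("y", i)] == pytest.approx(
                pyt_mass.calculate_mass(sequence=seq[-i:], ion_type="y", charge=1),
                abs=1e-3,
            )


class TestFragmentMatching:
    def test_exact_peak_matches_with_zero_ppm(self, ga_proteoform):
        ions = generate_ladders(ga_proteoform)
        s = spectrum_from_ions(ions)
        matches = match_fragments(ions, s, tol_ppm=10)
        assert len(matches) == 2
        assert all(abs(m.ppm_error) < 1e-6 for m in matches)

    def test_peak_20ppm_off_not_matched_at_10ppm(self, ga_proteoform):
        b1 = [i for i in generate_ladders(ga_proteoform) if (i.series, i.index) == ("b", 1)]
        s = Spectrum.from_peaks([(b1[0].theoretical_mz * (1 + 20e-6), 5.0)], ms_level=2)
        assert match_fragments(b1, s, tol_ppm=10) == []

    def test_empty_spectrum_empty_matches(self, ga_proteoform):
        s = Spectrum(np.array([]), np.array([]), ms_level=2)
        assert match_fragments(generate_ladders(ga_proteoform), s) == []


class TestZScore:
    @pytest.mark.parametrize(
        "intensities,expected",
        [
            ([10.0, 20.0, 30.0], [-1.0, 0.0, 1.0]),  # sample sd (n−1)
            ([7.0], [0.0]),
            ([5.0, 5.0, 5.0], [0.0, 0.0, 0.0]),
        ],
    )
    def test_population_scoring(self, intensities, expected):
        p = Proteoform(base=ProteinSequence("x", "GASPV"))
        ions = generate_ladders(p)[: len(intensities)]
        s = Spectrum.from_peaks(
            [(ion.theoretical_mz, i) for ion, i in zip(ions, intensities)], ms_level=2
        )
        matches = zscore_intensities(match_fragments(ions, s))
        got = [m.z_score for m in sorted(matches, key=lambda m: m.peak_intensity)]
        assert got == pytest.approx(sorted(expected), abs=1e-9)


@pytest.fixture()
def three_protein_db(rng):
    db = [random_protein(rng, 90, f"P{i}") for i in range(3)]
    # give P1 a transit-peptide-like N-terminus: 58 small residues (~4.3 kDa),
    # so its removal stays inside a 5 kDa precursor window
    transit = "".join(rng.choice(list("GAST"), size=58))
    db[1] = ProteinSequence("P1", transit + db[1].residues[58:])
    return db


class TestAbsoluteMassSearch:
    def test_nterm_processed_protein_found_via_y_ions(self, three_protein_db):
        truth = Proteoform(base=three_protein_db[1], start_index=59)
        cfg = SimulationConfig(seed=11, fragment_coverage=1.0)
        s, precursor, _ = simulate_fragment_spectrum(truth, cfg)
        hits = absolute_mass_search(
            precursor, s, three_protein_db, SearchParams(precursor_window=5000)
        )
        assert hits[0].proteoform.base.identifier == "P1"
        # N-terminus processed: support comes (almost) exclusively from y ions
        assert hits[0].cterm_coverage >= 20
        assert hits[0].nterm_coverage <= 1  # chance coincidences only
        removed = (
            three_protein_db[1].backbone_mass() - proteoform_mass(truth)
        )
        assert hits[0].mass_delta == pytest.approx(-removed, abs=1.0)

    def test_tight_window_returns_only_exact_candidate(self, three_protein_db):
        cfg = SimulationConfig(seed=3)
        truth = Proteoform(base=three_protein_db[0])
        s, precursor, _ = simulate_fragment_spectrum(truth, cfg)
        hits = absolute_mass_search(
            proteoform_mass(truth), s, three_protein_db,
            SearchParams(precursor_window=0.1),
        )
        assert [h.proteoform.base.identifier for h in hits] == ["P0"]

    def test_decoy_database_yields_no_accepted_prsms(self, three_protein_db):
        cfg = SimulationConfig(seed=5)
        truth = Proteoform(base=three_protein_db[2])
        s, precursor, _ = simulate_fragment_spectrum(truth, cfg)
        decoys = shuffle_database(three_protein_db, seed=17)
        hits = absolute_mass_search(
            precursor, s, decoys, SearchParams(precursor_window=5000, min_matched=5)
        )
        assert hits == []

    def test_true_protein_always_ranked_first_exhaustive_oracle(self, rng):
        """Ranking agrees with brute-force scoring of every database entry."""
        from riboforma.topdown import score_candidate

        db = [random_protein(rng, 60, f"Q{i}") for i in range(8)]
        params = SearchParams(precursor_window=5000, min_matched=1)
        for seed in range(3):
            truth = Proteoform(base=db[seed])
            s, precursor, _ = simulate_fragment_spectrum(
                truth, SimulationConfig(seed=seed)
            )
            hits = absolute_mass_search(precursor, s, db, params)
            oracle = max(
                (score_candidate(Proteoform(base=e), precursor, s, params) for e in db),
                key=lambda h: h.n_matched,
            )
            assert hits[0].proteoform.base.identifier == truth.base.identifier
            assert hits[0].n_matched == oracle.n_matched


class TestTerminalProcessing:
    def test_recovers_planted_truncation_and_gains_b_ions(self, rng):
        base = random_protein(rng, 30)
        truth = Proteoform(base=base, start_index=5)
        s, precursor, _ = simulate_fragment_spectrum(truth, SimulationConfig(seed=8))
        intact_hits = absolute_mass_search(
            precursor, s, [base], SearchParams(precursor_window=5000, min_matched=1)
        )
        result = infer_terminal_processing(
            base, precursor, s, max_nterm_trim=10, max_cterm_trim=5
        )
        top = result.forms[0]
        assert (top.proteoform.start_index, top.proteoform.end_index) == (5, 30)
        assert top.nterm_coverage > intact_hits[0].nterm_coverage

    def test_intact_precursor_returns_identity_form(self, rng):
        base = random_protein(rng, 25)
        truth = Proteoform(base=base)
        s, precursor, _ = simulate_fragment_spectrum(truth, SimulationConfig(seed=9))
        result = infer_terminal_processing(base, precursor, s,
                                           max_nterm_trim=10, max_cterm_trim=5)
        top = result.forms[0]
        assert (top.proteoform.start_index, top.proteoform.end_index) == (1, 25)
        assert top.proteoform.modifications == ()

    def test_no_consistent_form_reports_best_residual(self, rng):
        base = random_protein(rng, 25)
        s, _, _ = simulate_fragment_spectrum(
            Proteoform(base=base), SimulationConfig(seed=10)
        )
        bogus_precursor = proteoform_mass(Proteoform(base=base)) + 500.0
        result = infer_terminal_processing(base, bogus_precursor, s,
                                           max_nterm_trim=3, max_cterm_trim=2)
        assert result.forms == []
        assert np.isfinite(result.best_residual)

    def test_five_ragged_nterm_forms_recovered_with_acetyl_flags(self):
        """Co-occurring one-residue ragged ends, some N-terminally acetylated."""
        db, forms, _ = make_fixture_database(
            1,
            (120, 120),
            events=[{"protein": 0, "kind": "ragged",
                     "starts": [61, 62, 63, 68, 83],
                     "acetylated": [61, 68]}],
            seed=21,
        )
        recovered = []
        for i, truth in enumerate(forms):
            s, precursor, _ = simulate_fragment_spectrum(
                truth, SimulationConfig(seed=100 + i)
            )
            top = infer_terminal_processing(
                db[0], precursor, s, max_nterm_trim=90, max_cterm_trim=0
            ).forms[0]
            recovered.append(
                (top.proteoform.start_index,
                 tuple(m.name for m, _ in top.proteoform.modifications))
            )
        assert recovered == [
            (61, ("acetylation",)), (62, ()), (63, ()),
            (68, ("acetylation",)), (83, ()),
        ]


class TestUnitShiftLocalization:
    def s27_like(self, registry):
        db, forms, _ = make_fixture_database(
            1, (84, 84),
            events=[{"protein": 0, "kind": "modification", "name": "methylation",
                     "sites": [39, 55, 58], "residue": "C"}],
            seed=33,
        )
        return db[0], forms[0]

    def test_three_methyls_localized_to_cysteines(self, registry):
        base, truth = self.s27_like(registry)
        s, _, _ = simulate_fragment_spectrum(truth, SimulationConfig(seed=12))
        cys = {i + 1 for i, c in enumerate(base.residues) if c == "C"}
        result = localize_unit_shifts(
            Proteoform(base=base), s, n_units=3, candidate_residues=cys
        )
        assert not result.conflict
        assert result.localized_sites == {39, 55, 58}

    def test_zero_units_yields_no_sites(self, registry):
        base, _ = self.s27_like(registry)
        p = Proteoform(base=base)
        s, _, _ = simulate_fragment_spectrum(p, SimulationConfig(seed=13))
        result = localize_unit_shifts(p, s, n_units=0)
        assert result.localized_sites == set()
        assert not result.conflict
        assert all(k == 0 for k in result.cleavage_counts.values())

    def test_coverage_gap_produces_ambiguity_interval(self, registry, rng):
        """Ladders dark across the modified region localize nothing."""
        base = random_protein(rng, 40)
        site = 20
        seq = base.residues[:site - 1] + "K" + base.residues[site:]
        base = ProteinSequence(base.identifier, seq)
        truth = Proteoform(base=base, modifications=((registry["methylation"], site),))
        ions = [i for i in __import__("riboforma").generate_ladders(truth)
                if not (10 <= i.index <= 30)]  # cleavages 10..30 unobserved
        s = spectrum_from_ions(ions)
        result = localize_unit_shifts(Proteoform(base=base), s, n_units=1)
        assert result.localized_sites == set()
        assert len(result.ambiguous) == 1
        interval, count = result.ambiguous[0]
        assert count == 1 and site in interval

    def test_property_sweep_random_placements(self, rng, registry):
        """Full noiseless ladders recover any planting of ≤5 methyls exactly."""
        for trial in range(10):
            n_units = int(rng.integers(1, 6))
            length = int(rng.integers(30, 70))
            sites = sorted(rng.choice(np.arange(2, length), size=n_units, replace=False))
            seq = list(random_protein(rng, length).residues)
            for s_i in sites:
                seq[s_i - 1] = "C"
            base = ProteinSequence(f"T{trial}", "".join(seq))
            truth = Proteoform(
                base=base,
                modifications=tuple((registry["methylation"], int(s_i)) for s_i in sites),
            )
            spec, _, _ = simulate_fragment_spectrum(
                truth, SimulationConfig(seed=1000 + trial)
            )
            cys = {i + 1 for i, c in enumerate(base.residues) if c == "C"}
            result = localize_unit_shifts(
                Proteoform(base=base), spec, n_units=n_units, candidate_residues=cys
            )
            assert not result.conflict
            assert result.localized_sites == set(int(s_i) for s_i in sites)


class TestDecoyFdr:
    def test_planted_truth_gives_zero_fdr(self):
        db, _, _ = make_fixture_database(20, (40, 80), seed=4)
        spectra = []
        for i, entry in enumerate(db):
            s, precursor, _ = simulate_fragment_spectrum(
                Proteoform(base=entry), SimulationConfig(seed=200 + i)
            )
            spectra.append((precursor, s))
        result = decoy_fdr(db, spectra, SearchParams(min_matched=5), seed=55)
        assert result.fdr == 0.0
        assert result.n_target == 20

    def test_noise_spectra_null_calibration(self):
        """Target and decoy hit rates indistinguishable on pure noise."""
        db, _, _ = make_fixture_database(10, (40, 60), seed=6)
        rng = np.random.default_rng(77)
        spectra = []
        for i in range(15):
            mz = np.sort(rng.uniform(200, 2000, 80))
            s = Spectrum(mz, rng.uniform(1, 100, 80), ms_level=2)
            precursor = float(rng.uniform(4500, 7000))
            spectra.append((precursor, s))
        result = decoy_fdr(
            db, spectra, SearchParams(precursor_window=5000, min_matched=2), seed=88
        )
        total = result.n_target + result.n_decoy
        if total:
            p = stats.binomtest(result.n_decoy, total, 0.5).pvalue
            assert p > 0.01

    def test_empty_spectra_set_is_na(self):
        db, _, _ = make_fixture_database(2, (30, 40), seed=1)
        assert decoy_fdr(db, [], seed=0).fdr is None


class TestProteoformReport:
    def _prsm(self, base, precursor):
        return PrSM(
            proteoform=Proteoform(base=base), precursor_mass=precursor,
            mass_delta=0.0, matches=[],
        )

    def test_intensities_normalized_per_protein(self, rng):
        base = random_protein(rng, 30)
        m = base.backbone_mass()
        prsms = [self._prsm(base, m), self._prsm(base, m + 42.01)]
        ms1 = [m, m + 42.01]

        class _M:
            def __init__(self, mass, inten):
                self.mass, self.total_intensity = mass, inten

        report = proteoform_report(prsms, [_M(m, 30.0), _M(m + 42.01, 70.0)])
        assert report["normalized_intensity"].tolist() == pytest.approx([0.3, 0.7])

    def test_ambiguous_42da_reports_both_candidates(self, rng):
        base = random_protein(rng, 30)
        report = proteoform_report([self._prsm(base, base.backbone_mass() + 42.01)])
        assert report.loc[0, "annotation"] == "acetylation|trimethylation"

    def test_28da_labeled_dimethylation(self, rng):
        base = random_protein(rng, 30)
        report = proteoform_report([self._prsm(base, base.backbone_mass() + 28.03)])
        assert report.loc[0, "annotation"] == "dimethylation"

    def test_unannotated_delta_is_unk(self, rng):
        base = random_protein(rng, 30)
        report = proteoform_report([self._prsm(base, base.backbone_mass() + 213.11)])
        assert report.loc[0, "annotation"] == "UNK"
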