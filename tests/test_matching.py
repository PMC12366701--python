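"""Peak matching, site localization, and 18O linkage calling."""

import numpy as np
import pytest

from polyglu import (
    GluUnit,
    PeakList,
    Peptidoform,
    by_ladder,
    call_linkage,
    glu_chain,
    localize,
    match_peaks,
    read_mgf,
    simulate_o18_envelope,
    simulate_spectrum,
    write_mgf,
    SimulationConfig,
)
from polyglu.matching import l1_envelope_distance


def _spectrum_from_ions(ions, intensities=None, precursor=None):
    mzs = np.array([i.mz for i in ions])
    intens = np.asarray(intensities) if intensities is not None else np.full(len(ions), 100.0)
    pre_mz, pre_z = precursor if precursor else (mzs.max() + 100, 2)
    return PeakList(precursor_mz=pre_mz, precursor_z=pre_z, mz=mzs, intensity=intens)


class TestMatchPeaks:
    def test_exact_spectrum_fully_matched(self, alpha_peptide):
        pep, start = alpha_peptide
        ladder = by_ladder(Peptidoform(peptide=pep, start=start))
        spec = _spectrum_from_ions(ladder)
        matches = match_peaks(ladder, spec, tol_ppm=20)
        assert len(matches) == len(ladder)
        assert all(abs(m.ppm_error) < 1e-9 for m in matches)

    def test_peak_outside_tolerance_unmatched(self):
        ladder = by_ladder(Peptidoform(peptide="GADE", start=1))
        shifted = np.array([i.mz * (1 + 30e-6) for i in ladder])
        spec = PeakList(precursor_mz=500, precursor_z=2, mz=shifted,
                        intensity=np.full(len(shifted), 1.0))
        assert match_peaks(ladder, spec, tol_ppm=20) == []

    def test_one_peak_two_ions_smaller_ppm_wins(self):
        ladder = by_ladder(Peptidoform(peptide="GADE", start=1))
        ion = ladder[0]
        # one observed peak 3 ppm above the first ion; a decoy ion list where
        # a second theoretical ion sits 8 ppm below the same peak
        peak = ion.mz * (1 + 3e-6)
        other = ladder[1]
        fake = [ion, other]
        spec = PeakList(precursor_mz=500, precursor_z=2,
                        mz=np.array([peak]), intensity=np.array([10.0]))
        matches = match_peaks(fake, spec, tol_ppm=2000)
        assert len(matches) == 1
        assert matches[0].ion.key == ion.key

    def test_each_observed_peak_used_once(self):
        ladder = by_ladder(Peptidoform(peptide="GADE", start=1))
        spec = _spectrum_from_ions(ladder)
        matches = match_peaks(list(ladder) + list(ladder), spec, tol_ppm=20)
        assert len(matches) == len(ladder)

    def test_empty_spectrum(self):
        ladder = by_ladder(Peptidoform(peptide="GADE", start=1))
        spec = PeakList(precursor_mz=500, precursor_z=2, mz=np.array([]), intensity=np.array([]))
        assert match_peaks(ladder, spec) == []


class TestLocalize:
    def test_extension_spectrum_ranks_extension_first(self, worked_examples):
        ex = worked_examples["alpha_extension"]
        res = localize(ex["spectrum"], ex["candidates"])
        assert res.best == ex["truth"]
        assert res.site_call == "extension"
        assert res.delta_score > 0
        assert all(s1 >= s2 for s1, s2 in zip(res.scores, res.scores[1:]))

    def test_branch_spectrum_recovers_site(self, worked_examples):
        ex = worked_examples["alpha_branch_E445"]
        res = localize(ex["spectrum"], ex["candidates"])
        assert res.site_call == "branch@445"

    def test_only_shared_ions_gives_ambiguous(self, worked_examples):
        ex = worked_examples["alpha_extension"]
        ext, branches = ex["candidates"][0], ex["candidates"][1:]
        ladders = [{i.key: i for i in by_ladder(c)} for c in ex["candidates"]]
        shared = [
            ion
            for key, ion in ladders[0].items()
            if all(
                key in l and abs(l[key].mz - ion.mz) / ion.mz * 1e6 < 1e-3 for l in ladders[1:]
            )
        ]
        spec = _spectrum_from_ions(shared, precursor=(ex["spectrum"].precursor_mz, 2))
        res = localize(spec, ex["candidates"])
        assert res.site_call == "ambiguous"
        assert res.delta_score == pytest.approx(0.0, abs=1e-9)

    def test_score_invariant_to_intensity_scaling(self, worked_examples):
        ex = worked_examples["alpha_extension"]
        spec = ex["spectrum"]
        scaled = PeakList(
            precursor_mz=spec.precursor_mz,
            precursor_z=spec.precursor_z,
            mz=spec.mz.copy(),
            intensity=spec.intensity * 1e3,
        )
        r1 = localize(spec, ex["candidates"])
        r2 = localize(scaled, ex["candidates"])
        assert r1.scores == pytest.approx(r2.scores, rel=1e-12)

    def test_no_candidate_in_precursor_tolerance_errors(self, worked_examples):
        ex = worked_examples["alpha_extension"]
        wrong_k = [
            Peptidoform(
                peptide=c.peptide, start=c.start, extension=glu_chain(5, "D5")
            )
            for c in ex["candidates"][:1]
        ]
        with pytest.raises(ValueError, match="no candidate"):
            localize(ex["spectrum"], wrong_k)

    def test_noise_free_recovery_over_random_forms(self, alpha_peptide):
        """Any planted topology is recovered with positive margin when every
        discriminating ion is present."""
        pep, start = alpha_peptide
        cfg = SimulationConfig(
            coverage=1.0, mz_sd_ppm=0.0, intensity_sd=0.0, frag_intensity_sd=0.0, decoy_peaks=0
        )
        rng = np.random.default_rng(42)
        sites = (445, 446, 447)
        n_ok = 0
        trials = 100
        for t in range(trials):
            k = int(rng.integers(1, 6))
            choice = int(rng.integers(0, 4))
            if choice == 0:
                truth = Peptidoform(peptide=pep, start=start, extension=glu_chain(k, "D5"))
            else:
                truth = Peptidoform(
                    peptide=pep, start=start, branches=((sites[choice - 1], glu_chain(k, "D5")),)
                )
            cands = [Peptidoform(peptide=pep, start=start, extension=glu_chain(k, "D5"))] + [
                Peptidoform(peptide=pep, start=start, branches=((s, glu_chain(k, "D5")),))
                for s in sites
            ]
            spec = simulate_spectrum(truth, cfg, np.random.default_rng([7, t]), f"t{t}")
            res = localize(spec, cands)
            if res.best == truth and res.delta_score > 0:
                n_ok += 1
        assert n_ok == trials

    def test_delta_score_decays_with_decoy_density(self, alpha_peptide):
        pep, start = alpha_peptide
        truth = Peptidoform(peptide=pep, start=start, extension=glu_chain(2, "D5"))
        cands = [truth] + [
            Peptidoform(peptide=pep, start=start, branches=((s, glu_chain(2, "D5")),))
            for s in (445, 446, 447)
        ]
        # paired design: the signal peaks are drawn before the decoys, so the
        # same seed gives identical signal across decoy densities
        means = []
        # at full coverage the generating form's ladder is saturated by signal
        # peaks, so additional decoys can only lift the runner-up score
        for decoys in (0, 200, 800):
            cfg = SimulationConfig(coverage=1.0, decoy_peaks=decoys)
            deltas = [
                localize(
                    simulate_spectrum(truth, cfg, np.random.default_rng([55, r]), "d"),
                    cands,
                ).delta_score
                for r in range(25)
            ]
            means.append(np.mean(deltas))
        assert means[0] >= means[1] >= means[2]


class TestLinkageCalling:
    @pytest.fixture(scope="class")
    def o18_forms(self, alpha_peptide):
        pep, start = alpha_peptide
        alpha = Peptidoform(peptide=pep, start=start, extension=glu_chain(3, "O18"))
        gamma = Peptidoform(
            peptide=pep,
            start=start,
            extension=tuple(
                GluUnit("O18", "gamma" if i < 2 else "none") for i in range(3)
            ),
        )
        return alpha, gamma

    def test_full_retention_called_alpha(self, o18_forms):
        alpha, _ = o18_forms
        for i in range(25):
            env = simulate_o18_envelope(alpha, "alpha", np.random.default_rng([1, i]))
            assert call_linkage(env, alpha) == "alpha"

    def test_binomial_loss_called_gamma(self, o18_forms):
        _, gamma = o18_forms
        for i in range(25):
            env = simulate_o18_envelope(gamma, "gamma", np.random.default_rng([2, i]))
            assert call_linkage(env, gamma) == "gamma"

    def test_single_unit_chain_is_ambiguous(self, alpha_peptide):
        pep, start = alpha_peptide
        p = Peptidoform(peptide=pep, start=start, extension=glu_chain(1, "O18"))
        env = simulate_o18_envelope(p, "alpha", np.random.default_rng(3))
        with pytest.warns(UserWarning, match="indistinguishable"):
            assert call_linkage(env, p) == "ambiguous"

    def test_unlabeled_peptidoform_errors(self, alpha_peptide):
        pep, start = alpha_peptide
        p = Peptidoform(peptide=pep, start=start, extension=glu_chain(2, "D5"))
        with pytest.raises(ValueError, match="18O"):
            call_linkage([(100.0, 1.0)], p)

    def test_l1_distance_properties(self):
        a = [(100.0, 0.5), (101.0, 0.5)]
        assert l1_envelope_distance(a, a) == pytest.approx(0.0)
        b = [(103.0, 1.0)]
        assert l1_envelope_distance(a, b) == pytest.approx(2.0)


class TestMgfIO:
    def test_round_trip(self, tmp_path, worked_examples):
        spectra = [ex["spectrum"] for ex in worked_examples.values()]
        path = tmp_path / "spectra.mgf"
        write_mgf(spectra, path)
        back = read_mgf(path)
        assert len(back) == len(spectra)
        for orig, rt in zip(spectra, back):
            assert rt.source_id == orig.source_id
            assert rt.precursor_z == orig.precursor_z
            assert rt.precursor_mz == pytest.approx(orig.precursor_mz, abs=1e-6)
            np.testing.assert_allclose(rt.mz, orig.mz, atol=1e-5)
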