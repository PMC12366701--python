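"""Mass arithmetic, adduct m/z, isotope envelopes, and 18O retention."""

import pytest
from hypothesis import given, settings, strategies as st
from pyteomics import mass as pt_mass

from polyglu import GluUnit, Peptidoform, glu_chain
from polyglu.constants import PROTON
from polyglu.mass import (
    O18_SHIFT,
    ElementalComposition,
    composition,
    envelope,
    expected_o18_shift,
    glu_unit_composition,
    low_res_mz,
    mono_mass,
    mz,
    o18_retention,
    peptide_composition,
)

AA = "ACDEFGHIKLMNPQRSTVWY"


class TestComposition:
    def test_free_glutamic_acid(self):
        comp = peptide_composition("E")
        assert dict(comp) == {"C": 5, "H": 9, "N": 1, "O": 4}
        assert mono_mass(comp) == pytest.approx(147.05316, abs=5e-6)

    def test_unmodified_peptidoform_is_base_peptide(self):
        p = Peptidoform(peptide="GAEK", start=1)
        assert composition(p) == peptide_composition("GAEK")

    def test_label_unit_masses(self):
        light = mono_mass(glu_unit_composition(GluUnit("light")))
        d5 = mono_mass(glu_unit_composition(GluUnit("D5")))
        assert light == pytest.approx(129.04259, abs=5e-6)
        assert d5 == pytest.approx(134.07398, abs=5e-6)
        assert d5 - light == pytest.approx(5 * (2.0141017779 - 1.0078250319), abs=1e-9)

    def test_unknown_residue_errors(self):
        with pytest.raises(ValueError):
            peptide_composition("GAZ")

    @given(seq=st.text(alphabet=AA, min_size=1, max_size=15))
    @settings(max_examples=50, deadline=None, derandomize=True)
    def test_peptide_mass_agrees_with_pyteomics_oracle(self, seq):
        ours = mono_mass(peptide_composition(seq))
        oracle = pt_mass.calculate_mass(sequence=seq)
        assert ours == pytest.approx(oracle, abs=1e-3)

    @pytest.mark.parametrize("label", ["light", "D5", "O18"])
    def test_mass_additivity_per_extension_unit(self, label, alpha_peptide):
        pep, start = alpha_peptide
        unit_mass = mono_mass(glu_unit_composition(GluUnit(label)))
        for k in range(4):
            a = Peptidoform(peptide=pep, start=start, extension=glu_chain(k, label))
            b = Peptidoform(peptide=pep, start=start, extension=glu_chain(k + 1, label))
            delta = mono_mass(composition(b)) - mono_mass(composition(a))
            assert delta == pytest.approx(unit_mass, abs=1e-9)

    def test_branched_and_extended_forms_are_isobaric(self, alpha_peptide):
        pep, start = alpha_peptide
        ext = Peptidoform(peptide=pep, start=start, extension=glu_chain(3, "D5"))
        br = Peptidoform(peptide=pep, start=start, branches=((445, glu_chain(3, "D5")),))
        assert abs(mono_mass(composition(ext)) - mono_mass(composition(br))) < 1e-9


class TestMz:
    def test_o18_glutamate_deprotonated_high_res(self):
        glu18 = ElementalComposition({"C": 5, "H": 9, "N": 1, "O": 3, "18O": 1})
        assert round(mz(mono_mass(glu18), 1, "deprotonated"), 5) == 148.05013
        # the unit-resolution ESI reading is the nominal m/z
        assert low_res_mz(glu18, 1, "deprotonated") == 148.0

    def test_boc_o18_glutamate_sodiated(self):
        boc = ElementalComposition({"C": 10, "H": 17, "N": 1, "O": 5, "18O": 1})
        assert round(mz(mono_mass(boc), 1, "sodiated"), 1) == 272.1

    def test_protonated_deprotonated_symmetry(self):
        m = 500.0
        assert mz(m, 1, "protonated") - mz(m, 1, "deprotonated") == pytest.approx(
            2 * PROTON, abs=1e-12
        )

    def test_zero_charge_errors(self):
        with pytest.raises(ValueError):
            mz(100.0, 0)

    def test_empty_composition_mass_is_zero(self):
        assert mono_mass(ElementalComposition()) == 0.0


def _convolve_envelopes(ea, eb, tol=0.2):
    """Oracle: pairwise-sum convolution of two peak lists, merged on the
    nominal grid."""
    merged = {}
    for ma, aa in ea:
        for mb, ab in eb:
            key = round(ma + mb)
            p, msum = merged.get(key, (0.0, 0.0))
            merged[key] = (p + aa * ab, msum + aa * ab * (ma + mb))
    return sorted((msum / p, p) for p, msum in merged.values())


class TestEnvelope:
    def test_single_carbon(self):
        env = envelope({"C": 1})
        assert env[0] == (12.0, pytest.approx(0.9893))
        assert env[1][1] == pytest.approx(0.0107)

    def test_explicit_18o_is_fixed_shift(self):
        light = envelope({"C": 3, "O": 1})
        labeled = envelope({"C": 3, "18O": 1})
        # the labeled site contributes a fixed shift and no isotopic spread,
        # so the labeled envelope's abundances come from carbon alone
        assert labeled[0][0] - light[0][0] == pytest.approx(O18_SHIFT, abs=1e-9)
        assert labeled[0][1] == pytest.approx(envelope({"C": 3})[0][1], rel=1e-9)
        assert light[0][1] < labeled[0][1]  # natural 16O still convolves

    def test_c100_peak_ratio_matches_binomial(self):
        env = envelope({"C": 100})
        p13, p12 = 0.0107, 0.9893
        assert env[1][1] / env[0][1] == pytest.approx(100 * p13 / p12, rel=1e-9)

    def test_normalized_and_strictly_increasing(self, alpha_peptide):
        pep, _ = alpha_peptide
        env = envelope(peptide_composition(pep), prune=1e-6)
        assert abs(sum(a for _, a in env) - 1.0) < 1e-9
        masses = [m for m, _ in env]
        assert masses == sorted(masses) and len(set(masses)) == len(masses)

    @pytest.mark.parametrize(
        "part_a,part_b",
        [({"C": 10, "H": 12}, {"N": 4, "O": 6}), ({"C": 5, "S": 1}, {"C": 7, "O": 3})],
    )
    def test_envelope_associativity(self, part_a, part_b):
        whole = ElementalComposition(part_a) + ElementalComposition(part_b)
        direct = envelope(whole, prune=1e-10)
        via_parts = _convolve_envelopes(envelope(part_a, prune=1e-10), envelope(part_b, prune=1e-10))
        for (m1, a1), (m2, a2) in zip(direct, via_parts[: len(direct)]):
            if a1 < 1e-6:  # below this the pruned oracle parts lose cross terms
                break
            assert m1 == pytest.approx(m2, abs=1e-6)
            assert a1 == pytest.approx(a2, rel=1e-4)


class TestO18Retention:
    def test_all_alpha_chain_retains_everything(self, alpha_peptide):
        pep, start = alpha_peptide
        for k in (2, 3, 5):
            p = Peptidoform(peptide=pep, start=start, extension=glu_chain(k, "O18"))
            assert o18_retention(p) == {k: 1.0}

    def test_single_gamma_bond_fifty_fifty(self):
        chain = (GluUnit("O18", "gamma"), GluUnit("light", "none"))
        p = Peptidoform(peptide="GAEK", start=1, extension=chain)
        assert o18_retention(p) == {0: 0.5, 1: 0.5}

    def test_three_units_two_gamma_bonds_binomial(self):
        chain = (GluUnit("O18", "gamma"), GluUnit("O18", "gamma"), GluUnit("O18", "none"))
        p = Peptidoform(peptide="GAEK", start=1, extension=chain)
        dist = o18_retention(p)
        assert dist == {
            3: pytest.approx(0.25),
            2: pytest.approx(0.5),
            1: pytest.approx(0.25),
        }
        assert sum(dist.values()) == pytest.approx(1.0, abs=1e-12)

    def test_branch_initiation_does_not_lose_labels(self):
        # a branch chain attached via the substrate's gamma-carboxyl, all-alpha inside
        p = Peptidoform(peptide="GAEK", start=1, branches=((3, glu_chain(2, "O18")),))
        assert o18_retention(p) == {2: 1.0}

    def test_no_labels_errors(self):
        p = Peptidoform(peptide="GAEK", start=1, extension=glu_chain(2, "D5"))
        with pytest.raises(ValueError):
            o18_retention(p)

    @pytest.mark.parametrize("k", [1, 2, 4])
    def test_expected_shift_all_alpha(self, k, alpha_peptide):
        pep, start = alpha_peptide
        p = Peptidoform(peptide=pep, start=start, extension=glu_chain(k, "O18"))
        assert expected_o18_shift(p) == pytest.approx(2.00425 * k, abs=1e-3)
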