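import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from idpchar import seqdis
from idpchar.constants import CANONICAL_RESIDUES
from idpchar.seqdis import CompositionProfile, SequenceRecord

seq_strategy = st.text(alphabet=CANONICAL_RESIDUES, min_size=5, max_size=80)


class TestSequenceRecord:
    def test_rejects_empty_and_noncanonical(self):
        with pytest.raises(ValueError):
            SequenceRecord("x", "")
        with pytest.raises(ValueError):
            SequenceRecord("x", "ACDXB")

    def test_normalizes_case_and_whitespace(self):
        assert SequenceRecord("x", "ac de\n").residues == "ACDE"


class TestComposition:
    @pytest.mark.parametrize("seq,expected", [
        ("AAAA", {"A": 1.0}),
        ("ACDE", {"A": 0.25, "C": 0.25, "D": 0.25, "E": 0.25}),
    ])
    def test_simple_fractions(self, seq, expected):
        prof = seqdis.composition_fractions(SequenceRecord("t", seq))
        for aa in CANONICAL_RESIDUES:
            assert prof.fractions[aa] == pytest.approx(expected.get(aa, 0.0))

    def test_random_sequence_matches_generator_distribution(self):
        # fractions of a 1000-mer drawn from a stated distribution stay
        # within 3 binomial standard errors of it
        rng = np.random.default_rng(11)
        probs = np.full(20, 0.05)
        n = 1000
        letters = rng.choice(list(CANONICAL_RESIDUES), size=n, p=probs)
        prof = seqdis.composition_fractions(SequenceRecord("t", "".join(letters)))
        se = math.sqrt(0.05 * 0.95 / n)
        for aa in CANONICAL_RESIDUES:
            assert abs(prof.fractions[aa] - 0.05) <= 3 * se

    @given(seq_strategy)
    @settings(deadline=None, derandomize=True, max_examples=40)
    def test_fractions_sum_to_one(self, seq):
        prof = seqdis.composition_fractions(SequenceRecord("h", seq))
        assert sum(prof.fractions.values()) == pytest.approx(1.0, abs=1e-9)

    def test_profile_validation(self):
        with pytest.raises(ValueError):
            CompositionProfile({"A": 0.5})  # does not sum to 1
        with pytest.raises(ValueError):
            CompositionProfile({"A": 1.5, "C": -0.5})


class TestEnrichment:
    def uniform_ref(self):
        return CompositionProfile({aa: 0.05 for aa in CANONICAL_RESIDUES},
                                  source="reference-ordered")

    def test_identity_gives_zero(self):
        prof = CompositionProfile({aa: 0.05 for aa in CANONICAL_RESIDUES},
                                  n_residues=100)
        res = seqdis.enrichment(prof, self.uniform_ref(), n_boot=10, seed=0)
        assert all(e == 0.0 for e in res.enrichment.values())

    def test_doubling_gives_one(self):
        # f_sample = 0.2 vs f_ref = 0.1 for alanine
        fr = {aa: 0.8 / 19 for aa in CANONICAL_RESIDUES}
        fr["A"] = 0.2
        ref = {aa: 0.9 / 19 for aa in CANONICAL_RESIDUES}
        ref["A"] = 0.1
        res = seqdis.enrichment(
            CompositionProfile(fr, n_residues=100),
            CompositionProfile(ref, source="reference-ordered"),
            n_boot=10, seed=0)
        assert res.enrichment["A"] == pytest.approx(1.0)

    def test_absent_residue_is_minus_one(self):
        seq = SequenceRecord("t", "ACDE" * 25)
        res = seqdis.enrichment(seqdis.composition_fractions(seq),
                                self.uniform_ref(), n_boot=10, seed=0)
        assert res.enrichment["W"] == -1.0

    def test_zero_reference_warns_inf(self):
        ref = {aa: 1.0 / 19 for aa in CANONICAL_RESIDUES if aa != "W"}
        sample = seqdis.composition_fractions(SequenceRecord("t", "W" * 10))
        with pytest.warns(UserWarning):
            res = seqdis.enrichment(sample, CompositionProfile(ref),
                                    n_boot=10, seed=0)
        assert math.isinf(res.enrichment["W"])

    def test_antisymmetry_scaled_by_fraction_ratio(self):
        # e(s, r) = -e(r, s) * f_s / f_r for every residue present in both
        s_prof = seqdis.composition_fractions(
            SequenceRecord("t", "ACDEFGHIKL" * 12 + "AC" * 5))
        r_prof = CompositionProfile({aa: 0.05 for aa in CANONICAL_RESIDUES},
                                    n_residues=200)
        import warnings as _warnings
        e_sr = seqdis.enrichment(s_prof, r_prof, n_boot=5, seed=1).enrichment
        with _warnings.catch_warnings():
            # the swapped direction hits residues absent from the sample
            _warnings.simplefilter("ignore")
            e_rs = seqdis.enrichment(r_prof, s_prof, n_boot=5, seed=1).enrichment
        for aa in CANONICAL_RESIDUES:
            fs, fr = s_prof.fractions[aa], r_prof.fractions[aa]
            if fs > 0 and fr > 0:
                assert e_sr[aa] == pytest.approx(-e_rs[aa] * fs / fr)

    def test_determinism_given_seed(self):
        prof = seqdis.composition_fractions(SequenceRecord("t", "ACDEFGHIKL" * 10))
        a = seqdis.enrichment(prof, self.uniform_ref(), n_boot=50, seed=3)
        b = seqdis.enrichment(prof, self.uniform_ref(), n_boot=50, seed=3)
        assert a.ci_low == b.ci_low and a.ci_high == b.ci_high

    def test_ci_coverage_on_null_sequences(self):
        # sequences drawn from the reference itself: ~95% of residues
        # should be non-significant at alpha = 0.05 (Monte Carlo)
        rng = np.random.default_rng(7)
        ref = self.uniform_ref()
        nonsig = total = 0
        for rep in range(400):
            counts = rng.multinomial(200, [0.05] * 20)
            seq = "".join(aa * c for aa, c in zip(CANONICAL_RESIDUES, counts))
            prof = seqdis.composition_fractions(SequenceRecord("r", seq))
            res = seqdis.enrichment(prof, ref, n_boot=500, seed=rep)
            flags = list(res.significant.values())
            nonsig += sum(not f for f in flags)
            total += len(flags)
        assert 0.90 <= nonsig / total <= 0.99


class TestResidueClasses:
    @pytest.mark.parametrize("seq,key", [
        ("QSP", "disorder_promoting"),
        ("WFYI", "order_promoting"),
        ("DT", "neutral"),
    ])
    def test_class_assignment(self, seq, key):
        frac = seqdis.disorder_promoting_fraction(SequenceRecord("t", seq))
        assert frac[key] == 1.0

    @given(seq_strategy)
    @settings(deadline=None, derandomize=True, max_examples=40)
    def test_three_fractions_sum_to_one(self, seq):
        frac = seqdis.disorder_promoting_fraction(SequenceRecord("h", seq))
        assert sum(frac.values()) == pytest.approx(1.0)


class TestChargeHydropathy:
    def test_poly_ile_hydropathy_is_one(self):
        ch = seqdis.charge_hydropathy(SequenceRecord("t", "I" * 20))
        assert ch.mean_hydropathy == pytest.approx(1.0)

    def test_charge_cancellation(self):
        ch = seqdis.charge_hydropathy(SequenceRecord("t", "KDKDKDGGGG"))
        assert ch.mean_net_charge == 0.0

    def test_boundary_arithmetic(self):
        # direct oracle: a point at <H>=0.5 has boundary <R> = 2.785*0.5
        # - 1.151 = 0.2415; any <R> above it is disordered
        assert 2.785 * 0.5 - 1.151 == pytest.approx(0.2415)
        seq = SequenceRecord("t", "K" * 30 + "G" * 30)  # high charge
        ch = seqdis.charge_hydropathy(seq)
        boundary_r = 2.785 * ch.mean_hydropathy - 1.151
        assert ch.verdict == ("disordered" if ch.mean_net_charge > boundary_r
                              else ch.verdict)
        assert ch.mean_net_charge > boundary_r
        assert ch.verdict == "disordered"

    def test_ordered_sequence(self):
        ch = seqdis.charge_hydropathy(SequenceRecord("t", "ILVF" * 10))
        assert ch.verdict == "ordered"

    def test_verdict_invariant_under_shuffle(self):
        rng = np.random.default_rng(5)
        base = "QSPEKRILVFGADT" * 5
        ref = seqdis.charge_hydropathy(SequenceRecord("t", base))
        for _ in range(10):
            perm = "".join(rng.permutation(list(base)))
            ch = seqdis.charge_hydropathy(SequenceRecord("t", perm))
            # composition-only quantities are permutation invariant
            assert ch.mean_net_charge == pytest.approx(ref.mean_net_charge)
            assert ch.verdict == ref.verdict

    def test_short_sequence_errors(self):
        with pytest.raises(ValueError):
            seqdis.charge_hydropathy(SequenceRecord("t", "ACD"), window=5)


class TestFoldIndex:
    def test_poly_gly_value(self):
        # KD(G) = -0.4 -> H_norm = 0.45556; FI = 2.785*0.45556 - 1.151
        fi = seqdis.fold_index_profile(SequenceRecord("t", "G" * 60), window=51)
        assert fi[0] == pytest.approx(2.785 * (4.1 / 9.0) - 1.151, abs=1e-9)
        assert fi[0] == pytest.approx(0.1177, abs=1e-3)
        assert fi[0] > 0  # predicted folded

    def test_poly_glu_negative(self):
        fi = seqdis.fold_index_profile(SequenceRecord("t", "E" * 60), window=51)
        assert np.all(fi < 0)

    def test_homopolymer_profile_is_constant(self):
        for aa in "AGEKW":
            fi = seqdis.fold_index_profile(SequenceRecord("t", aa * 70), window=21)
            assert np.ptp(fi) == 0.0

    def test_bad_window_errors(self):
        with pytest.raises(ValueError):
            seqdis.fold_index_profile(SequenceRecord("t", "ACDEF" * 10), window=0)
        with pytest.raises(ValueError):
            seqdis.fold_index_profile(SequenceRecord("t", "ACDEF"), window=51)
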