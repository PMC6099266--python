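import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import grsmr
from grsmr import CohortVariant, HarmonizationError, ValidationError, VariantWeight
from grsmr.instrument import harmonize

_COMP = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _weight(effect="G", other="T", eaf=0.7, beta=0.25, rsid="rs1"):
    return VariantWeight(rsid=rsid, chrom="1", pos=100, effect_allele=effect,
                         other_allele=other, eaf=eaf, beta=beta, se=0.01,
                         pvalue=1e-9)


def _variant(counted, other, dosages, rsid="rs1"):
    return CohortVariant(rsid=rsid, counted_allele=counted, other_allele=other,
                         dosages=np.asarray(dosages, dtype=float))


class TestHarmonize:
    def test_all_nonpalindromic_orientations(self):
        """Every representation of a non-palindromic SNP maps back to the
        effect-allele orientation.

        For each non-palindromic (effect, other) pair, the cohort may report
        the same pair (identity), the swapped pair (dosage 2-d), the
        strand-complemented pair (identity) or the complemented swapped pair
        (2-d); a hand-built truth table enumerates all of them.
        """
        d = np.array([0.0, 1.0, 2.0, 0.5])
        pairs = [(e, o) for e, o in itertools.permutations("ACGT", 2)
                 if {e, o} not in ({"A", "T"}, {"C", "G"})]
        assert len(pairs) == 8
        checked = 0
        for effect, other in pairs:
            truth = {
                (effect, other): "identity",
                (other, effect): "swap",
                (_COMP[effect], _COMP[other]): "strand-flip",
                (_COMP[other], _COMP[effect]): "swap+flip",
            }
            for (counted, oth), action in truth.items():
                w = _weight(effect, other)
                expect = d if counted in (effect, _COMP[effect]) else 2.0 - d
                h = harmonize([w], [_variant(counted, oth, d)])
                assert h.actions["rs1"] == action
                np.testing.assert_allclose(h.dosages[:, 0], expect)
                checked += 1
        assert checked == 32  # 8 pairs x 4 representations

    def test_irreconcilable_alleles_name_the_rsid(self):
        w = _weight("G", "T")
        with pytest.raises(HarmonizationError, match="rs1"):
            harmonize([w], [_variant("G", "C", [0, 1])])

    def test_variant_absent_from_cohort(self):
        with pytest.raises(HarmonizationError, match="absent"):
            harmonize([_weight()], [])

    def test_palindromic_dropped_by_default(self):
        w = _weight("A", "T", eaf=0.8)
        with pytest.warns(UserWarning, match="palindromic"):
            h = harmonize([w], [_variant("A", "T", [0, 1, 2])])
        assert h.actions["rs1"] == "dropped"
        assert h.dosages.shape[1] == 0

    def test_palindromic_inferred_by_frequency(self):
        # cohort counts the low-frequency allele of an EAF-0.8 SNP -> swap
        w = _weight("A", "T", eaf=0.8)
        d = [0, 0, 1, 0, 0]  # counted-allele freq 0.1
        h = harmonize([w], [_variant("T", "A", d)], palindromic_policy="infer")
        assert h.actions["rs1"] == "swap"
        np.testing.assert_allclose(h.dosages[:, 0], 2.0 - np.asarray(d, float))

    def test_idempotence(self, weights):
        """Harmonizing an already-harmonized cohort changes nothing."""
        rng = np.random.default_rng(0)
        variants = [
            _variant(w.effect_allele, w.other_allele,
                     rng.binomial(2, w.eaf, 50), rsid=w.rsid)
            for w in weights
        ]
        h1 = harmonize(weights, variants, palindromic_policy="infer")
        variants2 = [
            _variant(w.effect_allele, w.other_allele, h1.dosages[:, j], rsid=w.rsid)
            for j, w in enumerate(weights)
        ]
        h2 = harmonize(weights, variants2, palindromic_policy="infer")
        np.testing.assert_array_equal(h1.dosages, h2.dosages)
        assert all(a in ("identity",) for r, a in h2.actions.items())

    def test_eaf_discordance_warns(self):
        w = _weight("G", "T", eaf=0.9)
        with pytest.warns(UserWarning, match="differs from weight EAF"):
            harmonize([w], [_variant("G", "T", [0.0] * 20)])


class TestRelativeExposure:
    def test_score_examples(self, weights):
        """Known dosage patterns give the hand-computed weighted sums."""
        rsids = [w.rsid for w in weights]
        frame = pd.DataFrame(
            [np.zeros(5), np.array([1.0 if r == "rs4588" else 0.0 for r in rsids]),
             2.0 * np.ones(5)],
            columns=rsids, index=["zero", "one_rs4588", "two_all"])
        s = grsmr.compute_relative_exposure(frame, weights).as_series()
        assert s["zero"] == 0.0
        assert s["one_rs4588"] == pytest.approx(0.2469, abs=1e-12)
        assert s["two_all"] == pytest.approx(1.8772, abs=1e-12)

    def test_missing_policy_exclude_vs_impute(self, weights):
        rsids = [w.rsid for w in weights]
        frame = pd.DataFrame([[np.nan, 1, 1, 1, 1]], columns=rsids, index=["a"])
        excl = grsmr.compute_relative_exposure(frame, weights, missing="exclude")
        assert np.isnan(excl.score[0])
        imp = grsmr.compute_relative_exposure(frame, weights, missing="impute")
        expected = 2 * weights[0].eaf * weights[0].beta + \
            sum(w.beta for w in weights[1:])
        assert imp.score[0] == pytest.approx(expected)

    def test_no_retained_snps_is_error(self, weights):
        frame = pd.DataFrame({"rs_unknown": [1.0]})
        with pytest.raises(ValidationError, match="no retained"):
            grsmr.compute_relative_exposure(frame, weights)

    @given(st.lists(st.integers(0, 2), min_size=5, max_size=5))
    @settings(max_examples=50, deadline=None)
    def test_score_linearity(self, dosage):
        """The score of a dosage vector is the sum of its one-SNP scores."""
        weights = grsmr.packaged_weights()
        rsids = [w.rsid for w in weights]
        full = pd.DataFrame([dosage], columns=rsids, dtype=float)
        total = grsmr.compute_relative_exposure(full, weights).score[0]
        parts = 0.0
        for j, r in enumerate(rsids):
            one = pd.DataFrame(np.zeros((1, 5)), columns=rsids)
            one.iloc[0, j] = dosage[j]
            parts += grsmr.compute_relative_exposure(one, weights).score[0]
        assert total == pytest.approx(parts, abs=1e-12)


class TestInstrumentStrength:
    def test_r2_within_reported_band(self, weights):
        """The packaged instrument explains 3-5% of exposure variance."""
        r2 = grsmr.expected_instrument_r2(weights)
        assert 0.03 <= r2 <= 0.05
        by_hand = sum(w.beta ** 2 * 2 * w.eaf * (1 - w.eaf) for w in weights)
        assert r2 == pytest.approx(by_hand, abs=1e-15)
        assert r2 == pytest.approx(0.0438, abs=5e-4)

    def test_zero_beta_contributes_nothing(self):
        assert grsmr.expected_instrument_r2(
            [_weight(beta=0.0)]) == 0.0

    def test_quadratic_scaling_in_beta(self, weights):
        doubled = [
            VariantWeight(rsid=w.rsid, chrom=w.chrom, pos=w.pos,
                          effect_allele=w.effect_allele, other_allele=w.other_allele,
                          eaf=w.eaf, beta=2 * w.beta, se=w.se, pvalue=w.pvalue)
            for w in weights
        ]
        assert grsmr.expected_instrument_r2(doubled) == pytest.approx(
            4 * grsmr.expected_instrument_r2(weights))
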