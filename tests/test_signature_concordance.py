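"""Signature contribution algebra, concordance and mismatch scores."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

import mutopt as m
from mutopt.spectrum import SBS96_LABELS


def sig_matrix(columns: dict) -> m.SignatureMatrix:
    S = pd.DataFrame(columns, index=list(SBS96_LABELS)).fillna(0.0)
    return m.SignatureMatrix(S / S.sum(axis=0))


def uniform_sig():
    return pd.Series(1.0 / 96, index=list(SBS96_LABELS))


def one_hot(label):
    s = pd.Series(0.0, index=list(SBS96_LABELS))
    s[label] = 1.0
    return s


CLS = "T[T>A]G"


class TestProportions:
    def test_single_and_two_signature_fractions(self):
        p = m.signature_proportions(pd.Series({"SBS4": 100.0}))
        assert p["SBS4"] == 1.0
        p = m.signature_proportions(pd.Series({"A": 30.0, "B": 10.0}))
        assert p["A"] == 0.75 and p["B"] == 0.25

    def test_zero_exposures_skipped_with_warning(self):
        with pytest.warns(UserWarning):
            assert m.signature_proportions(pd.Series({"A": 0.0})) is None

    @given(st.lists(st.floats(0.01, 1e4), min_size=2, max_size=5),
           st.floats(0.1, 100.0))
    @settings(max_examples=50, deadline=None)
    def test_sums_to_one_and_scale_invariant(self, counts, k):
        E = pd.Series(counts, index=[f"S{i}" for i in range(len(counts))])
        p = m.signature_proportions(E)
        assert p.sum() == pytest.approx(1.0)
        assert np.allclose(m.signature_proportions(E * k), p)


class TestContributions:
    def test_single_signature_is_one_where_defined(self):
        sigs = sig_matrix({"A": uniform_sig()})
        w = m.substitution_contributions(pd.Series({"A": 1.0}), sigs)
        assert np.allclose(w.loc["A"], 1.0)

    def test_disjoint_one_hot_signatures(self):
        sigs = sig_matrix({"A": one_hot(CLS), "B": one_hot("A[C>A]A")})
        w = m.substitution_contributions(pd.Series({"A": 0.5, "B": 0.5}), sigs)
        assert w.loc["A", CLS] == 1.0 and w.loc["B", "A[C>A]A"] == 1.0
        # classes neither signature can produce are undefined
        assert w["C[C>G]C"].isna().all()

    def test_hand_arithmetic(self):
        # p=(0.8,0.2), S at the class (0.01, 0.04) -> w_1 = 0.008/0.016 = 0.5
        a = pd.Series(0.99 / 95, index=list(SBS96_LABELS))
        b = pd.Series(0.96 / 95, index=list(SBS96_LABELS))
        a[CLS], b[CLS] = 0.01, 0.04
        sigs = m.SignatureMatrix(pd.DataFrame({"A": a, "B": b}))
        w = m.substitution_contributions(pd.Series({"A": 0.8, "B": 0.2}), sigs)
        assert w.loc["A", CLS] == pytest.approx(0.5, abs=1e-12)

    def test_columns_sum_to_one(self, exposure_bundle):
        sigs, exposures, _, _ = exposure_bundle
        p = m.signature_proportions(exposures.iloc[0])
        w = m.substitution_contributions(p, sigs)
        sums = w.sum(axis=0, skipna=True)
        defined = ~w.isna().all(axis=0)
        assert np.allclose(sums[defined], 1.0, atol=1e-9)


class TestBurden:
    def test_uniform_single_signature(self):
        sigs = sig_matrix({"A": uniform_sig()})
        E = pd.Series({"A": 50.0})
        w = m.substitution_contributions(m.signature_proportions(E), sigs)
        b = m.burden_proportions(E, w)
        assert np.allclose(b.values, 1.0 / 96)

    def test_one_hot_single_signature(self):
        sigs = sig_matrix({"A": one_hot(CLS)})
        E = pd.Series({"A": 7.0})
        w = m.substitution_contributions(m.signature_proportions(E), sigs)
        b = m.burden_proportions(E, w)
        assert b[CLS] == 1.0 and b.drop(CLS).eq(0).all()
        assert m.concordance_score(b, CLS) == 1.0

    def test_two_signature_longhand_oracle(self):
        rng = np.random.default_rng(4)
        a = pd.Series(rng.dirichlet(np.ones(96)), index=list(SBS96_LABELS))
        bsig = pd.Series(rng.dirichlet(np.ones(96)), index=list(SBS96_LABELS))
        sigs = sig_matrix({"A": a, "B": bsig})
        E = pd.Series({"A": 120.0, "B": 40.0})
        p = m.signature_proportions(E)
        w = m.substitution_contributions(p, sigs)
        b = m.burden_proportions(E, w)
        # longhand: per class, counts E_k * w_kc summed then normalized
        raw = {}
        for c in SBS96_LABELS:
            denom = p["A"] * sigs.S.loc[c, "A"] + p["B"] * sigs.S.loc[c, "B"]
            wA = p["A"] * sigs.S.loc[c, "A"] / denom
            wB = p["B"] * sigs.S.loc[c, "B"] / denom
            raw[c] = E["A"] * wA + E["B"] * wB
        total = sum(raw.values())
        for c in SBS96_LABELS[::9]:
            assert b[c] == pytest.approx(raw[c] / total)
        # simple mode matches the direct E @ S reading
        b2 = m.burden_proportions(E, w, sigs, mode="simple")
        direct = (sigs.S["A"] * E["A"] + sigs.S["B"] * E["B"])
        assert np.allclose(b2.values, (direct / direct.sum()).values)

    def test_modes_differ_in_general(self):
        rng = np.random.default_rng(5)
        a = pd.Series(rng.dirichlet(np.ones(96) * 0.2), index=list(SBS96_LABELS))
        c = pd.Series(rng.dirichlet(np.ones(96) * 0.2), index=list(SBS96_LABELS))
        sigs = sig_matrix({"A": a, "C": c})
        E = pd.Series({"A": 300.0, "C": 10.0})
        w = m.substitution_contributions(m.signature_proportions(E), sigs)
        b1 = m.burden_proportions(E, w)
        b2 = m.burden_proportions(E, w, sigs, mode="simple")
        assert not np.allclose(b1.values, b2.values)

    def test_uniform_burden_concordance(self):
        b = pd.Series(1.0 / 96, index=list(SBS96_LABELS))
        assert m.concordance_score(b, CLS) == pytest.approx(1 / 96)


class TestMismatch:
    def test_single_signature_zero(self):
        sigs = sig_matrix({"A": uniform_sig()})
        p = pd.Series({"A": 1.0})
        w = m.substitution_contributions(p, sigs)
        top, score = m.mismatch_score(w, p, CLS)
        assert top == "A" and score == 0.0

    def test_minor_signature_driving_driver_class(self):
        # p=(0.9, 0.1); signature B produces the class almost alone
        a, b = uniform_sig().copy(), uniform_sig().copy()
        sigs = sig_matrix({"A": a, "B": b})
        w = pd.DataFrame(
            0.5, index=["A", "B"], columns=list(SBS96_LABELS)
        )
        w[CLS] = [0.05, 0.95]
        p = pd.Series({"A": 0.9, "B": 0.1})
        top, score = m.mismatch_score(w, p, CLS)
        assert top == "B" and score == pytest.approx(0.85)
        w[CLS] = [0.95, 0.05]
        top, score = m.mismatch_score(w, p, CLS)
        assert top == "A" and score == pytest.approx(0.05)

    def test_unreachable_class_flagged(self):
        sigs = sig_matrix({"A": one_hot("A[C>A]A")})
        p = pd.Series({"A": 1.0})
        w = m.substitution_contributions(p, sigs)
        with pytest.warns(UserWarning):
            top, score = m.mismatch_score(w, p, CLS)
        assert top is None and score is None


class TestDriverMapping:
    @pytest.mark.parametrize(
        "gene,aa,expected",
        [
            ("Kras", "Q61L", "T[T>A]G"),
            ("KRAS", "Q61R", "T[T>C]G"),
            ("KRAS", "G12D", "A[C>T]C"),
            ("KRAS", "G12C", "C[C>A]A"),
            ("KRAS", "G12V", "A[C>A]C"),
            ("KRAS", "G13D", "G[C>T]C"),
            ("KRAS", "L19F", "T[C>A]A"),
            ("KRAS", "Q61K", "T[C>A]A"),
            ("Braf", "V637E", "G[T>A]G"),
            ("BRAF", "V600E", "G[T>A]G"),
        ],
    )
    def test_hotspot_classes(self, gene, aa, expected):
        assert m.map_driver_to_class(gene, aa).label == expected

    def test_unknown_driver_lists_known_labels(self):
        with pytest.raises(KeyError, match="KRAS Q61L"):
            m.map_driver_to_class("Kras", "A146T")


class TestTumorAnalysis:
    def test_exposure_scale_invariance(self, exposure_bundle):
        sigs, exposures, drivers, _ = exposure_bundle
        t1 = m.concordance_table(exposures, sigs, drivers.head(10))
        t2 = m.concordance_table(exposures * 10.0, sigs, drivers.head(10))
        for col in ("concordance_score", "mismatch_score"):
            assert np.allclose(t1[col], t2[col])
        assert list(t1["top_signature"]) == list(t2["top_signature"])

    def test_analyze_tumor_consistency(self, exposure_bundle):
        sigs, exposures, drivers, _ = exposure_bundle
        row = drivers.iloc[0]
        res = m.analyze_tumor(
            row.tumor_id, exposures.loc[row.tumor_id], sigs,
            "KRAS", "synthetic", driver_class=row.substitution_class,
        )
        assert res.burden.sum() == pytest.approx(1.0, abs=1e-9)
        assert res.concordance_score == pytest.approx(
            res.burden[row.substitution_class]
        )
        assert res.w_driver.sum() == pytest.approx(1.0, abs=1e-9)
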