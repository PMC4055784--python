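import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from phytonet import bioactivity as bio


def rec(mtype="Ki", value=6.0, organism="Homo sapiens", key="K1",
        protein="P1"):
    return {"compound_inchikey": key, "protein_id": protein,
            "organism": organism, "type": mtype, "value": value}


class TestFilterRecords:
    def test_keeps_allowed_drops_disallowed_preserving_order(self):
        df = pd.DataFrame([
            rec("Ki", organism="Homo sapiens"),
            rec("Ki", organism="Danio rerio"),
            rec("IC50", organism="Mus musculus"),
            rec("AC50", organism="Homo sapiens"),  # unknown type
        ])
        out = bio.filter_records(df)
        assert list(out.index) == [0, 2]

    def test_empty_input(self):
        df = pd.DataFrame(columns=["compound_inchikey", "protein_id",
                                   "organism", "type", "value"])
        assert len(bio.filter_records(df)) == 0

    def test_negative_potency_dropped_and_inhibition_clamped(self):
        df = pd.DataFrame([
            rec("potency", value=-5.0),
            rec("inhibition", value=150.0),
            rec("inhibition", value=-10.0),
        ])
        out = bio.filter_records(df)
        assert len(out) == 2
        assert sorted(out["value"]) == [0.0, 100.0]


class TestIsPositive:
    @pytest.mark.parametrize("mtype,value,expected", [
        ("Ki", 6.0, True),
        ("Ki", 5.5, False),       # boundary: strictly greater
        ("IC50", 5.51, True),
        ("EC50", 5.4, False),
        ("Kd", 9.0, True),
        ("inhibition", 20.0, False),  # boundary: strictly greater
        ("inhibition", 20.1, True),
        ("potency", 500.0, False),    # boundary: strictly lower
        ("potency", 499.9, True),
    ])
    def test_threshold_rules(self, mtype, value, expected):
        assert bio.is_positive(mtype, value) is expected

    def test_vectorized_agrees_with_scalar(self):
        rows = [rec(m, v) for m in ("Ki", "inhibition", "potency")
                for v in (0.0, 5.5, 20.0, 21.0, 499.0, 500.0, 7.0)]
        df = pd.DataFrame(rows)
        mask = bio.positive_mask(df)
        for (_, row), got in zip(df.iterrows(), mask):
            assert got == bio.is_positive(row["type"], row["value"])


class TestAggregate:
    def test_positive_fraction(self):
        df = pd.DataFrame([rec(value=v) for v in (6, 7, 8, 3)])
        out = bio.aggregate(df)
        assert len(out) == 1
        row = out.iloc[0]
        assert row["n_positive"] == 3 and row["n_total"] == 4
        assert row["probability"] == 0.75 and bool(row["interacting"])

    def test_half_probability_is_interacting(self):
        df = pd.DataFrame([rec(value=6.0), rec(value=3.0)])
        row = bio.aggregate(df).iloc[0]
        assert row["probability"] == 0.5 and bool(row["interacting"])

    def test_all_negative_not_interacting(self):
        df = pd.DataFrame([rec(value=3.0), rec(value=4.0)])
        row = bio.aggregate(df).iloc[0]
        assert row["probability"] == 0.0 and not bool(row["interacting"])

    def test_empty_group_is_error(self):
        with pytest.raises(ValueError):
            bio.aggregate(pd.DataFrame(columns=["compound_inchikey",
                                                "protein_id", "type",
                                                "value"]))

    def test_permutation_invariance(self):
        rows = [rec(value=v, protein=p) for p in ("P1", "P2")
                for v in (6.0, 3.0, 7.0)]
        df = pd.DataFrame(rows)
        shuffled = df.sample(frac=1.0, random_state=7)
        pd.testing.assert_frame_equal(bio.aggregate(df),
                                      bio.aggregate(shuffled))

    def test_interacting_count_monotone_in_thresholds(self):
        rng = np.random.default_rng(5)
        rows = [rec(mtype=m, value=v, key=f"K{i % 13}",
                    protein=f"P{i % 7}")
                for i, (m, v) in enumerate(zip(
                    rng.choice(["Ki", "inhibition", "potency"], 300),
                    rng.uniform(0, 600, 300)))]
        df = pd.DataFrame(rows)
        base = bio.aggregate(df)["interacting"].sum()
        for tighter in (bio.Thresholds(pchembl=6.5),
                        bio.Thresholds(inhibition_pct=40),
                        bio.Thresholds(potency_um=100)):
            assert bio.aggregate(df, tighter)["interacting"].sum() <= base


class TestTanimoto:
    def test_identical_and_disjoint(self):
        assert bio.tanimoto({1, 2, 3}, {1, 2, 3}) == 1.0
        assert bio.tanimoto({1, 2}, {3, 4}) == 0.0
        assert bio.tanimoto(frozenset(), frozenset()) == 0.0

    def test_hand_case(self):
        assert bio.tanimoto({1, 2, 3}, {2, 3, 4}) == 0.5

    def test_array_length_mismatch(self):
        with pytest.raises(ValueError, match="mismatch"):
            bio.tanimoto(np.zeros(8), np.zeros(16))

    def test_matches_brute_force_on_random_pairs(self):
        rng = np.random.default_rng(42)
        for _ in range(1000):
            a = rng.integers(0, 2, 64).astype(bool)
            b = rng.integers(0, 2, 64).astype(bool)
            sa = {i for i, x in enumerate(a) if x}
            sb = {i for i, x in enumerate(b) if x}
            union = sa | sb
            expected = len(sa & sb) / len(union) if union else 0.0
            assert bio.tanimoto(a, b) == expected
            assert bio.tanimoto(sa, sb) == expected

    @given(st.frozensets(st.integers(0, 63)), st.frozensets(
        st.integers(0, 63)))
    @settings(max_examples=200, deadline=None)
    def test_symmetry_and_bounds(self, a, b):
        t = bio.tanimoto(a, b)
        assert t == bio.tanimoto(b, a)
        assert 0.0 <= t <= 1.0


def comp(cid, key, mw, bits):
    return bio.Compound(compound_id=cid, inchikey=key, mw=mw,
                        fingerprint=frozenset(bits))


class TestMatchCompound:
    def test_exact_by_full_inchikey(self):
        q = comp("Q", "AAAA-BBB-N", 300, range(10))
        r = comp("R", "AAAA-BBB-N", 999, range(50, 60))
        exact, similar = bio.match_compound(q, [r])
        assert exact == [r] and similar == []

    def test_tc_boundary_inclusive_mw_strict(self):
        # 17 shared of 20-bit union -> Tc = 0.85 exactly
        q = comp("Q", "Q-KEY-N", 300.0, range(17 + 2))   # bits 0..18
        r = comp("R", "R-KEY-N", 349.0, list(range(17)) + [30])
        assert bio.tanimoto(q.fingerprint, r.fingerprint) == 0.85
        _, similar = bio.match_compound(q, [r])
        assert len(similar) == 1 and similar[0].delta_mw == 49.0

    def test_mw_difference_of_50_rejected(self):
        q = comp("Q", "Q-KEY-N", 300.0, range(10))
        r = comp("R", "R-KEY-N", 350.0, range(10))  # Tc = 1, ΔMW = 50
        _, similar = bio.match_compound(q, [r])
        assert similar == []

    def test_below_tc_rejected(self):
        q = comp("Q", "Q-KEY-N", 300.0, range(10))
        r = comp("R", "R-KEY-N", 300.0, range(5, 15))  # Tc = 1/3
        _, similar = bio.match_compound(q, [r])
        assert similar == []


class TestBuildInteractionTable:
    def setup_method(self):
        self.catalog = pd.DataFrame({
            "plant_id": ["PL1", "PL1", "PL2"],
            "plant_name": ["a", "a", "b"],
            "edible": [True, True, False],
            "compound_id": ["C1", "C2", "C3"],
        })
        self.compounds = {
            "C1": comp("C1", "KEY1", 300, range(10)),
            "C2": comp("C2", "KEY2", 310, range(20, 40)),
            "C3": comp("C3", "KEY3", 320, range(40, 50)),
        }
        # C1 has direct evidence; REF is similar to C2 and has evidence;
        # C3 has only non-interacting evidence
        self.reference = [comp("REF", "KEYR", 315, range(20, 40))]
        self.evidence = pd.DataFrame({
            "compound_inchikey": ["KEY1", "KEYR", "KEY3"],
            "protein_id": ["T1", "T2", "T3"],
            "n_positive": [3, 2, 0],
            "n_total": [3, 2, 2],
            "probability": [1.0, 1.0, 0.0],
            "interacting": [True, True, False],
        })

    def test_routes(self):
        table = bio.build_interaction_table(
            self.catalog, self.compounds, self.evidence,
            reference_compounds=self.reference,
            direct_proteins={"T1", "T2", "T3"},
            similar_proteins={"T2"})
        routes = {(r.plant_id, r.compound_id, r.protein_id): r.route
                  for r in table.itertuples()}
        assert routes == {("PL1", "C1", "T1"): "direct",
                          ("PL1", "C2", "T2"): "similar"}

    def test_similar_route_restricted_to_seed_proteins(self):
        table = bio.build_interaction_table(
            self.catalog, self.compounds, self.evidence,
            reference_compounds=self.reference,
            direct_proteins={"T1", "T2", "T3"},
            similar_proteins=set())  # no seeds -> no similar rows
        assert set(table["route"]) == {"direct"}

    def test_non_interacting_evidence_yields_no_rows(self):
        only_c3 = self.catalog[self.catalog["compound_id"] == "C3"]
        table = bio.build_interaction_table(
            only_c3, self.compounds, self.evidence,
            reference_compounds=self.reference)
        assert len(table) == 0
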