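"""DAMP calling thresholds, overlap accounting, categories, enrichment."""

import itertools
import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from coldmem import dampcall as dc
from coldmem.quantify import CutoffParams


def quant_row(pid, r115, r116, p3, p6, genotype="A"):
    return [
        {
            "protein_id": pid,
            "genotype": genotype,
            "replicate_set": f"set{s}",
            "r115": r115,
            "r116": r116,
            "n_peptides": 3,
            "p_3h": p3,
            "p_6h": p6,
        }
        for s in (1, 2, 3)
    ]


def calls_frame(entries, genotype="A"):
    """entries: iterable of (protein_id, timepoint, direction)."""
    rows = [
        {
            "protein_id": pid,
            "genotype": genotype,
            "timepoint": tp,
            "direction": d,
            "fold": 2.0 if d == "up" else 0.5,
            "p": 0.01,
        }
        for pid, tp, d in entries
    ]
    return pd.DataFrame(rows, columns=dc.CALL_COLUMNS)


class TestCallDamps:
    def test_up_down_unchanged(self):
        quant = pd.DataFrame(
            quant_row("P1", 1.5, 1.0, 0.01, 0.5)
            + quant_row("P2", 1.0, 0.70, 0.5, 0.01)
            + quant_row("P3", 1.1, 0.95, 0.01, 0.01)
        )
        calls = dc.call_damps(quant, {"P1", "P2", "P3"})
        d = {(r.protein_id, r.timepoint): r.direction for r in calls.itertuples()}
        assert d[("P1", "3h")] == "up"
        assert d[("P2", "6h")] == "down"  # 0.70 <= 1/1.4
        assert d[("P3", "3h")] == "unchanged"

    def test_non_membrane_never_called(self):
        quant = pd.DataFrame(quant_row("P9", 3.0, 3.0, 0.001, 0.001))
        calls = dc.call_damps(quant, set())
        assert len(calls) == 0

    def test_boundary_is_inclusive(self):
        cut = CutoffParams(d_log2=1.0, p_threshold=0.05)  # fold cutoff 2.0 exact
        quant = pd.DataFrame(
            quant_row("P1", 2.0, 0.5, 0.05, 0.05) + quant_row("P2", 1.99, 1.0, 0.05, 0.04)
        )
        calls = dc.call_damps(quant, {"P1", "P2"}, cut)
        d = {(r.protein_id, r.timepoint): r.direction for r in calls.itertuples()}
        assert d[("P1", "3h")] == "up"  # fold == cutoff, p == threshold
        assert d[("P1", "6h")] == "down"  # fold == 1/cutoff
        assert d[("P2", "3h")] == "unchanged"

    def test_missing_replicate_set_excluded(self):
        rows = quant_row("P1", 2.0, 2.0, 0.01, 0.01)[:2]  # only two sets
        calls = dc.call_damps(pd.DataFrame(rows), {"P1"})
        assert len(calls) == 0
        assert calls.attrs["n_excluded_missing_sets"] == 1


class TestOverlapTable:
    def test_printed_summary_counts(self):
        # 3 h: 11 up + 29 down in A, 80 up + 33 down in B, common 3 up + 6 down.
        a, b = [], []
        for i in range(3):
            a.append((f"CU{i}", "3h", "up")); b.append((f"CU{i}", "3h", "up"))
        for i in range(6):
            a.append((f"CD{i}", "3h", "down")); b.append((f"CD{i}", "3h", "down"))
        a += [(f"AU{i}", "3h", "up") for i in range(8)]
        a += [(f"AD{i}", "3h", "down") for i in range(23)]
        b += [(f"BU{i}", "3h", "up") for i in range(77)]
        b += [(f"BD{i}", "3h", "down") for i in range(27)]
        table = dc.overlap_table(calls_frame(a), calls_frame(b, "B"))
        total = table[(table.timepoint == "3h") & (table.stratum == "total")].iloc[0]
        assert (total.total_a, total.unique_a) == (40, 31)
        assert (total.total_b, total.unique_b) == (113, 104)
        assert (total.common, total.common_pct) == (9, 6)
        up = table[(table.timepoint == "3h") & (table.stratum == "up")].iloc[0]
        assert (up.common, up.common_pct) == (3, 3)
        down = table[(table.timepoint == "3h") & (table.stratum == "down")].iloc[0]
        assert (down.common, down.common_pct) == (6, 11)

    def test_disjoint_and_identical(self):
        a = calls_frame([("P1", "3h", "up"), ("P2", "3h", "down")])
        b = calls_frame([("P3", "3h", "up")], "B")
        row = dc.overlap_table(a, b).iloc[0]
        assert row.common == 0 and row.common_pct == 0
        same = dc.overlap_table(a, a).iloc[0]
        assert same.common == 2 and same.common_pct == 100

    def test_common_requires_matching_direction(self):
        a = calls_frame([("P1", "3h", "up")])
        b = calls_frame([("P1", "3h", "down")], "B")
        assert dc.overlap_table(a, b).iloc[0].common == 0
        assert dc.overlap_table(a, b, match_direction=False).iloc[0].common == 1

    @settings(max_examples=100, derandomize=True)
    @given(
        st.sets(st.integers(0, 40)),
        st.sets(st.integers(0, 40)),
        st.data(),
    )
    def test_arithmetic_identities_on_random_calls(self, ids_a, ids_b, data):
        dirs = st.sampled_from(["up", "down"])
        a = calls_frame([(f"P{i}", "3h", data.draw(dirs)) for i in ids_a])
        b = calls_frame([(f"P{i}", "3h", data.draw(dirs)) for i in ids_b], "B")
        for row in dc.overlap_table(a, b).itertuples():
            assert row.unique_a == row.total_a - row.common
            assert row.unique_b == row.total_b - row.common
            assert row.common_pct == dc.union_percentage(
                row.total_a, row.total_b, row.common
            )


def test_damp_protein_summary_distinct_accounting():
    a = calls_frame(
        [(f"C{i}", "3h", "up") for i in range(54)]
        + [(f"X{i}", "6h", "down") for i in range(28)]
    )
    b = calls_frame(
        [(f"D{i}", "3h", "up") for i in range(109)]
        + [(f"X{i}", "3h", "up") for i in range(28)],
        "B",
    )
    s = dc.damp_protein_summary(a, b)
    assert s == {
        "total_a": 82, "total_b": 137, "unique_a": 54, "unique_b": 109,
        "common": 28, "total_distinct": 191,
    }


class TestCategoryCounts:
    def test_single_label(self):
        calls = calls_frame([("P1", "3h", "up"), ("P2", "3h", "up"), ("P3", "6h", "down")])
        ann = {"P1": ["hydrolase activity"], "P2": ["hydrolase activity"],
               "P3": ["hydrolase activity"]}
        out = dc.category_counts(calls, ann)
        assert out.loc[out.category == "hydrolase activity", "n_damps"].iloc[0] == 3

    def test_multi_label_increments_both(self):
        calls = calls_frame([("P1", "3h", "up")])
        out = dc.category_counts(calls, {"P1": ["binding", "transporter activity"]})
        assert set(out["category"]) == {"binding", "transporter activity"}
        assert (out["n_damps"] == 1).all()

    def test_empty_annotation_buckets_unannotated(self):
        calls = calls_frame([("P1", "3h", "up"), ("P2", "3h", "down")])
        out = dc.category_counts(calls, {})
        assert list(out["category"]) == ["unannotated"]
        assert out["n_damps"].iloc[0] == 2


def brute_hypergeom_tail(k, N, K, n):
    total = math.comb(N, n)
    return sum(
        math.comb(K, i) * math.comb(N - K, n - i)
        for i in range(k, min(K, n) + 1)
    ) / total


class TestEnrich:
    def test_forced_full_overlap(self):
        bg = {f"P{i}" for i in range(20)}
        cat = {f"P{i}" for i in range(5)}
        assert dc.enrich(cat, bg, bg) == pytest.approx(1.0)
        # overlap 5 of 5 selected: p = 1 / C(20,5)
        assert dc.enrich(cat, cat, bg) == pytest.approx(1 / math.comb(20, 5))

    def test_no_overlap_near_one(self):
        bg = {f"P{i}" for i in range(100)}
        cat = {f"P{i}" for i in range(3)}
        sel = {f"P{i}" for i in range(50, 60)}
        p = dc.enrich(cat, sel, bg)
        assert p == pytest.approx(brute_hypergeom_tail(0, 100, 3, 10))
        assert p == 1.0

    def test_matches_brute_force_summation(self):
        ids = [f"P{i}" for i in range(25)]
        for N, K, n in itertools.product([5, 12, 25], [0, 3, 7], [0, 4, 9]):
            if K > N or n > N:
                continue
            bg = set(ids[:N])
            cat = set(ids[:K])
            for k in range(max(0, K + n - N), min(K, n) + 1):
                sel = set(ids[:k]) | set(ids[K : K + n - k])
                assert dc.enrich(cat, sel, bg) == pytest.approx(
                    brute_hypergeom_tail(k, N, K, n), rel=1e-9
                )

    def test_contract_violations(self):
        with pytest.raises(ValueError):
            dc.enrich(set(), set(), set())
        with pytest.raises(ValueError):
            dc.enrich({"Q"}, set(), {"P"})


def test_bh_adjustment_monotone():
    p = [0.001, 0.01, 0.02, 0.5, 0.9]
    adj = dc.adjust_bh(p)
    assert np.all(adj >= p)
    assert np.all(np.diff(adj[np.argsort(p)]) >= -1e-12)
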