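"""Count filtering, enrichment fractions and origin classification."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from oripool.barseq import (
    CALL_ARTIFACT,
    CALL_CARRYOVER,
    CALL_FUNCTIONAL,
    CALL_NOT_DETECTED,
    ClassifierParams,
    CountTable,
    EnrichmentMatrix,
    SampleMeta,
    classify_origins,
    filter_counts,
    origin_enrichment,
    render_matrix,
    strictly_declining,
)


def table_from(counts: dict[str, dict[str, int]], samples=None) -> CountTable:
    rows = [
        {"sample_id": s, "barcode": b, "count": c}
        for s, bcs in counts.items()
        for b, c in bcs.items()
    ]
    metas = samples or {s: SampleMeta(s, "host", "plate") for s in counts}
    return CountTable(pd.DataFrame(rows), metas)


class TestFilterCounts:
    def test_below_six_boundary(self):
        filtered, _ = filter_counts(table_from({"s1": {"b1": 5, "b2": 6, "b3": 100}}))
        assert set(filtered.df["barcode"]) == {"b2", "b3"}

    def test_all_pass_retained_one(self):
        t = table_from({"s1": {"b1": 10, "b2": 6}})
        filtered, retained = filter_counts(t)
        assert filtered.df.equals(t.df) and retained["s1"] == 1.0

    def test_retained_fraction(self):
        _, retained = filter_counts(table_from({"s1": {"b1": 10, "b2": 5, "b3": 85}}))
        assert retained["s1"] == pytest.approx(0.95)

    def test_empty_sample_warns(self):
        with pytest.warns(UserWarning):
            _, retained = filter_counts(table_from({"s1": {"b1": 2}}))
        assert retained["s1"] == 0.0

    @given(st.lists(st.integers(0, 30), min_size=1, max_size=30))
    @settings(derandomize=True, max_examples=50, deadline=None)
    def test_idempotent(self, counts):
        t = table_from({"s1": {f"b{i}": c for i, c in enumerate(counts)}})
        once, _ = filter_counts(t)
        twice, retained = filter_counts(once)
        assert once.df.reset_index(drop=True).equals(twice.df.reset_index(drop=True))
        if once.df["count"].sum() > 0:
            assert retained["s1"] == 1.0


ASSOC = {"x": "A", "y": "A", "z": "A", "u": "B"}


class TestEnrichment:
    def test_fraction_normalization(self):
        m = origin_enrichment(table_from({"s1": {"x": 30, "u": 70}}), ASSOC)
        assert m.fraction("A", "s1") == pytest.approx(0.3)
        assert m.fraction("B", "s1") == pytest.approx(0.7)
        assert m.unmapped_fraction["s1"] == pytest.approx(0.0)

    def test_unmapped_in_denominator(self):
        m = origin_enrichment(table_from({"s1": {"x": 50, "qq": 50}}), ASSOC)
        assert m.fraction("A", "s1") == pytest.approx(0.5)
        assert m.unmapped_fraction["s1"] == pytest.approx(0.5)

    def test_barcode_diversity(self):
        m = origin_enrichment(table_from({"s1": {"x": 10, "y": 20, "z": 6, "u": 7}}), ASSOC)
        assert m.n_barcodes("A", "s1") == 3 and m.n_barcodes("B", "s1") == 1

    def test_fractions_sum_to_one(self):
        rng = np.random.default_rng(1)
        counts = {
            f"s{j}": {f"b{i}": int(rng.integers(6, 500)) for i in range(40)} for j in range(3)
        }
        assoc = {f"b{i}": f"O{i % 7}" for i in range(0, 40, 2)}  # half unmapped
        m = origin_enrichment(table_from(counts), assoc)
        totals = m.df.groupby("sample_id")["fraction"].sum() + m.unmapped_fraction
        assert np.allclose(totals, 1.0, atol=1e-9)

    def test_render_matrix_round_trip(self, tmp_path):
        m = origin_enrichment(table_from({"s1": {"x": 30, "u": 70}, "s2": {"y": 10}}), ASSOC)
        path = tmp_path / "matrix.tsv"
        df = render_matrix(m, None, path)
        assert len(df) == 2 * 2  # 2 origins x 2 samples
        back = EnrichmentMatrix.from_tsv(path, m.samples)
        merged = back.df.merge(m.df, on=["origin", "sample_id"], suffixes=("_a", "_b"))
        assert np.allclose(merged["fraction_a"], merged["fraction_b"], atol=1e-9)

    def test_all_zero_origin_row_present(self):
        m = origin_enrichment(table_from({"s1": {"x": 30}}), ASSOC)
        assert m.fraction("B", "s1") == 0.0 and m.n_barcodes("B", "s1") == 0


class TestTrendDetector:
    @pytest.mark.parametrize(
        "series,expected",
        [
            ([0.04, 0.02, 0.01, 0.005], True),
            ([0.04, 0.04, 0.01], False),
            ([0.04, 0.05, 0.01], False),
            ([0.1, 0.05], None),
            ([], None),
            ([3, 2, 1], True),
        ],
    )
    def test_strict_decline(self, series, expected):
        assert strictly_declining(series) is expected


def make_matrix(rows, samples):
    df = pd.DataFrame(rows, columns=["origin", "sample_id", "fraction", "n_barcodes", "top_barcode_share"])
    origins = sorted(set(df["origin"]))
    full = pd.MultiIndex.from_product([origins, list(samples)], names=["origin", "sample_id"])
    df = df.set_index(["origin", "sample_id"]).reindex(full, fill_value=0).reset_index()
    totals = df.groupby("sample_id")["fraction"].sum()
    return EnrichmentMatrix(df, 1.0 - totals, samples)


HOST_SAMPLES = {
    "plate": SampleMeta("plate", "h", "plate"),
    "out": SampleMeta("out", "h", "plate_outgrowth"),
    **{f"T{t}": SampleMeta(f"T{t}", "h", "liquid", t) for t in (1, 2, 3, 4)},
}


class TestClassification:
    def test_multi_barcode_plate_enrichment_is_functional(self):
        rows = [("good", "plate", 0.6, 40, 0.1)] + [
            ("good", f"T{t}", f, 40, 0.1) for t, f in zip((1, 2, 3, 4), (0.3, 0.4, 0.5, 0.6))
        ]
        calls = classify_origins(make_matrix(rows, HOST_SAMPLES), {"good": 5.0})
        assert calls[0].call == CALL_FUNCTIONAL

    def test_plate_evidence_survives_liquid_decline(self):
        # functional on plate but outcompeted during serial passage
        rows = [("masked", "plate", 0.4, 12, 0.2)] + [
            ("masked", f"T{t}", f, 5, 0.3) for t, f in zip((1, 2, 3, 4), (0.04, 0.02, 0.01, 0.005))
        ]
        calls = classify_origins(make_matrix(rows, HOST_SAMPLES), {"masked": 5.0})
        assert calls[0].call == CALL_FUNCTIONAL

    def test_single_barcode_spike_is_artifact(self):
        rows = [("spike", "plate", 0.02, 3, 0.6)] + [
            ("spike", f"T{t}", f, 1, 1.0) for t, f in zip((1, 2, 3, 4), (0.01, 0.03, 0.08, 0.2))
        ]
        calls = classify_origins(make_matrix(rows, HOST_SAMPLES), {"spike": 1.0})
        assert calls[0].call == CALL_ARTIFACT

    def test_dominated_enrichment_is_artifact_despite_stray_barcodes(self):
        rows = [("spike", "plate", 0.02, 4, 0.5)] + [
            ("spike", f"T{t}", f, n, d)
            for t, f, n, d in [(1, 0.01, 4, 0.5), (2, 0.03, 2, 0.95), (3, 0.08, 2, 0.99), (4, 0.2, 1, 1.0)]
        ]
        calls = classify_origins(make_matrix(rows, HOST_SAMPLES), {"spike": 1.0})
        assert calls[0].call == CALL_ARTIFACT

    def test_low_declining_abundant_origin_is_carryover(self):
        rows = [("co", "plate", 0.045, 8, 0.3), ("co", "out", 0.03, 8, 0.3)] + [
            ("co", f"T{t}", f, 8, 0.3) for t, f in zip((1, 2, 3, 4), (0.04, 0.02, 0.01, 0.005))
        ] + [("rare", "plate", 0.001, 1, 1.0)]
        calls = classify_origins(
            make_matrix(rows, HOST_SAMPLES), {"co": 10.0, "rare": 0.1}
        )
        by = {c.origin: c.call for c in calls}
        assert by["co"] == CALL_CARRYOVER
        assert by["rare"] == CALL_NOT_DETECTED  # low abundance: not carryover

    def test_low_abundance_declining_origin_not_carryover(self):
        rows = [
            ("co", f"T{t}", f, 4, 0.4) for t, f in zip((1, 2, 3, 4), (0.04, 0.02, 0.01, 0.005))
        ] + [("big", "plate", 0.6, 40, 0.1)]
        calls = classify_origins(
            make_matrix(rows, HOST_SAMPLES), {"co": 0.5, "big": 20.0},
            ClassifierParams(abundance_quantile=0.75),
        )
        assert {c.origin: c.call for c in calls}["co"] == CALL_NOT_DETECTED

    def test_missing_liquid_series_gives_partial_evidence(self):
        samples = {"plate": SampleMeta("plate", "h", "plate")}
        rows = [("good", "plate", 0.3, 10, 0.2)]
        calls = classify_origins(make_matrix(rows, samples), {"good": 1.0})
        assert calls[0].call == CALL_FUNCTIONAL and calls[0].partial_evidence

    def test_every_origin_gets_exactly_one_call_per_host(self):
        rows = [("a", "plate", 0.3, 10, 0.2), ("b", "T1", 0.01, 2, 0.5)]
        calls = classify_origins(make_matrix(rows, HOST_SAMPLES), {"a": 1.0, "b": 1.0})
        assert sorted((c.origin, c.host) for c in calls) == [("a", "h"), ("b", "h")]
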