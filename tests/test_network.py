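"""Co-occurrence matrices, co-correlations, and thresholded networks."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import pallimed as pm
from conftest import random_binary_dtm


def make_dtm(columns: dict[str, list[int]], mode="binary"):
    terms = sorted(columns)
    values = np.column_stack([columns[t] for t in terms])
    rows = [f"p{i}" for i in range(values.shape[0])]
    return pm.DocumentTermMatrix(rows, terms, values, mode=mode)


def brute_force_cooccurrence(dtm):
    m = len(dtm.terms)
    out = np.zeros((m, m), dtype=int)
    for i in range(m):
        for j in range(m):
            out[i, j] = int(np.sum(dtm.values[:, i] * dtm.values[:, j]))
    return out


def test_worked_example_cooccurrence(worked_example_dtm):
    C = pm.cooccurrence(worked_example_dtm)
    expected_diag = {"albumin": 3, "vancomycin": 2, "fentanyl": 1, "furosemide": 2}
    for term, d in expected_diag.items():
        assert C.pair(term, term) == d
    assert C.pair("albumin", "vancomycin") == 2
    assert C.pair("albumin", "fentanyl") == 1
    assert C.pair("albumin", "furosemide") == 2
    assert C.pair("vancomycin", "fentanyl") == 1
    assert C.pair("vancomycin", "furosemide") == 1
    assert C.pair("fentanyl", "furosemide") == 1
    assert np.array_equal(C.counts, C.counts.T)


def test_single_column_sum_of_squares():
    dtm = make_dtm({"morphine": [1, 2, 0]}, mode="count")
    C = pm.cooccurrence(dtm)
    assert C.counts.shape == (1, 1) and C.counts[0, 0] == 5


@settings(derandomize=True, max_examples=50)
@given(seed=st.integers(0, 10_000))
def test_cooccurrence_matches_pair_counting(seed):
    dtm = random_binary_dtm(np.random.default_rng(seed))
    C = pm.cooccurrence(dtm)
    assert np.array_equal(C.counts, brute_force_cooccurrence(dtm))


def test_phi_identical_columns():
    dtm = make_dtm({"a": [1, 0, 1], "b": [1, 0, 1]})
    assert pm.cocorrelation(dtm).pair("a", "b") == pytest.approx(1.0)


def test_phi_worked_example_pair():
    # 2x2 table n11=1, n10=1, n01=1, n00=0 -> phi = -0.5
    dtm = make_dtm({"furosemide": [1, 1, 0], "vancomycin": [1, 0, 1]})
    assert pm.cocorrelation(dtm).pair("vancomycin", "furosemide") == pytest.approx(-0.5)


def test_phi_complementary_columns():
    dtm = make_dtm({"a": [1, 0, 1, 0], "b": [0, 1, 0, 1]})
    assert pm.cocorrelation(dtm).pair("a", "b") == pytest.approx(-1.0)


def test_constant_column_undefined():
    dtm = make_dtm({"albumin": [1, 1, 1], "b": [1, 0, 1]})
    corr = pm.cocorrelation(dtm)
    assert np.isnan(corr.pair("albumin", "b"))
    assert np.isnan(corr.pair("albumin", "albumin"))
    net = pm.build_network(dtm, corr=corr, min_frequency=1, corr_threshold=-1.0)
    assert all({a, b} != {"albumin", "b"} for a, b, _ in net.edges)


def test_count_mode_binarized_with_warning():
    dtm = make_dtm({"a": [2, 0, 3], "b": [1, 0, 1]}, mode="count")
    with pytest.warns(UserWarning, match="binariz"):
        corr = pm.cocorrelation(dtm)
    assert corr.pair("a", "b") == pytest.approx(1.0)


def test_unknown_method_rejected(worked_example_dtm):
    with pytest.raises(ValueError, match="method"):
        pm.cocorrelation(worked_example_dtm, method="pearson2")


@pytest.mark.parametrize("method", ["cosine", "jaccard"])
def test_alternative_methods(method):
    dtm = make_dtm({"a": [1, 1, 0, 0], "b": [1, 0, 1, 0]})
    corr = pm.cocorrelation(dtm, method=method)
    n11, fa, fb = 1, 2, 2
    expected = n11 / np.sqrt(fa * fb) if method == "cosine" else n11 / (fa + fb - n11)
    assert corr.pair("a", "b") == pytest.approx(expected)
    assert corr.pair("a", "a") == pytest.approx(1.0)


@settings(derandomize=True, max_examples=40)
@given(seed=st.integers(0, 10_000))
def test_phi_symmetric_and_bounded(seed):
    dtm = random_binary_dtm(np.random.default_rng(seed))
    values = pm.cocorrelation(dtm).values
    finite = np.isfinite(values)
    assert np.array_equal(finite, finite.T)
    assert np.allclose(values[finite], values.T[finite])
    assert (np.abs(values[finite]) <= 1 + 1e-12).all()
    nonconstant = [
        j for j in range(len(dtm.terms))
        if 0 < dtm.values[:, j].sum() < dtm.shape[0]
    ]
    for j in nonconstant:
        assert values[j, j] == pytest.approx(1.0)


def test_single_strong_pair_yields_one_edge():
    # a/b co-occur in 3 of 4 patients; others scattered
    dtm = make_dtm(
        {
            "a": [1, 1, 1, 0],
            "b": [1, 1, 1, 0],
            "c": [1, 0, 0, 1],
            "d": [0, 1, 0, 1],
        }
    )
    net = pm.build_network(dtm, min_frequency=1, corr_threshold=0.5)
    assert net.edges == [("a", "b", 1.0)]
    assert len(net.nodes) == 4  # isolated nodes retained


def test_min_frequency_filters_nodes(worked_example_dtm):
    net = pm.build_network(worked_example_dtm, min_frequency=10, corr_threshold=0.5)
    assert net.nodes == [] and net.edges == []


def test_threshold_zero_matches_enumeration():
    rng = np.random.default_rng(3)
    dtm = random_binary_dtm(rng)
    corr = pm.cocorrelation(dtm)
    net = pm.build_network(dtm, corr=corr, min_frequency=1, corr_threshold=0.0)
    expected = {
        tuple(sorted((corr.terms[i], corr.terms[j])))
        for i in range(len(corr.terms))
        for j in range(i + 1, len(corr.terms))
        if np.isfinite(corr.values[i, j]) and corr.values[i, j] >= 0
    }
    assert {(a, b) for a, b, _ in net.edges} == expected


@settings(derandomize=True, max_examples=30)
@given(
    seed=st.integers(0, 10_000),
    thresholds=st.tuples(
        st.floats(-1, 1, allow_nan=False), st.floats(-1, 1, allow_nan=False)
    ),
    freqs=st.tuples(st.integers(0, 10), st.integers(0, 10)),
)
def test_raising_thresholds_never_adds(seed, thresholds, freqs):
    dtm = random_binary_dtm(np.random.default_rng(seed))
    corr = pm.cocorrelation(dtm)
    t_lo, t_hi = sorted(thresholds)
    f_lo, f_hi = sorted(freqs)
    loose = pm.build_network(dtm, corr=corr, min_frequency=f_lo, corr_threshold=t_lo)
    tight = pm.build_network(dtm, corr=corr, min_frequency=f_hi, corr_threshold=t_hi)
    assert set(t for t, _ in tight.nodes) <= set(t for t, _ in loose.nodes)
    assert {(a, b) for a, b, _ in tight.edges} <= {(a, b) for a, b, _ in loose.edges}


def test_network_invariant_to_row_and_column_order(worked_example_dtm):
    rng = np.random.default_rng(0)
    rp = rng.permutation(worked_example_dtm.shape[0])
    dtm = pm.DocumentTermMatrix(
        [worked_example_dtm.row_ids[i] for i in rp],
        worked_example_dtm.terms,
        worked_example_dtm.values[rp],
    )
    a = pm.build_network(worked_example_dtm, min_frequency=1, corr_threshold=0.0)
    b = pm.build_network(dtm, min_frequency=1, corr_threshold=0.0)
    assert a == b


def test_top_cooccurrences_ordering():
    dtm = make_dtm(
        {
            "a": [1, 1, 1, 0, 0],
            "b": [1, 1, 1, 1, 0],
            "c": [0, 0, 1, 1, 1],
            "d": [1, 0, 1, 0, 1],
        }
    )
    corr = pm.cocorrelation(dtm)
    top = pm.top_cooccurrences(corr, k=3)
    values = [v for _, _, v in top]
    assert values == sorted(values, reverse=True)
    everything = pm.top_cooccurrences(corr, k=100)
    assert len(everything) == 6  # all defined pairs when k exceeds count
    with pytest.raises(ValueError):
        pm.top_cooccurrences(corr, k=0)


def test_top_cooccurrences_tie_lexicographic():
    dtm = make_dtm({"a": [1, 0, 1], "b": [1, 0, 1], "c": [1, 0, 1]})
    top = pm.top_cooccurrences(pm.cocorrelation(dtm), k=3)
    assert [(a, b) for a, b, _ in top] == [("a", "b"), ("a", "c"), ("b", "c")]


def test_graphml_roundtrip(tmp_path, worked_example_dtm):
    net = pm.build_network(worked_example_dtm, min_frequency=1, corr_threshold=0.0)
    path = tmp_path / "net.graphml"
    pm.export_network(net, path)
    assert pm.load_network(path) == net


def test_one_edge_graphml(tmp_path):
    dtm = make_dtm({"a": [1, 0, 1], "b": [1, 0, 1]})
    net = pm.build_network(dtm, min_frequency=1, corr_threshold=0.5)
    path = tmp_path / "net.graphml"
    pm.export_network(net, path)
    back = pm.load_network(path)
    assert back.graph.number_of_nodes() == 2
    assert back.graph.number_of_edges() == 1


def test_empty_network_exports(tmp_path, worked_example_dtm):
    net = pm.build_network(worked_example_dtm, min_frequency=99)
    path = tmp_path / "empty.graphml"
    pm.export_network(net, path)
    assert pm.load_network(path).graph.number_of_nodes() == 0


def test_edge_tsv_export(tmp_path, worked_example_dtm):
    net = pm.build_network(worked_example_dtm, min_frequency=1, corr_threshold=0.0)
    path = tmp_path / "net.tsv"
    pm.export_network(net, path, fmt="edge-tsv")
    lines = path.read_text().strip().splitlines()
    assert lines[0] == "term_a\tterm_b\tcocorrelation"
    assert len(lines) - 1 == len(net.edges)
    nodes = (tmp_path / "net.nodes.tsv").read_text()
    assert "min_frequency=1" in nodes and "albumin" in nodes


def test_builder_estimator(worked_example_dtm):
    builder = pm.CooccurrenceNetworkBuilder(min_frequency=1, corr_threshold=0.0)
    builder.fit(worked_example_dtm)
    assert builder.cooccurrence_.pair("albumin", "albumin") == 3
    assert builder.network_.min_frequency == 1
    with pytest.raises(TypeError):
        pm.CooccurrenceNetworkBuilder().fit(worked_example_dtm.values)
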