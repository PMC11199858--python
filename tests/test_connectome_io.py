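"""Connectome container, file round trips and FLNe/LNe conversions."""

import numpy as np
import pytest

from cortexflow import (
    Connectome,
    InjectionRecord,
    NodeMeta,
    compute_distances,
    flne_to_lne,
    lne_to_flne,
    read_adjacency,
    read_injection_records,
    read_link_list,
    read_node_meta,
    write_adjacency,
    write_injection_records,
    write_link_list,
    write_node_meta,
)

from conftest import random_connectome


# ---------------------------------------------------------------------------
# containers
# ---------------------------------------------------------------------------


def test_duplicate_labels_rejected():
    with pytest.raises(ValueError, match="duplicate"):
        Connectome(labels=["A", "A"], W=np.zeros((2, 2)))


def test_self_links_rejected():
    W = np.eye(2)
    with pytest.raises(ValueError, match="self-link"):
        Connectome(labels=["A", "B"], W=W)


def test_negative_weights_rejected():
    W = np.array([[0.0, -1.0], [0.0, 0.0]])
    with pytest.raises(ValueError, match="negative"):
        Connectome(labels=["A", "B"], W=W)


def test_flne_column_sum_validated():
    W = np.array([[0.0, 0.4], [0.0, 0.0]])  # column sums 0.4, not 1
    with pytest.raises(ValueError, match="sum to 1"):
        Connectome(labels=["A", "B"], W=W, weight_kind="FLNe",
                   measured=np.array([False, True]))


def test_node_meta_requires_finite_coord():
    with pytest.raises(ValueError):
        NodeMeta(label="A", coord=(0.0, np.nan, 1.0))


def test_injection_record_count_consistency():
    with pytest.raises(ValueError, match="LNtot"):
        InjectionRecord(target="A", LNi=10, LNe_total=20, LNtot=999)
    with pytest.raises(ValueError):
        InjectionRecord(target="A", LNi=-1, LNe_total=1, LNtot=0)


# ---------------------------------------------------------------------------
# link-list reading
# ---------------------------------------------------------------------------


@pytest.mark.parametrize("delim", ["\t", ",", " "])
def test_read_link_list_three_rows(tmp_path, delim):
    path = tmp_path / "links.txt"
    path.write_text(
        f"A{delim}B{delim}2.0\nB{delim}C{delim}1.0\nA{delim}C{delim}0.5\n"
    )
    c = read_link_list(str(path))
    assert c.n_nodes == 3 and c.n_links == 3
    assert c.W[c.index("A"), c.index("B")] == 2.0
    # B and C appear as targets -> measured
    assert list(c.measured) == [False, True, True]


def test_read_link_list_header_and_comments(tmp_path):
    path = tmp_path / "links.tsv"
    path.write_text("# a comment\nsource\ttarget\tweight\nA\tB\t1.5\n")
    c = read_link_list(str(path))
    assert c.n_links == 1 and c.W[0, 1] == 1.5


def test_read_link_list_empty_is_error(tmp_path):
    path = tmp_path / "empty.txt"
    path.write_text("# nothing here\n")
    with pytest.raises(ValueError, match="no links parsed"):
        read_link_list(str(path))


def test_read_link_list_missing_file():
    with pytest.raises(FileNotFoundError):
        read_link_list("/nonexistent/links.txt")


def test_read_link_list_self_link_reports_row(tmp_path):
    path = tmp_path / "links.txt"
    path.write_text("A\tB\t1.0\nB\tB\t2.0\n")
    with pytest.raises(ValueError, match=":2"):
        read_link_list(str(path))


def test_read_link_list_negative_weight(tmp_path):
    path = tmp_path / "links.txt"
    path.write_text("A\tB\t-1.0\n")
    with pytest.raises(ValueError, match="negative"):
        read_link_list(str(path))


def test_read_link_list_duplicates(tmp_path):
    path = tmp_path / "links.txt"
    path.write_text("A\tB\t1.0\nA\tB\t2.0\n")
    with pytest.raises(ValueError, match="duplicate"):
        read_link_list(str(path))
    c = read_link_list(str(path), aggregate="sum")
    assert c.W[0, 1] == 3.0


def test_link_list_round_trip(tmp_path, toy_connectome):
    path = tmp_path / "links.tsv"
    write_link_list(toy_connectome, str(path))
    c2 = read_link_list(str(path))
    for s in toy_connectome.labels:
        for t in toy_connectome.labels:
            w = toy_connectome.W[toy_connectome.index(s), toy_connectome.index(t)]
            if w > 0:
                assert c2.W[c2.index(s), c2.index(t)] == pytest.approx(w)
    assert c2.n_links == toy_connectome.n_links


# ---------------------------------------------------------------------------
# adjacency reading
# ---------------------------------------------------------------------------


def test_read_adjacency_2x2(tmp_path):
    path = tmp_path / "adj.csv"
    path.write_text(",A,B\nA,0,3\nB,1,0\n")
    c = read_adjacency(str(path))
    assert c.W[c.index("A"), c.index("B")] == 3.0
    assert c.W[c.index("B"), c.index("A")] == 1.0


def test_adjacency_round_trip(tmp_path, toy_connectome):
    path = tmp_path / "adj.csv"
    write_adjacency(toy_connectome, str(path))
    c2 = read_adjacency(str(path))
    links1 = {
        (s, t, round(float(toy_connectome.W[i, j]), 9))
        for i, s in enumerate(toy_connectome.labels)
        for j, t in enumerate(toy_connectome.labels)
        if toy_connectome.W[i, j] > 0
    }
    links2 = {
        (s, t, round(float(c2.W[i, j]), 9))
        for i, s in enumerate(c2.labels)
        for j, t in enumerate(c2.labels)
        if c2.W[i, j] > 0
    }
    assert links1 == links2


def test_rectangular_adjacency(tmp_path):
    """116 sources x 55 measured targets unions to one 116-node network."""
    rng = np.random.default_rng(7)
    sources = [f"s{i:03d}" for i in range(116)]
    targets = sources[:55]
    M = (rng.uniform(size=(116, 55)) < 0.2) * rng.lognormal(0, 1, (116, 55))
    for j in range(55):
        M[j, j] = 0.0  # no self-links
    path = tmp_path / "rect.csv"
    lines = ["," + ",".join(targets)]
    for i, s in enumerate(sources):
        lines.append(s + "," + ",".join(f"{v:.10g}" for v in M[i]))
    path.write_text("\n".join(lines) + "\n")
    c = read_adjacency(str(path))
    assert c.n_nodes == 116
    assert int(c.measured.sum()) == 55
    expect = {
        (sources[i], targets[j]): float(M[i, j])
        for i in range(116)
        for j in range(55)
        if M[i, j] > 0
    }
    got = {
        (c.labels[i], c.labels[j]): float(c.W[i, j])
        for i, j in zip(*np.nonzero(c.W))
    }
    assert set(expect) == set(got)
    for key, val in expect.items():
        assert got[key] == pytest.approx(val, rel=1e-9)


def test_adjacency_duplicate_or_bad_cells(tmp_path):
    p1 = tmp_path / "dup.csv"
    p1.write_text(",A,A\nA,0,1\nB,1,0\n")
    with pytest.raises(ValueError, match="duplicate"):
        read_adjacency(str(p1))
    p2 = tmp_path / "bad.csv"
    p2.write_text(",A,B\nA,0,x\nB,1,0\n")
    with pytest.raises(ValueError, match="non-numeric"):
        read_adjacency(str(p2))


# ---------------------------------------------------------------------------
# metadata / records files
# ---------------------------------------------------------------------------


def test_node_meta_round_trip(tmp_path, toy_connectome):
    path = tmp_path / "meta.tsv"
    write_node_meta(toy_connectome, str(path))
    df = read_node_meta(str(path))
    assert list(df.index) == toy_connectome.labels
    np.testing.assert_allclose(
        df[["x_mm", "y_mm", "z_mm"]].to_numpy(), toy_connectome.coords
    )
    assert list(df["measured"]) == list(toy_connectome.measured)


def test_injection_records_round_trip(tmp_path):
    recs = [
        InjectionRecord("B", 1.0, 10.0, 200.0, 210.0),
        InjectionRecord("C", 0.5, 5.0, 50.0, 55.0),
    ]
    path = tmp_path / "recs.tsv"
    write_injection_records(recs, str(path))
    back = read_injection_records(str(path))
    assert back == recs


# ---------------------------------------------------------------------------
# weight conversions
# ---------------------------------------------------------------------------


def _two_node_flne():
    W = np.zeros((3, 3))
    W[0, 2] = 0.25
    W[1, 2] = 0.75
    return Connectome(
        labels=["A", "B", "T"], W=W, weight_kind="FLNe",
        measured=np.array([False, False, True]),
    )


def test_flne_to_lne_scales_column():
    c = _two_node_flne()
    out = flne_to_lne(c, [InjectionRecord("T", LNe_total=200.0)])
    np.testing.assert_allclose(out.W[:, 2], [50.0, 150.0, 0.0])
    assert out.W[:, 2].sum() == pytest.approx(200.0, abs=1e-9)
    assert out.weight_kind == "LNe"


def test_flne_to_lne_single_source():
    W = np.zeros((2, 2))
    W[0, 1] = 1.0
    c = Connectome(labels=["A", "T"], W=W, weight_kind="FLNe",
                   measured=np.array([False, True]))
    out = flne_to_lne(c, [InjectionRecord("T", LNe_total=500.0)])
    assert out.W[0, 1] == pytest.approx(500.0)


def test_flne_to_lne_missing_record_and_bad_total():
    c = _two_node_flne()
    with pytest.raises(ValueError, match="no injection record"):
        flne_to_lne(c, [InjectionRecord("X", LNe_total=10.0)])
    with pytest.raises(ValueError, match="non-positive"):
        flne_to_lne(c, [InjectionRecord("T", LNe_total=0.0)])


@pytest.mark.parametrize(
    "combine,expected", [("mean", 150.0), ("sum", 300.0), ("max", 200.0)]
)
def test_flne_to_lne_pooling_policies(combine, expected):
    c = _two_node_flne()
    recs = [InjectionRecord("T", LNe_total=100.0), InjectionRecord("T", LNe_total=200.0)]
    out = flne_to_lne(c, recs, combine=combine)
    assert out.W[:, 2].sum() == pytest.approx(expected)


def test_lne_to_flne_examples():
    W = np.zeros((3, 3))
    W[0, 2] = 50.0
    W[1, 2] = 150.0
    c = Connectome(labels=["A", "B", "T"], W=W,
                   measured=np.array([False, True, True]))
    out = lne_to_flne(c)
    np.testing.assert_allclose(out.W[:, 2], [0.25, 0.75, 0.0])
    # measured-but-unconnected column B stays zero, no NaN
    assert np.all(out.W[:, 1] == 0.0)
    assert np.all(np.isfinite(out.W))


def test_conversion_round_trip_against_normalisation_oracle():
    """flne_to_lne(lne_to_flne(x)) with totals from x reproduces x; the FLNe
    side is checked against an independent per-column normalisation."""
    rng = np.random.default_rng(11)
    for _ in range(10):
        c = random_connectome(rng, n=20, measured_frac=0.4)
        flne = lne_to_flne(c)
        # independent oracle: explicit per-column loop
        for j in range(c.n_nodes):
            s = c.W[:, j].sum()
            if s > 0:
                np.testing.assert_allclose(flne.W[:, j], c.W[:, j] / s, atol=1e-12)
        recs = [
            InjectionRecord(lab, LNe_total=float(c.W[:, j].sum()))
            for j, lab in enumerate(c.labels)
            if c.W[:, j].sum() > 0
        ]
        back = flne_to_lne(flne, recs)
        np.testing.assert_allclose(back.W, c.W, atol=1e-12)


def test_conversions_preserve_counts(synth_small):
    c, _ = synth_small
    flne = lne_to_flne(c)
    assert flne.n_links == c.n_links
    assert flne.n_nodes == c.n_nodes
    assert int(flne.measured.sum()) == int(c.measured.sum())


# ---------------------------------------------------------------------------
# distances
# ---------------------------------------------------------------------------


def test_compute_distances_345():
    c = Connectome(
        labels=["A", "B"], W=np.zeros((2, 2)),
        measured=np.array([True, True]),
        coords=np.array([[0.0, 0.0, 0.0], [3.0, 4.0, 0.0]]),
    )
    c = compute_distances(c)
    assert c.D[0, 1] == pytest.approx(5.0)
    assert np.all(np.diag(c.D) == 0.0)


def test_compute_distances_matches_elementwise():
    rng = np.random.default_rng(3)
    coords = rng.uniform(-5, 5, size=(50, 3))
    c = Connectome(
        labels=[f"n{i}" for i in range(50)], W=np.zeros((50, 50)),
        measured=np.ones(50, bool), coords=coords,
    )
    c = compute_distances(c)
    for i in range(50):
        for j in range(50):
            assert c.D[i, j] == pytest.approx(
                float(np.sqrt(((coords[i] - coords[j]) ** 2).sum())), abs=1e-12
            )


def test_compute_distances_requires_coords(toy_connectome):
    c = toy_connectome.copy()
    c.coords = None
    with pytest.raises(ValueError, match="coordinates"):
        compute_distances(c)
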