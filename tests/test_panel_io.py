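"""Panel, graph and report I/O: round-trips and validation errors."""

import json

import numpy as np
import pandas as pd
import pytest

from mortmap import (
    AdjacencyGraph,
    ArealPanel,
    make_srs_graph,
    read_graph,
    read_panel,
    simulate_panel,
    write_graph,
    write_panel,
    write_report,
)
from mortmap.sampler import ModelFitStats


def test_counts_roundtrip_toy(tmp_path, toy_panel):
    p = tmp_path / "counts.csv"
    write_panel(toy_panel, p)
    back = read_panel(p)
    assert back.area_ids == ["a", "b"]
    assert back.time_ids == [1, 2]
    np.testing.assert_array_equal(back.O, [[10, 12], [20, 18]])


def test_counts_roundtrip_simulated(tmp_path, srs_graph):
    panel, _ = simulate_panel(
        srs_graph, T=5, seed=11,
        covariate_spec=[{"name": "anc", "beta": 0.2, "corr_with_s": 0.5}],
    )
    write_panel(panel, tmp_path / "c.csv", tmp_path / "x.csv", header="seed=11")
    back = read_panel(tmp_path / "c.csv", tmp_path / "x.csv")
    assert back.area_ids == panel.area_ids
    np.testing.assert_array_equal(back.O, panel.O)
    np.testing.assert_allclose(back.X.to_numpy(), panel.X.to_numpy(), rtol=1e-6)


@pytest.mark.parametrize(
    "obs,match",
    [(-5, "negative"), (3.5, "non-integer"), ("x", "non-numeric")],
)
def test_counts_bad_observed_rejected(tmp_path, obs, match):
    p = tmp_path / "bad.csv"
    p.write_text(
        "area_id,time_id,observed\n"
        f"a,1,10\na,2,{obs}\nb,1,7\nb,2,9\n"
    )
    with pytest.raises(ValueError, match=match):
        read_panel(p)


def test_counts_missing_cell_lists_it(tmp_path):
    p = tmp_path / "gap.csv"
    p.write_text("area_id,time_id,observed\na,1,10\na,2,11\nb,1,7\n")
    with pytest.raises(ValueError, match=r"missing \(area,time\)"):
        read_panel(p)


def test_covariate_area_mismatch(tmp_path, toy_panel):
    write_panel(toy_panel, tmp_path / "c.csv")
    (tmp_path / "x.csv").write_text("area_id,anc\na,60\nb,70\nzzz,80\n")
    with pytest.raises(ValueError, match="zzz"):
        read_panel(tmp_path / "c.csv", tmp_path / "x.csv")


def test_panel_area_order_is_first_appearance(tmp_path):
    p = tmp_path / "c.csv"
    p.write_text("area_id,time_id,observed\nz,1,1\nz,2,2\na,2,4\na,1,3\n")
    panel = read_panel(p)
    assert panel.area_ids == ["z", "a"]
    assert panel.time_ids == [1, 2]
    np.testing.assert_array_equal(panel.O, [[1, 2], [3, 4]])


# -- graphs -----------------------------------------------------------------

def test_graph_parse_path(tmp_path):
    p = tmp_path / "g.txt"
    p.write_text("3\n1 1 2\n2 2 1 3\n3 1 2\n")
    g = read_graph(p)
    assert g.neighbors == [[2], [1, 3], [2]]
    assert g.islands == []


def test_graph_asymmetry_names_pair(tmp_path):
    p = tmp_path / "g.txt"
    p.write_text("2\n1 1 2\n2 0\n")
    with pytest.raises(ValueError, match="node 1 lists 2"):
        read_graph(p)


def test_graph_island_parses_and_is_flagged(tmp_path):
    p = tmp_path / "g.txt"
    p.write_text("3\n1 1 2\n2 1 1\n3 0\n")
    g = read_graph(p)
    assert g.islands == [3]


@pytest.mark.parametrize(
    "body,match",
    [
        ("2\n1 2 2 2\n2 1 1\n", "duplicate"),
        ("2\n1 1 5\n2 0\n", "outside"),
        ("2\n1 1 1\n2 0\n", "itself"),
    ],
)
def test_graph_invalid_rejected(tmp_path, body, match):
    p = tmp_path / "g.txt"
    p.write_text(body)
    with pytest.raises(ValueError, match=match):
        read_graph(p)


def test_graph_rejects_every_asymmetric_two_node_listing():
    for nbrs in ([[2], []], [[], [1]]):
        with pytest.raises(ValueError, match="asymmetric"):
            AdjacencyGraph(2, nbrs)


def test_graph_write_read_roundtrip(tmp_path, srs_graph):
    write_graph(srs_graph, tmp_path / "g.txt", header="fixture")
    back = read_graph(tmp_path / "g.txt")
    assert back.neighbors == srs_graph.neighbors


# -- reports ----------------------------------------------------------------

def _fake_risk_report():
    return pd.DataFrame(
        {
            "area_id": ["a", "b", "c"],
            "spatial_rr": [1.2345678, 0.891, 1.0],
            "exceed_prob": [0.9, 0.2, 0.55],
            "label": ["hot", "cold", "hot"],
            "delta_mean": [0.01, -0.02, 0.0],
            "delta_lo": [-0.1, -0.2, -0.05],
            "delta_hi": [0.12, 0.16, 0.05],
        }
    )


def test_risk_report_csv_schema(tmp_path):
    path = tmp_path / "risk.csv"
    write_report(_fake_risk_report(), path, "csv")
    back = pd.read_csv(path, comment="#")
    assert list(back.columns) == [
        "area_id", "spatial_rr", "exceed_prob", "label",
        "delta_mean", "delta_lo", "delta_hi",
    ]
    assert np.isclose(back["spatial_rr"][0], 1.23457)  # 6 significant digits


def test_report_json_roundtrip(tmp_path):
    stats = ModelFitStats(dbar=100.123456789, d_at_mean=90.0, p_d=10.123456789,
                          dic=110.246913578)
    path = tmp_path / "fit.json"
    write_report(stats, path, "json")
    first = json.loads(path.read_text())
    write_report(pd.DataFrame([first]), tmp_path / "fit2.json", "json")
    second = json.loads((tmp_path / "fit2.json").read_text())
    assert first == second  # lossless at 6 significant digits


def test_report_unknown_format(tmp_path):
    with pytest.raises(ValueError, match="xml"):
        write_report(_fake_risk_report(), tmp_path / "r.xml", "xml")
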