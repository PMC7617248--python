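"""Ingestion, validation and network construction."""

from itertools import combinations

import pytest

from nmabridge import (
    SchemaError,
    ValidationError,
    build_network,
    common_treatments,
    flag_nct_studies,
    network_descriptives,
    read_arm_table,
    write_arm_table,
)
from nmabridge.data_model import export_edge_list
from nmabridge.simulate import ScenarioConfig, generate_scenario

from conftest import make_dataset, make_study


def test_minimal_two_row_csv(tmp_path):
    p = tmp_path / "mini.csv"
    p.write_text(
        "study,subgroup,treatment,n,mean,sd\n"
        "s1,P1,A,10,0.5,1.0\n"
        "s1,P1,B,12,0.9,1.1\n"
    )
    ds = read_arm_table(p)
    assert ds.n_studies == 1
    assert ds.studies[0].n_arms == 2
    assert ds.studies[0].treatments == ("A", "B")


def test_missing_column_is_schema_error(tmp_path):
    p = tmp_path / "bad.csv"
    p.write_text("study,treatment,n,mean\ns1,A,10,0.5\n")
    with pytest.raises(SchemaError, match="sd"):
        read_arm_table(p)


@pytest.mark.parametrize(
    "row, message",
    [
        ("s1,P1,A,10,0.5,0.0", "sd"),
        ("s1,P1,A,0,0.5,1.0", "n"),
    ],
)
def test_invalid_arm_named_in_error(tmp_path, row, message):
    p = tmp_path / "bad.csv"
    p.write_text(
        "study,subgroup,treatment,n,mean,sd\n"
        f"{row}\n"
        "s1,P1,B,10,0.9,1.1\n"
    )
    with pytest.raises(ValidationError, match=message):
        read_arm_table(p)


def test_duplicate_treatment_within_study_rejected(tmp_path):
    p = tmp_path / "dup.csv"
    p.write_text(
        "study,subgroup,treatment,n,mean,sd\n"
        "s1,P1,A,10,0.5,1.0\n"
        "s1,P1,a ,12,0.9,1.1\n"  # same drug, different formatting
    )
    with pytest.raises(ValidationError, match="duplicate"):
        read_arm_table(p)


def test_dialect_mapping(tmp_path):
    p = tmp_path / "alt.csv"
    p.write_text("trial,drug,N,chg,stdev\nt1,A,10,0.1,1.0\nt1,B,10,0.4,1.0\n")
    ds = read_arm_table(
        p,
        dialect={"study": "trial", "treatment": "drug", "n": "N",
                 "mean": "chg", "sd": "stdev"},
        subgroup="P1",
    )
    assert ds.n_studies == 1


def test_round_trip_preserves_dataset(tmp_path):
    _, dense, _ = generate_scenario(ScenarioConfig(seed=5))
    p = tmp_path / "dense.csv"
    write_arm_table(dense, p)
    back = read_arm_table(p)
    assert back == dense


def test_rebaseline_option(tmp_path):
    p = tmp_path / "rb.csv"
    p.write_text(
        "study,subgroup,treatment,n,mean,sd\n"
        "s1,P1,A,10,0.5,1.0\ns1,P1,Placebo,10,0.0,1.0\n"
    )
    ds = read_arm_table(p, rebaseline_to="placebo")
    assert ds.studies[0].treatments[0] == "Placebo"


def test_three_arm_study_gives_three_edges():
    ds = make_dataset(
        [make_study("s1", [("A", 10, 0, 1), ("B", 10, 0, 1), ("C", 10, 0, 1)])]
    )
    net = build_network(ds, "A")
    assert len(net.edges) == 3


def test_two_study_chain_network():
    ds = make_dataset(
        [
            make_study("s1", [("A", 10, 0, 1), ("B", 10, 0, 1)]),
            make_study("s2", [("B", 10, 0, 1), ("C", 10, 0, 1)]),
        ]
    )
    net = build_network(ds, "A")
    assert len(net.nodes) == 3
    assert net.n_direct == 2


def test_empty_dataset_rejected():
    with pytest.raises(ValidationError):
        build_network(make_dataset([]), "A")


def test_edge_count_matches_brute_force():
    """Oracle: double loop over studies x treatment pairs."""
    _, dense, _ = generate_scenario(
        ScenarioConfig(seed=9, studies_per_edge_dense=2)
    )
    ds = make_dataset(
        list(dense.studies)
        + [make_study("m1", [("Placebo", 10, 0, 1), ("DrugA", 10, 0, 1),
                             ("DrugB", 10, 0.2, 1)], subgroup="dense")],
        subgroup="dense",
    )
    net = build_network(ds, "Placebo")
    expected = set()
    for s in ds.studies:
        for a, b in combinations(s.treatments, 2):
            expected.add(frozenset((a, b)))
    assert net.n_direct == len(expected)
    assert net.n_direct <= network_descriptives(net, ds).n_possible


def test_descriptives_trial_pace_and_possible_comparisons():
    # 19 trials over 1973-2017 among 15 treatments, as in a sparse
    # pediatric psychiatry network
    studies = []
    years = [1973] + [1980 + 2 * i for i in range(17)] + [2017]
    for i, y in enumerate(years):
        studies.append(
            make_study(
                f"s{i}",
                [("Placebo", 56, 0.0, 1.0), (f"T{i % 14}", 57, 0.3, 1.0)],
                year=y,
            )
        )
    ds = make_dataset(studies)
    net = build_network(ds, "Placebo")
    summ = network_descriptives(net, ds)
    assert summ.n_treatments == 15
    assert summ.n_possible == 105
    assert summ.n_studies == 19
    assert round(summ.mean_years_per_study, 1) == 2.3
    assert summ.median_sample_size == 113


def test_median_sample_size_single_study():
    ds = make_dataset([make_study("s1", [("A", 10, 0, 1), ("B", 10, 0, 1)])])
    net = build_network(ds, "A")
    assert network_descriptives(net, ds).median_sample_size == 20


def test_common_treatments_union_intersection():
    ds1 = make_dataset(
        [make_study("s1", [("A", 9, 0, 1), ("B", 9, 0, 1), ("C", 9, 0, 1)])]
    )
    ds2 = make_dataset(
        [make_study("s2", [("b", 9, 0, 1), ("c", 9, 0, 1), ("D", 9, 0, 1)])],
    )
    t_a, t_c = common_treatments(build_network(ds1, "A"), build_network(ds2, "b"))
    assert t_a == ["A", "B", "C", "D"]
    assert t_c == ["B", "C"]  # case-insensitive match, first spelling wins


def test_identical_networks_share_everything():
    ds = make_dataset([make_study("s1", [("A", 9, 0, 1), ("B", 9, 0, 1)])])
    net = build_network(ds, "A")
    t_a, t_c = common_treatments(net, net)
    assert t_a == t_c == ["A", "B"]


def test_disjoint_networks_error():
    ds1 = make_dataset([make_study("s1", [("A", 9, 0, 1), ("B", 9, 0, 1)])])
    ds2 = make_dataset([make_study("s2", [("C", 9, 0, 1), ("D", 9, 0, 1)])])
    with pytest.raises(ValidationError, match="bridge"):
        common_treatments(build_network(ds1, "A"), build_network(ds2, "C"))


def test_flag_nct_studies():
    dense = make_dataset(
        [
            make_study("in", [("B", 9, 0, 1), ("C", 9, 0, 1)]),
            make_study("out", [("B", 9, 0, 1), ("D", 9, 0, 1)]),
        ]
    )
    assert flag_nct_studies(dense, ["A", "B", "C"]) == {"out"}


def test_edge_list_export(tmp_path, triangle_ds):
    import pandas as pd

    net = build_network(triangle_ds, "Placebo")
    p = tmp_path / "edges.csv"
    export_edge_list(net, p)
    df = pd.read_csv(p)
    assert set(df.columns) == {"treat1", "treat2", "n_studies", "study_ids"}
    assert df["n_studies"].sum() == 4
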