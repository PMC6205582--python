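import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from metabotrend import (
    InputVectorSet,
    annotate_peaks,
    expected_mz,
    export_pathway_lists,
    pathway_overlap,
)
from metabotrend.clustering import ClusterModel
from metabotrend.core_data import KnowledgeBase, empty_pathways

PROTON = 1.007276


def _kb(compounds=None, pathways=None):
    if compounds is None:
        compounds = {"glc": ("glucose", 180.063388)}
    comp = pd.DataFrame(
        {
            "name": [v[0] for v in compounds.values()],
            "monoisotopic_mass": [v[1] for v in compounds.values()],
        },
        index=pd.Index(list(compounds), name="compound_id"),
    )
    adducts = pd.DataFrame(
        {"n": [1, 1], "charge": [1, -1], "mass_shift": [PROTON, -PROTON]},
        index=pd.Index(["[M+H]+", "[M-H]-"], name="adduct"),
    )
    pw = empty_pathways()
    if pathways:
        pw = pd.DataFrame(
            [
                {"pathway_id": pid, "pathway_name": pid, "compound_id": cid}
                for pid, members in pathways.items()
                for cid in members
            ]
        )
    return KnowledgeBase(compounds=comp, adducts=adducts, pathways=pw)


def _peaks(rows):
    df = pd.DataFrame(rows, columns=["peak_id", "mz", "mode"])
    df["rt"] = 60.0
    return df.set_index("peak_id")


def test_expected_mz_identity_adduct():
    assert expected_mz(250.0, 1, 1, 0.0) == pytest.approx(250.0)


def test_expected_mz_protonated_glucose():
    assert expected_mz(180.063388, 1, 1, PROTON) == pytest.approx(181.070664, abs=1e-6)


def test_expected_mz_doubly_charged():
    assert expected_mz(100.0, 1, 2, 2 * PROTON) == pytest.approx(51.007276, abs=1e-6)


def test_zero_charge_rejected():
    with pytest.raises(ValueError):
        expected_mz(100.0, 1, 0, 0.0)


def test_empty_compound_table_yields_no_annotations():
    kb = _kb()
    kb_empty = KnowledgeBase(
        compounds=kb.compounds.iloc[:0], adducts=kb.adducts, pathways=empty_pathways()
    )
    ann = annotate_peaks(_peaks([("p1", 181.0707, "+")]), kb_empty, 5.0)
    assert ann.empty


def test_match_within_5ppm_with_signed_error():
    ann = annotate_peaks(_peaks([("p1", 181.070700, "+")]), _kb(), 5.0)
    assert len(ann) == 1
    row = ann.iloc[0]
    assert row["compound_id"] == "glc" and row["adduct"] == "[M+H]+"
    assert row["error_ppm"] == pytest.approx(0.20, abs=0.02)
    assert row["confidence"] == "putative (MSI level 5)"


def test_peak_24ppm_away_not_matched_at_5ppm():
    ann = annotate_peaks(_peaks([("p1", 181.0750, "+")]), _kb(), 5.0)
    assert ann.empty


def test_polarity_filtering():
    # negative-mode peak at the protonated (positive) target: no match;
    # at the deprotonated target: match
    kb = _kb()
    pos_target = 181.070664
    neg_target = 180.063388 - PROTON
    ann = annotate_peaks(
        _peaks([("p1", pos_target, "-"), ("p2", neg_target, "-")]), kb, 5.0
    )
    assert list(ann["peak_id"]) == ["p2"]
    assert ann.iloc[0]["adduct"] == "[M-H]-"


@settings(derandomize=True, max_examples=20)
@given(perm=st.permutations(range(4)))
def test_annotation_independent_of_peak_order(perm):
    rows = [
        ("p1", 181.070664, "+"),
        ("p2", 179.056112, "-"),
        ("p3", 300.0, "+"),
        ("p4", 181.070700, "+"),
    ]
    reordered = [rows[i] for i in perm]
    a = annotate_peaks(_peaks(rows), _kb(), 5.0)
    b = annotate_peaks(_peaks(reordered), _kb(), 5.0)
    pd.testing.assert_frame_equal(a, b)


# ---------------------------------------------------------------------------
# pathway overlap
# ---------------------------------------------------------------------------

def _model(cluster_members: dict[int, list[str]]):
    labels = [p for members in cluster_members.values() for p in members]
    assignment = np.array(
        [c for c, members in cluster_members.items() for _ in members]
    )
    vs = InputVectorSet(
        mode="concatenated",
        matrix=np.zeros((len(labels), 1)),
        labels=labels,
        layout=[("*", 0.0)],
    )
    return ClusterModel(
        vectors=vs,
        centers=np.zeros((max(cluster_members) + 1, 1)),
        assignment=assignment,
        distances=np.zeros(len(labels)),
    )


def _annotations(pairs):
    return pd.DataFrame(
        [
            {
                "peak_id": p,
                "compound_id": c,
                "adduct": "[M+H]+",
                "expected_mz": 0.0,
                "observed_mz": 0.0,
                "error_ppm": 0.0,
                "confidence": "putative (MSI level 5)",
            }
            for p, c in pairs
        ]
    )


def test_no_annotations_no_overlap_rows():
    kb = _kb(
        compounds={"A": ("cA", 100.0)}, pathways={"P1": ["A"]}
    )
    out = pathway_overlap(_model({0: ["p1"]}), _annotations([]), kb)
    assert out.empty


def test_overlap_counts_worked_example():
    # p1->A, p2->A, p3->B, p4 unannotated; P1={A,C}, P2={B}
    kb = _kb(
        compounds={"A": ("cA", 100.0), "B": ("cB", 200.0), "C": ("cC", 300.0)},
        pathways={"P1": ["A", "C"], "P2": ["B"]},
    )
    model = _model({0: ["p1", "p2", "p3", "p4"]})
    ann = _annotations([("p1", "A"), ("p2", "A"), ("p3", "B")])
    out = pathway_overlap(model, ann, kb).set_index("pathway_id")
    assert out.loc["P1", "n_peaks"] == 2 and out.loc["P1", "n_compounds"] == 1
    assert out.loc["P2", "n_peaks"] == 1 and out.loc["P2", "n_compounds"] == 1
    # sorted by n_peaks descending
    assert list(out.index) == ["P1", "P2"]


def test_overlap_count_bounds(small_study):
    ds, kb, _ = small_study
    from metabotrend import dkmeanspp, group_profiles, build_input_vectors

    prof = group_profiles(ds, window=0)
    vs = build_input_vectors(prof)
    model = dkmeanspp(vs, k=3)
    ann = annotate_peaks(ds.peaks, kb, 5.0)
    out = pathway_overlap(model, ann, kb)
    sizes = {pid: len(m) for pid, m in kb.pathway_members().items()}
    for _, row in out.iterrows():
        assert row["n_compounds"] <= sizes[row["pathway_id"]]
        assert row["n_compounds"] <= sum(
            1 for _ in row["compound_ids"].split(";")
        )
        assert row["n_peaks"] >= 1


# ---------------------------------------------------------------------------
# export
# ---------------------------------------------------------------------------

def test_empty_overlap_exports_nothing(tmp_path):
    out = pathway_overlap(
        _model({0: ["p1"]}),
        _annotations([]),
        _kb(compounds={"A": ("cA", 100.0)}, pathways={"P1": ["A"]}),
    )
    assert export_pathway_lists(out, tmp_path) == []


def test_export_compound_list_contents(tmp_path):
    kb = _kb(
        compounds={"A": ("cA", 100.0), "B": ("cB", 200.0), "C": ("cC", 300.0)},
        pathways={"P1": ["A", "C"], "P2": ["B"]},
    )
    model = _model({0: ["p1", "p2", "p3", "p4"]})
    ann = _annotations([("p1", "A"), ("p2", "A"), ("p3", "B")])
    files = export_pathway_lists(pathway_overlap(model, ann, kb), tmp_path)
    by_name = {f.name: f for f in files}
    assert by_name["cluster0_P1.txt"].read_text() == "A\n"


def test_two_clusters_sharing_a_pathway_export_two_files(tmp_path):
    kb = _kb(compounds={"A": ("cA", 100.0)}, pathways={"P1": ["A"]})
    model = _model({0: ["p1"], 1: ["p2"]})
    ann = _annotations([("p1", "A"), ("p2", "A")])
    files = export_pathway_lists(pathway_overlap(model, ann, kb), tmp_path)
    assert len(files) == 2
    assert {f.name for f in files} == {"cluster0_P1.txt", "cluster1_P1.txt"}
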