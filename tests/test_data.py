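"""Dataset reading, curation, structure-based splitting and profiling."""

import numpy as np
import pytest
from rdkit import Chem

from fpgnn.data import (ConfigurationError, EmptyDatasetError, MoleculeRecord, clean_dataset,
                        cluster_split, elbow_curve, profile_dataset, read_dataset,
                        write_dataset)
from fpgnn.featurize import FP_LENGTH


def _rec(smiles, labels=(1.0,), mask=None, rid="r"):
    mask = np.ones(len(labels), bool) if mask is None else np.asarray(mask, bool)
    canonical = Chem.MolToSmiles(Chem.MolFromSmiles(smiles))
    return MoleculeRecord(rid, smiles, canonical, np.asarray(labels, float), mask)


# --- read_dataset -------------------------------------------------------------------


def test_read_dataset_maps_labels_and_masks(tmp_path):
    path = tmp_path / "d.csv"
    path.write_text("smiles,t1\nCCO,1\nCCN,0\nCCC,\n")
    records = read_dataset(path, ["t1"])
    assert [r.mask[0] for r in records] == [True, True, False]
    assert [r.labels[0] for r in records[:2]] == [1.0, 0.0]
    assert records[0].smiles_canonical == "CCO"


def test_read_dataset_drops_malformed_smiles(tmp_path, caplog):
    path = tmp_path / "d.csv"
    path.write_text("smiles,t1\nC1CC,1\nCCO,0\n")  # unclosed ring
    with caplog.at_level("WARNING"):
        records = read_dataset(path, ["t1"])
    assert len(records) == 1
    assert "1 rows" in caplog.text


def test_read_dataset_partial_multitask_mask(tmp_path):
    path = tmp_path / "d.csv"
    path.write_text("smiles,a,b,c,d,e\nCCO,1,,,0,\n")
    (rec,) = read_dataset(path, ["a", "b", "c", "d", "e"])
    assert rec.mask.tolist() == [True, False, False, True, False]


def test_read_dataset_errors(tmp_path):
    path = tmp_path / "d.csv"
    path.write_text("structure,t1\nCCO,1\n")
    with pytest.raises(ConfigurationError):
        read_dataset(path, ["t1"])
    path.write_text("smiles,t1\nnot_a_smiles_xx,1\n")
    with pytest.raises(EmptyDatasetError):
        read_dataset(path, ["t1"])


def test_dataset_roundtrip(tmp_path):
    records = [_rec("CCO", (1.0, 0.0), (True, False), "a"),
               _rec("c1ccccc1", (0.0, 1.0), (True, True), "b")]
    path = tmp_path / "d.csv"
    write_dataset(records, path, ["t1", "t2"])
    back = read_dataset(path, ["t1", "t2"])
    assert [r.smiles_canonical for r in back] == [r.smiles_canonical for r in records]
    assert all((a.mask == b.mask).all() for a, b in zip(back, records))


# --- clean_dataset --------------------------------------------------------------------


def test_clean_keeps_largest_organic_fragment():
    cleaned, counts = clean_dataset([_rec("CC(=O)O.[Na+]")])
    assert len(cleaned) == 1
    assert cleaned[0].smiles_canonical == Chem.MolToSmiles(Chem.MolFromSmiles("CC(=O)O"))


def test_clean_removes_inorganics():
    cleaned, counts = clean_dataset([_rec("O=[Si]=O"), _rec("CCO")])
    assert [r.smiles_canonical for r in cleaned] == ["CCO"]
    assert counts["inorganic"] == 1


def test_clean_deduplicates_by_canonical_form():
    cleaned, counts = clean_dataset([_rec("OCC", (1.0,)), _rec("CCO", (1.0,))])
    assert len(cleaned) == 1
    assert counts["duplicate"] == 1
    assert cleaned[0].mask[0] and cleaned[0].labels[0] == 1.0


def test_clean_conflicting_duplicate_labels_become_missing():
    cleaned, counts = clean_dataset([_rec("OCC", (1.0,)), _rec("CCO", (0.0,))])
    assert len(cleaned) == 1
    assert not cleaned[0].mask[0]
    assert counts["label_conflicts"] == 1


def test_clean_merges_complementary_masks():
    a = _rec("OCC", (1.0, 0.0), (True, False))
    b = _rec("CCO", (0.0, 0.0), (False, True))
    (merged,), _ = clean_dataset([a, b])
    assert merged.mask.tolist() == [True, True]
    assert merged.labels.tolist() == [1.0, 0.0]


def test_clean_is_idempotent():
    records = [_rec("CC(=O)O.[Na+]"), _rec("O=[Si]=O"), _rec("OCC"), _rec("CCO"),
               _rec("c1ccccc1CN")]
    once, _ = clean_dataset(records)
    twice, counts = clean_dataset(once)
    assert [r.smiles_canonical for r in twice] == [r.smiles_canonical for r in once]
    assert counts["inorganic"] == counts["duplicate"] == 0
    canon = [r.smiles_canonical for r in twice]
    assert len(set(canon)) == len(canon)


# --- cluster split -----------------------------------------------------------------------


@pytest.fixture(scope="module")
def two_families():
    benzenes = ["c1ccccc1", "Cc1ccccc1", "CCc1ccccc1", "Oc1ccccc1", "Nc1ccccc1",
                "COc1ccccc1", "CNc1ccccc1", "Cc1ccccc1C", "Cc1ccc(C)cc1", "Oc1ccccc1C",
                "CCc1ccccc1C", "Cc1ccc(O)cc1", "Nc1ccc(C)cc1", "CCOc1ccccc1",
                "Cc1cccc(C)c1", "Oc1ccc(O)cc1", "CCc1ccc(C)cc1", "COc1ccc(C)cc1",
                "Nc1ccc(N)cc1", "Cc1ccccc1N"]
    amines = ["CCN", "CCCN", "CCNC", "CCCCN", "CCN(C)C", "CCCNC", "CCCCCN", "CNCCN",
              "CCNCC", "CCCN(C)C", "NCCCN", "CCCCNC", "CNCCCN", "CCCCCCCCN", "CCCCCCN",
              "NCCN", "CNC", "CCCCN(C)C", "NCCCCN", "CCCCCCCN"]
    records = [_rec(s, rid=f"b{i}") for i, s in enumerate(benzenes)] + \
              [_rec(s, rid=f"a{i}") for i, s in enumerate(amines)]
    canon = [r.smiles_canonical for r in records]
    assert len(set(canon)) == len(canon)
    return records


def test_cluster_split_separates_structural_families(two_families):
    split = cluster_split(two_families, k=2, n_valid=5, n_test=5, seed=3)
    assignments = np.array(split.split_meta["assignments"])
    families = np.array([r.id.startswith("b") for r in two_families])
    purity = max((assignments == families).mean(), (assignments != families).mean())
    assert purity >= 0.9


def test_cluster_split_partitions_are_disjoint_and_seeded(two_families):
    s1 = cluster_split(two_families, k=2, n_valid=6, n_test=6, seed=5)
    s2 = cluster_split(two_families, k=2, n_valid=6, n_test=6, seed=5)
    parts = [{r.smiles_canonical for r in p} for p in (s1.train, s1.validation, s1.test)]
    assert not (parts[0] & parts[1] or parts[0] & parts[2] or parts[1] & parts[2])
    assert len(s1.train) + 12 == len(two_families)
    assert s1.split_meta["assignments"] == s2.split_meta["assignments"]
    assert [r.id for r in s1.test] == [r.id for r in s2.test]


def test_cluster_split_k1_is_seeded_random_split(two_families):
    split = cluster_split(two_families, k=1, n_valid=5, n_test=5, seed=1)
    assert set(split.split_meta["assignments"]) == {0}
    assert len(split.validation) == 5 and len(split.test) == 5


def test_cluster_split_parameter_errors(two_families):
    with pytest.raises(ValueError):
        cluster_split(two_families, k=len(two_families) + 1, n_valid=2, n_test=2, seed=0)
    with pytest.raises(ValueError):
        cluster_split(two_families, k=2, n_valid=30, n_test=30, seed=0)


def test_wss_nonincreasing_in_k(two_families):
    s2 = cluster_split(two_families, k=2, n_valid=4, n_test=4, seed=0)
    s3 = cluster_split(two_families, k=3, n_valid=4, n_test=4, seed=0)
    assert s3.split_meta["wss"] <= s2.split_meta["wss"] + 1e-9


def test_elbow_curve_two_blob_structure(two_families):
    curve = elbow_curve(two_families, k_max=4, seed=0)
    ks, wss = zip(*curve)
    assert ks == (1, 2, 3, 4)
    drop12 = wss[0] - wss[1]
    drop23 = wss[1] - wss[2]
    assert drop12 > 2 * drop23  # the two-family structure dominates
    with pytest.raises(ValueError):
        elbow_curve(two_families, k_max=1, seed=0)


def test_elbow_curve_zero_variance():
    records = [_rec("CCO", rid=str(i)) for i in range(6)]
    fps = np.zeros((6, FP_LENGTH))
    curve = elbow_curve(records, k_max=3, seed=0, fps=np.vstack([fps[0]] * 6))
    assert all(w == pytest.approx(0.0, abs=1e-9) for _, w in curve)


# --- profiling ----------------------------------------------------------------------------


def test_profile_methane_mw_and_empty_scaffold():
    profile = profile_dataset([_rec("C")])
    assert profile.mw_values[0] == pytest.approx(16.043, abs=0.01)
    assert profile.scaffold_fraction == 1.0  # single molecule, one (empty) scaffold


def test_profile_scaffold_fraction_extremes():
    shared = [_rec(s, rid=str(i)) for i, s in enumerate(
        ["c1ccccc1C", "c1ccccc1CC", "c1ccccc1O", "c1ccccc1N"])]
    assert profile_dataset(shared).scaffold_fraction == pytest.approx(1 / 4)
    distinct = [_rec(s, rid=str(i)) for i, s in enumerate(
        ["c1ccccc1", "C1CCCCC1", "c1ccncc1", "c1ccoc1"])]
    assert profile_dataset(distinct).scaffold_fraction == 1.0


def test_profile_counts_and_scaffold_smiles_invariance():
    a = _rec("OCC", (1.0,), rid="a")
    b = _rec("CCO", (0.0,), rid="b")
    c = _rec("CCO", (0.0,), (False,), rid="c")
    profile = profile_dataset([a, b, c])
    assert profile.task_counts[0] == {"positive": 1, "negative": 1, "missing": 1}
    # same molecule written two ways -> one scaffold bucket
    assert profile.scaffold_fraction == pytest.approx(1 / 3)
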