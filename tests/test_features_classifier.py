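import math

import numpy as np
import pytest
from sklearn.tree import DecisionTreeClassifier

from strandbias.counting import CountRecord
from strandbias.features_classifier import (
    FeatureVector,
    StrandBiasModel,
    StrandednessLabel,
    extract_features,
    label_genes,
    predict,
    train_model,
)
from strandbias.gene_models import build_database
from strandbias.junction_sim import JunctionExpectation

from .conftest import make_gtf


@pytest.fixture()
def feature_db(tmp_path):
    """Two-gene layout: a multiexonic gene with a 1 kb unique exon region and
    a 10 kb intron, plus an isolated monoexonic gene far away."""
    gtf = make_gtf(
        tmp_path / "f.gtf",
        [
            {
                "gene_id": "MX",
                "strand": "+",
                "transcripts": {"t": [(0, 1000), (11000, 11010)]},
            },
            {"gene_id": "MONO", "strand": "-", "transcripts": {"t2": [(50000, 51000)]}},
        ],
    )
    return build_database(gtf)


def _exp(gid, p):
    return {gid: JunctionExpectation(gid, p, 1, p)}


def test_exon_intron_log_ratio_arithmetic(feature_db):
    """n_ustno=100 over ~1 kb unique exon, n_intr=10 over 10 kb intron,
    pseudocount 1 -> log2((101/1010)/(11/10000)) ~ 6.51."""
    counts = {
        "MX": CountRecord("MX", n_ust=100, n_ustno=100, n_jctn=0, n_intr=10),
        "MONO": CountRecord("MONO"),
    }
    exps = _exp("MX", 0.1)
    feats = extract_features(counts, exps, feature_db)
    g = feature_db.genes["MX"]
    expected = math.log2(((100 + 1) / g.nonoverlap_len) / ((10 + 1) / g.intron_len))
    assert feats["MX"].exon_intron_log_ratio == pytest.approx(expected)
    assert g.intron_len == 10000
    assert expected == pytest.approx(6.52, abs=0.02)


def test_junction_log_ratio_zero_when_observed_equals_expected(feature_db):
    counts = {
        "MX": CountRecord("MX", n_ust=200, n_ustno=150, n_jctn=20, n_intr=0),
        "MONO": CountRecord("MONO"),
    }
    feats = extract_features(counts, _exp("MX", 0.1), feature_db)
    assert feats["MX"].junction_log_ratio == pytest.approx(0.0)


def test_isolated_monoexonic_gene_features(feature_db):
    counts = {
        "MX": CountRecord("MX", n_ust=10),
        "MONO": CountRecord("MONO", n_ust=5, n_ustno=5),
    }
    feats = extract_features(counts, _exp("MX", 0.1), feature_db)
    mono = feats["MONO"]
    assert mono.monoexonic
    assert mono.junction_log_ratio is None
    assert mono.exon_intron_log_ratio is None
    assert mono.neighbor_expression == 0.0
    assert mono.overlap_fraction == 0.0


def test_neighbor_expression_is_max_normalized_count(tmp_path):
    gtf = make_gtf(
        tmp_path / "n.gtf",
        [
            {"gene_id": "G", "strand": "+", "transcripts": {"t": [(0, 1000)]}},
            {"gene_id": "N1", "strand": "-", "transcripts": {"t1": [(1500, 2500)]}},
            {"gene_id": "N2", "strand": "-", "transcripts": {"t2": [(3000, 3500)]}},
        ],
    )
    db = build_database(gtf)
    counts = {
        "G": CountRecord("G", n_ust=10),
        "N1": CountRecord("N1", n_ust=100),  # 100 per kb
        "N2": CountRecord("N2", n_ust=300),  # 600 per kb
    }
    feats = extract_features(counts, {}, db)
    assert feats["G"].neighbor_expression == pytest.approx(600.0)


def test_missing_expectation_for_multiexonic_is_error(feature_db):
    counts = {"MX": CountRecord("MX", n_ust=10), "MONO": CountRecord("MONO")}
    with pytest.raises(KeyError, match="MX"):
        extract_features(counts, {}, feature_db)


def test_labels_thresholds_and_errors(feature_db):
    # equal counts -> ratio 0; 4x -> affected when detectable
    counts = {
        "MX": CountRecord("MX", n_ust=400, n_ustno=400, n_stno=100),
        "MONO": CountRecord("MONO", n_ust=50, n_ustno=50, n_stno=50),
    }
    labels = label_genes(counts, feature_db, strandedness="R")
    assert labels["MX"].log2_ratio == pytest.approx(math.log2(401 / 101))
    assert labels["MX"].affected
    assert labels["MONO"].log2_ratio == pytest.approx(0.0)
    assert not labels["MONO"].affected
    with pytest.raises(ValueError, match="stranded"):
        label_genes(counts, feature_db, strandedness="U")


def test_label_ratio_below_threshold_not_affected(feature_db):
    counts = {
        "MX": CountRecord("MX", n_ust=100, n_ustno=100, n_stno=60),
        "MONO": CountRecord("MONO", n_ust=1000, n_ustno=1000, n_stno=1000),
    }
    labels = label_genes(counts, feature_db, strandedness="R")
    assert labels["MX"].log2_ratio == pytest.approx(math.log2(101 / 61))
    assert labels["MX"].log2_ratio == pytest.approx(0.73, abs=0.01)
    assert not labels["MX"].affected


def test_label_monotone_in_ustno(feature_db):
    prev = -1.0
    for ustno in (10, 20, 40, 80, 160):
        counts = {
            "MX": CountRecord("MX", n_ust=ustno, n_ustno=ustno, n_stno=10),
            "MONO": CountRecord("MONO"),
        }
        r = label_genes(counts, feature_db, strandedness="R")["MX"].log2_ratio
        assert r > prev
        prev = r


def _fv(gid, jlr, eilr, neigh, ovl, mono=False, n_ust=100):
    return FeatureVector(gid, jlr, eilr, neigh, ovl, mono, n_ust)


def _lab(gid, affected):
    return StrandednessLabel(gid, 2.0 if affected else 0.0, affected, True)


def _separable_training_set(n=40, seed=0):
    """Affected genes separated by a single junction_log_ratio threshold;
    balanced classes so leaf fractions equal raw instance fractions."""
    rng = np.random.default_rng(seed)
    features, labels = {}, {}
    for i in range(n):
        affected = i % 2 == 0
        jlr = rng.uniform(-6, -3) if affected else rng.uniform(-1, 2)
        gid = f"g{i:03d}"
        features[gid] = _fv(gid, jlr, rng.uniform(0, 5), rng.uniform(0, 50), 0.0)
        labels[gid] = _lab(gid, affected)
    for i in range(n, n + 10):
        affected = i % 2 == 0
        gid = f"m{i:03d}"
        features[gid] = _fv(
            gid, None, None, 100.0 if affected else 1.0, 0.0, mono=True
        )
        labels[gid] = _lab(gid, affected)
    return features, labels


def test_separable_data_perfect_training_accuracy():
    features, labels = _separable_training_set()
    model = train_model([(features, labels)], seed=0)
    preds = predict(features, model)
    for gid, fv in features.items():
        want_affected = labels[gid].affected
        assert (preds[gid].p_affected > 0.5) == want_affected, gid
        assert preds[gid].confidence == pytest.approx(1 - preds[gid].p_affected)


def test_training_is_deterministic_and_serializable(tmp_path):
    features, labels = _separable_training_set()
    m1 = train_model([(features, labels)], seed=7)
    m2 = train_model([(features, labels)], seed=7)
    p1, p2 = tmp_path / "m1.json", tmp_path / "m2.json"
    m1.save(p1)
    m2.save(p2)
    assert p1.read_bytes() == p2.read_bytes()
    loaded = StrandBiasModel.load(p1)
    preds_a = predict(features, m1)
    preds_b = predict(features, loaded)
    assert all(
        preds_a[g].confidence == preds_b[g].confidence for g in features
    )


def test_leaf_fraction_probability():
    """A leaf holding 3 affected / 1 unaffected instances scores 0.75."""
    X = np.array([[0.0], [0.1], [0.2], [0.3], [5.0], [5.1], [5.2], [5.3]])
    y = np.array([0, 0, 0, 0, 1, 1, 1, 0])  # right leaf: 3 affected, 1 not
    clf = DecisionTreeClassifier(max_depth=1, random_state=0).fit(X, y)
    from strandbias.features_classifier import _export_tree, _tree_p_affected

    tree = _export_tree(clf)
    assert _tree_p_affected(tree, [5.0]) == pytest.approx(0.75)
    assert _tree_p_affected(tree, [0.0]) == pytest.approx(0.0)
    # and matches sklearn's own leaf probabilities
    assert _tree_p_affected(tree, [5.0]) == pytest.approx(
        clf.predict_proba([[5.0]])[0][1]
    )


def test_predict_routes_by_exon_structure_and_flags_unobserved():
    features, labels = _separable_training_set()
    model = train_model([(features, labels)], seed=0)
    feats = {
        "multi": _fv("multi", -5.0, 1.0, 0.0, 0.0),
        "mono": _fv("mono", None, None, 100.0, 0.0, mono=True),
        "silent": _fv("silent", None, None, 0.0, 0.0, mono=True, n_ust=0),
    }
    preds = predict(feats, model)
    assert preds["multi"].model_used == "multiexonic"
    assert preds["mono"].model_used == "monoexonic"
    assert preds["silent"].model_used == "not_applicable"
    assert preds["silent"].confidence is None


def test_predict_errors_on_undefined_required_feature():
    features, labels = _separable_training_set()
    model = train_model([(features, labels)], seed=0)
    broken = {"bad": _fv("bad", None, None, 0.0, 0.0, mono=False)}
    with pytest.raises(ValueError, match="bad"):
        predict(broken, model)


def test_single_class_training_is_error():
    features, labels = _separable_training_set()
    all_neg = {g: _lab(g, False) for g in labels}
    with pytest.raises(ValueError, match="single class"):
        train_model([(features, all_neg)], seed=0)


def test_only_detectable_genes_enter_training():
    features, labels = _separable_training_set()
    # flip every unaffected multiexonic gene to undetectable: training must fail
    stripped = {
        g: StrandednessLabel(g, lab.log2_ratio, lab.affected, lab.affected)
        for g, lab in labels.items()
    }
    with pytest.raises(ValueError, match="single class"):
        train_model([(features, stripped)], seed=0)
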