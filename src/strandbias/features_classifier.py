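"""Predictive metrics, strandedness labels, and the decision-tree scorer.

Four alignment-derived metrics separate genes whose unstranded counts are
inflated by opposite-strand transcription from regular genes:

* ``junction_log_ratio``   — log2 of observed vs expected junction reads;
  carry-over reads ignore splice sites, pushing this down.
* ``exon_intron_log_ratio``— log2 of length-normalized exonic vs intronic
  read density; carry-over reads cover introns, pushing this down.
* ``neighbor_expression``  — maximum length-normalized unstranded count
  among genes within 2 kb; carry-over needs a highly expressed source.
* ``overlap_fraction``     — fraction of the exonic span shared with other
  genes' exons.

The first two are undefined for monoexonic genes, so two depth-limited
decision trees are trained: depth 5 on all four metrics for multiexonic
genes and depth 3 on the last two for monoexonic genes. The emitted
confidence is 1 minus the predicted probability of being affected
(1 = expression trusted, 0 = likely inflated).

Training labels come from stranded data: a gene is strandedness-affected
when log2(N_ustno/N_stno) > 1 (more than two-fold overestimation) and its
unstranded expression is detectable (TPM > 1).
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
from sklearn.tree import DecisionTreeClassifier

from .counting import CountRecord, compute_tpm
from .gene_models import GenomeDatabase
from .junction_sim import JunctionExpectation

MODEL_FORMAT_VERSION = 1
DEFAULT_PSEUDOCOUNT = 1.0
MULTIEXONIC_FEATURES = (
    "junction_log_ratio",
    "exon_intron_log_ratio",
    "neighbor_expression",
    "overlap_fraction",
)
MONOEXONIC_FEATURES = ("neighbor_expression", "overlap_fraction")


@dataclass(frozen=True)
class FeatureVector:
    gene_id: str
    junction_log_ratio: float | None
    exon_intron_log_ratio: float | None
    neighbor_expression: float
    overlap_fraction: float
    monoexonic: bool
    n_ust: int


@dataclass(frozen=True)
class StrandednessLabel:
    gene_id: str
    log2_ratio: float
    affected: bool
    detectable: bool


@dataclass(frozen=True)
class GenePrediction:
    gene_id: str
    confidence: float | None
    p_affected: float | None
    model_used: str  # multiexonic | monoexonic | not_applicable


def extract_features(
    counts: Mapping[str, CountRecord],
    expectations: Mapping[str, JunctionExpectation],
    db: GenomeDatabase,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> dict[str, FeatureVector]:
    """Compute the four metrics from an unstranded counting pass.

    Only the strand-blind count types (n_ust, n_ustno, n_jctn, n_intr) are
    read, so the same function serves stranded libraries counted as if
    unstranded.
    """
    eps = pseudocount
    out: dict[str, FeatureVector] = {}
    for gid, rec in counts.items():
        g = db.genes[gid]
        if g.monoexonic:
            jlr = eilr = None
        else:
            if gid not in expectations:
                raise KeyError(
                    f"multiexonic gene {gid} missing from junction expectations "
                    "(database/count mismatch?)"
                )
            p_exp = expectations[gid].p_expected
            jlr = math.log2((rec.n_jctn + eps) / (p_exp * rec.n_ust + eps))
            # isoform unions can leave no intronic bases; clamp the length
            # so the density stays finite
            intron_len = max(g.intron_len, 1)
            nonoverlap_len = max(g.nonoverlap_len, 1)
            eilr = math.log2(
                ((rec.n_ustno + eps) / nonoverlap_len)
                / ((rec.n_intr + eps) / intron_len)
            )
        neigh = 0.0
        for hid in db.neighbors.get(gid, ()):
            h = db.genes[hid]
            if h.exonic_len > 0:
                neigh = max(neigh, counts[hid].n_ust / (h.exonic_len / 1000.0))
        out[gid] = FeatureVector(
            gene_id=gid,
            junction_log_ratio=jlr,
            exon_intron_log_ratio=eilr,
            neighbor_expression=neigh,
            overlap_fraction=g.overlap_fraction,
            monoexonic=g.monoexonic,
            n_ust=rec.n_ust,
        )
    return out


def label_genes(
    stranded_counts: Mapping[str, CountRecord],
    db: GenomeDatabase,
    tpm_threshold: float = 1.0,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
    strandedness: str = "R",
) -> dict[str, StrandednessLabel]:
    """Strandedness-affected labels from a stranded counting pass."""
    if strandedness == "U":
        raise ValueError("labels require stranded data (library U given)")
    eps = pseudocount
    tpm = compute_tpm(dict(stranded_counts), db, which="n_ustno")
    out: dict[str, StrandednessLabel] = {}
    for gid, rec in stranded_counts.items():
        ratio = math.log2((rec.n_ustno + eps) / (rec.n_stno + eps))
        detectable = tpm[gid] > tpm_threshold
        out[gid] = StrandednessLabel(
            gene_id=gid,
            log2_ratio=ratio,
            affected=bool(ratio > 1.0 and detectable),
            detectable=detectable,
        )
    return out


def _export_tree(clf: DecisionTreeClassifier) -> dict:
    t = clf.tree_
    return {
        "children_left": t.children_left.tolist(),
        "children_right": t.children_right.tolist(),
        "feature": t.feature.tolist(),
        "threshold": [float(x) for x in t.threshold],
        "value": [[float(v) for v in row[0]] for row in t.value],
        "classes": [int(c) for c in clf.classes_],
    }


def _tree_p_affected(tree: dict, x: Sequence[float]) -> float:
    i = 0
    left = tree["children_left"]
    right = tree["children_right"]
    feat = tree["feature"]
    thr = tree["threshold"]
    while left[i] != -1:
        i = left[i] if x[feat[i]] <= thr[i] else right[i]
    value = tree["value"][i]
    total = sum(value)
    idx = tree["classes"].index(1)
    return value[idx] / total if total > 0 else 0.0


@dataclass
class StrandBiasModel:
    """Two serialized decision trees plus training metadata.

    Persisted as versioned JSON holding the trees' array form; prediction
    walks the arrays (left branch on feature <= threshold), so a saved
    model is self-contained.
    """

    tree_multiexonic: dict
    tree_monoexonic: dict
    metadata: dict

    def save(self, path: str | Path) -> None:
        payload = {
            "format_version": MODEL_FORMAT_VERSION,
            "tree_multiexonic": self.tree_multiexonic,
            "tree_monoexonic": self.tree_monoexonic,
            "metadata": self.metadata,
        }
        with open(path, "w") as fh:
            json.dump(payload, fh, sort_keys=True, indent=1)
            fh.write("\n")

    @classmethod
    def load(cls, path: str | Path) -> "StrandBiasModel":
        with open(path) as fh:
            payload = json.load(fh)
        if payload.get("format_version") != MODEL_FORMAT_VERSION:
            raise ValueError(f"unsupported model format {payload.get('format_version')}")
        return cls(
            tree_multiexonic=payload["tree_multiexonic"],
            tree_monoexonic=payload["tree_monoexonic"],
            metadata=payload["metadata"],
        )

    def p_affected(self, fv: FeatureVector) -> float:
        if fv.monoexonic:
            x = [fv.neighbor_expression, fv.overlap_fraction]
            return _tree_p_affected(self.tree_monoexonic, x)
        if fv.junction_log_ratio is None or fv.exon_intron_log_ratio is None:
            raise ValueError(
                f"multiexonic gene {fv.gene_id} has undefined junction/intron features"
            )
        x = [
            fv.junction_log_ratio,
            fv.exon_intron_log_ratio,
            fv.neighbor_expression,
            fv.overlap_fraction,
        ]
        return _tree_p_affected(self.tree_multiexonic, x)


def train_model(
    feature_sets: Sequence[
        tuple[Mapping[str, FeatureVector], Mapping[str, StrandednessLabel]]
    ],
    seed: int = 0,
    max_depth_multiexonic: int = 5,
    max_depth_monoexonic: int = 3,
    pseudocount: float = DEFAULT_PSEUDOCOUNT,
) -> StrandBiasModel:
    """Fit the two trees on pooled (gene x sample) instances.

    Only genes with detectable expression enter training. Instances are
    class-weight balanced (affected genes are a small minority) and the fit
    is deterministic given the seed and input order.
    """
    X_multi: list[list[float]] = []
    y_multi: list[int] = []
    X_mono: list[list[float]] = []
    y_mono: list[int] = []
    for features, labels in feature_sets:
        for gid in sorted(features):
            fv = features[gid]
            lab = labels.get(gid)
            if lab is None or not lab.detectable:
                continue
            if fv.monoexonic:
                X_mono.append([fv.neighbor_expression, fv.overlap_fraction])
                y_mono.append(int(lab.affected))
            else:
                X_multi.append(
                    [
                        fv.junction_log_ratio,
                        fv.exon_intron_log_ratio,
                        fv.neighbor_expression,
                        fv.overlap_fraction,
                    ]
                )
                y_multi.append(int(lab.affected))
    trees = {}
    for name, X, y, depth, feats in (
        ("multiexonic", X_multi, y_multi, max_depth_multiexonic, MULTIEXONIC_FEATURES),
        ("monoexonic", X_mono, y_mono, max_depth_monoexonic, MONOEXONIC_FEATURES),
    ):
        if not X:
            raise ValueError(f"no detectable {name} training instances")
        if len(set(y)) < 2:
            raise ValueError(
                f"{name} training data contains a single class; both affected "
                "and unaffected genes are required"
            )
        clf = DecisionTreeClassifier(
            max_depth=depth, random_state=seed, class_weight="balanced"
        )
        clf.fit(np.asarray(X, dtype=float), np.asarray(y, dtype=int))
        trees[name] = _export_tree(clf)
    metadata = {
        "seed": int(seed),
        "pseudocount": pseudocount,
        "feature_order_multiexonic": list(MULTIEXONIC_FEATURES),
        "feature_order_monoexonic": list(MONOEXONIC_FEATURES),
        "max_depth_multiexonic": max_depth_multiexonic,
        "max_depth_monoexonic": max_depth_monoexonic,
        "n_instances_multiexonic": len(X_multi),
        "n_instances_monoexonic": len(X_mono),
        "n_samples": len(feature_sets),
        "class_weight": "balanced",
    }
    return StrandBiasModel(
        tree_multiexonic=trees["multiexonic"],
        tree_monoexonic=trees["monoexonic"],
        metadata=metadata,
    )


def predict(
    features: Mapping[str, FeatureVector], model: StrandBiasModel
) -> dict[str, GenePrediction]:
    """Confidence scores for every gene with observed expression.

    Genes with no unstranded reads cannot be scored and are emitted with
    confidence None (reported NA downstream).
    """
    out: dict[str, GenePrediction] = {}
    for gid in sorted(features):
        fv = features[gid]
        if fv.n_ust == 0:
            out[gid] = GenePrediction(gid, None, None, "not_applicable")
            continue
        p = model.p_affected(fv)
        out[gid] = GenePrediction(
            gid,
            confidence=1.0 - p,
            p_affected=p,
            model_used="monoexonic" if fv.monoexonic else "multiexonic",
        )
    return out
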