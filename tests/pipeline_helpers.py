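"""Shared pipeline drivers for the acceptance checks.

These run the package end-to-end on synthetic data: count each pseudo-cell
type's stranded BAM, derive strand-blind features and stranded labels from
the same pass, train on all types but the last, and score the held-out one.
"""

from __future__ import annotations

from sklearn.metrics import roc_auc_score

from strandbias.counting import LibraryConfig, count_bam
from strandbias.features_classifier import (
    extract_features,
    label_genes,
    predict,
    train_model,
)
from strandbias.junction_sim import ReadConfiguration, simulate_all

# fixture reads are spliced at every boundary crossing, so the matching
# expectation is the overhang-1 probability
FIXTURE_OVERHANG = 1


def equalized_abundance(db, read_length):
    """Molar abundances that give every gene the same expected read count
    (abundance inversely proportional to total placements)."""
    out = {}
    for gid, g in db.genes.items():
        placements = 0
        for _tid, exons in g.isoforms:
            t_len = sum(e - s for s, e in exons)
            placements += max(t_len - read_length + 1, 1)
        out[gid] = 1.0 / placements
    return out


def feature_label_sets(db, sims, read_length):
    cfg = ReadConfiguration(read_length=read_length, min_overhang=FIXTURE_OVERHANG)
    expectations = simulate_all(db.genes, cfg)
    out = []
    for sim in sims:
        counts, _ = count_bam(sim.stranded_bam, db, LibraryConfig(strandedness="R"))
        features = extract_features(counts, expectations, db)
        labels = label_genes(counts, db, strandedness="R")
        out.append((features, labels, counts))
    return out


def holdout_evaluation(db, sims, read_length, seed):
    """Train on all but the last pseudo-cell type; AUC on the held-out one."""
    sets = feature_label_sets(db, sims, read_length)
    train_sets = [(f, l) for f, l, _ in sets[:-1]]
    model = train_model(train_sets, seed=seed)
    features, labels, _counts = sets[-1]
    preds = predict(features, model)
    scores = {"multiexonic": ([], []), "monoexonic": ([], [])}
    for gid, fv in features.items():
        lab = labels[gid]
        if not lab.detectable or preds[gid].p_affected is None:
            continue
        key = "monoexonic" if fv.monoexonic else "multiexonic"
        scores[key][0].append(int(lab.affected))
        scores[key][1].append(preds[gid].p_affected)
    aucs = {}
    for key, (y, p) in scores.items():
        aucs[key] = roc_auc_score(y, p) if len(set(y)) == 2 else float("nan")
    return model, aucs, sets
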