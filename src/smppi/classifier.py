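"""Class-balanced random-forest ensemble for overlap/non-overlap residues.

Interface datasets are heavily imbalanced (roughly one overlap residue per
four non-overlap residues), which skews a single forest toward the
majority class.  Training therefore repeats a down-sampling draw K times:
each ensemble member is a random forest fitted on all minority-class
residues plus an equally sized subset drawn (without replacement) from the
majority class.  The final call is a majority vote over the K members; a
residue is predicted 'O' when more than half the members vote 'O' (an
exact tie goes to 'N', the conservative class).

Forest defaults follow the classic randomForest settings the method was
built on: 500 unpruned trees per member, Gini impurity, floor(sqrt(13))=3
features considered per split.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .features import FEATURE_COLUMNS
from .patches import SurfacePatch

logger = logging.getLogger(__name__)

__all__ = [
    "BalancedForestEnsemble", "PredictionResult", "BindingPatchPrediction",
    "train", "predict", "evaluate", "feature_importance",
    "predict_binding_patches", "save_model", "load_model",
]

MODEL_FORMAT_VERSION = 1


@dataclass
class BalancedForestEnsemble:
    members: list[RandomForestClassifier]
    K: int
    feature_names: list[str]
    seed: int
    class_order: tuple[str, str] = ("O", "N")


@dataclass
class PredictionResult:
    labels: dict  # key -> 'O'/'N'
    vote_fractions: dict  # key -> fraction of members voting 'O'
    confusion: Optional[dict] = None  # TP/FP/FN/TN when truth supplied


@dataclass
class BindingPatchPrediction:
    patches: list[SurfacePatch]
    ratios: list[float]
    min_votes: int


def _check_features(df: pd.DataFrame, names: Sequence[str]) -> np.ndarray:
    missing = [c for c in names if c not in df.columns]
    if missing:
        raise ValueError(f"missing feature column(s): {missing}")
    return df[list(names)].to_numpy(dtype=float)


def train(
    features: pd.DataFrame,
    labels: Sequence[str],
    K: int = 1000,
    n_trees: int = 500,
    max_features: int | str = 3,
    seed: int = 0,
    feature_names: Optional[Sequence[str]] = None,
) -> BalancedForestEnsemble:
    """Fit K balanced forests on a labelled feature table.

    Each member is trained on every minority-class sample plus an equal
    number of majority-class samples drawn without replacement (a fresh
    draw per member).  Deterministic given ``seed``.
    """
    if K < 1:
        raise ValueError(f"K must be >= 1, got {K}")
    names = list(feature_names) if feature_names is not None else FEATURE_COLUMNS
    x = _check_features(features, names)
    y = np.asarray(labels)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ValueError(f"training data contains a single class: {classes}")
    minority = classes[np.argmin(counts)]
    majority = classes[np.argmax(counts)]
    n_min = counts.min()
    idx_min = np.flatnonzero(y == minority)
    idx_maj = np.flatnonzero(y == majority)

    rng = np.random.default_rng(seed)
    members = []
    for _ in range(K):
        draw = rng.choice(idx_maj, size=n_min, replace=False)
        idx = np.concatenate([idx_min, draw])
        forest = RandomForestClassifier(
            n_estimators=n_trees,
            max_features=max_features,
            criterion="gini",
            random_state=int(rng.integers(2**31 - 1)),
            n_jobs=1,
        )
        forest.fit(x[idx], y[idx])
        members.append(forest)
    return BalancedForestEnsemble(members, K, names, seed)


def predict(
    model: BalancedForestEnsemble,
    features: pd.DataFrame,
    truth: Optional[Mapping] = None,
) -> PredictionResult:
    """Majority-vote prediction over the ensemble members.

    Vote fraction = members voting 'O' / K; the label is 'O' iff the
    fraction exceeds 0.5.  When ``truth`` maps the feature index to known
    labels, the 2×2 confusion counts are filled in.
    """
    x = _check_features(features, model.feature_names)
    votes_o = np.zeros(len(x))
    for forest in model.members:
        votes_o += (forest.predict(x) == "O")
    frac = votes_o / model.K
    keys = list(features.index)
    labels = {k: ("O" if f > 0.5 else "N") for k, f in zip(keys, frac)}
    fractions = {k: float(f) for k, f in zip(keys, frac)}
    confusion = None
    if truth is not None:
        confusion = _confusion(labels, truth)
    return PredictionResult(labels, fractions, confusion)


def _confusion(pred: Mapping, truth: Mapping) -> dict:
    tp = fp = fn = tn = 0
    for k, p in pred.items():
        t = truth[k]
        if p == "O" and t == "O":
            tp += 1
        elif p == "O" and t == "N":
            fp += 1
        elif p == "N" and t == "O":
            fn += 1
        else:
            tn += 1
    return {"TP": tp, "FP": fp, "FN": fn, "TN": tn}


def evaluate(prediction: PredictionResult, truth: Mapping) -> dict:
    """Confusion counts, accuracy and per-class error rates vs known labels."""
    c = _confusion(prediction.labels, truth)
    n = sum(c.values())
    n_o = c["TP"] + c["FN"]
    n_n = c["TN"] + c["FP"]
    return {
        **c,
        "accuracy": (c["TP"] + c["TN"]) / n if n else float("nan"),
        "error_O": c["FN"] / n_o if n_o else float("nan"),
        "error_N": c["FP"] / n_n if n_n else float("nan"),
    }


def feature_importance(
    model: BalancedForestEnsemble,
    features: pd.DataFrame,
    labels: Sequence[str],
    n_shuffles: int = 10,
    seed: int = 0,
) -> dict[str, float]:
    """Permutation importance: mean decrease in accuracy per feature.

    For each feature the column is shuffled ``n_shuffles`` times on a
    labelled evaluation set and the drop of ensemble accuracy relative to
    the unshuffled baseline is averaged.
    """
    y = np.asarray(labels)
    base = np.mean(
        [prediction == t for prediction, t in
         zip(predict(model, features).labels.values(), y)]
    )
    rng = np.random.default_rng(seed)
    out: dict[str, float] = {}
    for name in model.feature_names:
        accs = []
        for _ in range(n_shuffles):
            shuffled = features.copy()
            shuffled[name] = rng.permutation(shuffled[name].to_numpy())
            pred = predict(model, shuffled)
            accs.append(np.mean([p == t for p, t in zip(pred.labels.values(), y)]))
        out[name] = float(base - np.mean(accs))
    return out


def predict_binding_patches(
    prediction: PredictionResult,
    patches: Sequence[SurfacePatch],
    min_votes: int = 5,
) -> BindingPatchPrediction:
    """Filter size-7 patches down to high-confidence binding patches.

    A patch is reported when its central residue is predicted 'O' and at
    least ``min_votes`` of its members (central included) are predicted
    'O'.  Reported patches are sorted by their predicted-O ratio,
    descending (ties by central residue id).
    """
    kept: list[tuple[float, SurfacePatch]] = []
    for patch in patches:
        if len(patch.members) != 7:
            logger.warning(
                "patch at %s has size %d (expected 7); evaluated anyway",
                patch.central, len(patch.members),
            )
        missing = [m for m in patch.members if m not in prediction.labels]
        if missing:
            raise ValueError(f"patch member(s) without prediction: {missing}")
        if prediction.labels[patch.central] != "O":
            continue
        n_o = sum(1 for m in patch.members if prediction.labels[m] == "O")
        if n_o < min_votes:
            continue
        kept.append((n_o / len(patch.members), patch))
    kept.sort(key=lambda t: (-t[0], t[1].central))
    return BindingPatchPrediction(
        [p for _, p in kept], [r for r, _ in kept], min_votes
    )


# ---------------------------------------------------------------------------
# Serialisation
# ---------------------------------------------------------------------------

def save_model(model: BalancedForestEnsemble, path: str) -> None:
    joblib.dump(
        {
            "format_version": MODEL_FORMAT_VERSION,
            "feature_names": model.feature_names,
            "K": model.K,
            "seed": model.seed,
            "class_order": model.class_order,
            "members": model.members,
        },
        path,
    )


def load_model(path: str) -> BalancedForestEnsemble:
    blob = joblib.load(path)
    if blob.get("format_version") != MODEL_FORMAT_VERSION:
        raise ValueError(f"unsupported model format: {blob.get('format_version')}")
    return BalancedForestEnsemble(
        blob["members"], blob["K"], blob["feature_names"], blob["seed"],
        tuple(blob["class_order"]),
    )


def predictions_to_tsv(prediction: PredictionResult, structure=None) -> str:
    lines = ["chain\tresnum\ticode\tvote_fraction\tlabel"]
    for rid in sorted(prediction.labels):
        lines.append(
            f"{rid.chain_id}\t{rid.seq_number}\t{rid.icode}\t"
            f"{prediction.vote_fractions[rid]:.4f}\t{prediction.labels[rid]}"
        )
    return "\n".join(lines) + "\n"
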