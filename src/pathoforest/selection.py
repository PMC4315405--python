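"""Two-step greedy feature selection with family-aware cross-validation.

Step one runs backward elimination independently on each of 10
family-aware cross-validation folds: starting from all candidates, the
feature with the least mean decrease in gini index is dropped, the forest
retrained, and so on down to one feature; the subset with the highest
held-out accuracy wins (ties favour the smaller set). The union of the
10 fold subsets forms the non-redundant set.

Step two is forward selection over the non-redundant set, seeded with its
top gini-ranked feature; each round adds the feature giving the largest
relative accuracy gain under 10-fold family-aware CV, stopping when no
addition strictly improves accuracy.

Family-aware means all variants of one protein family stay in a single
fold, preventing homology leakage between train and test.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier


@dataclass(frozen=True)
class SelectionConfig:
    """Forest and CV settings used inside the selection loops.

    Selection forests default to 100 trees for tractability; the final
    production model is always trained with the full ensemble settings.
    """

    n_trees: int = 100
    mtry: int = 2
    k: int = 10
    seed: int = 0
    gain: str = "relative"  # or "absolute"


@dataclass
class SelectionTrace:
    """Audit record of the two-step selection."""

    step1_subsets: list[list[str]] = field(default_factory=list)
    step1_records: list[list[dict]] = field(default_factory=list)
    non_redundant_set: list[str] = field(default_factory=list)
    step2_records: list[dict] = field(default_factory=list)
    selected_feature_set: list[str] = field(default_factory=list)

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "step1_subsets": self.step1_subsets,
                    "step1_records": self.step1_records,
                    "non_redundant_set": self.non_redundant_set,
                    "step2_records": self.step2_records,
                    "selected_feature_set": self.selected_feature_set,
                },
                fh,
                indent=2,
            )


def family_kfold(
    family_ids: pd.Series, k: int = 10, seed: int = 0
) -> list[np.ndarray]:
    """Partition variants into k folds without splitting any family.

    Families are shuffled (seeded) then greedily assigned, largest first,
    to the currently smallest fold, giving fold sizes as balanced as the
    family-size multiset allows. Returns positional index arrays.
    """
    families = family_ids.groupby(family_ids).groups  # family -> index labels
    if len(families) < k:
        raise ValueError(f"only {len(families)} families for k={k} folds")
    rng = np.random.default_rng(seed)
    names = list(families)
    rng.shuffle(names)
    # stable sort by size keeps the seeded shuffle as tie-break
    names.sort(key=lambda f: -len(families[f]))

    pos = {lab: i for i, lab in enumerate(family_ids.index)}
    folds: list[list[int]] = [[] for _ in range(k)]
    for name in names:
        target = min(range(k), key=lambda i: len(folds[i]))
        folds[target].extend(pos[lab] for lab in families[name])
    return [np.array(sorted(f), dtype=int) for f in folds]


def _fit_forest(X: np.ndarray, y: np.ndarray, cfg: SelectionConfig, seed: int):
    forest = RandomForestClassifier(
        n_estimators=cfg.n_trees,
        max_features=min(cfg.mtry, X.shape[1]),
        random_state=seed % (2**31),
        n_jobs=1,
    )
    forest.fit(X, y)
    return forest


def _gini_ranking(forest, features: list[str]) -> list[str]:
    """Features ordered by decreasing mean decrease in gini index.

    Ties are broken by feature name so reruns are reproducible.
    """
    imp = forest.feature_importances_
    return [f for _, f in sorted(zip(-imp, features), key=lambda t: (t[0], t[1]))]


def backward_elimination(
    X_train: pd.DataFrame,
    y_train: np.ndarray,
    X_test: pd.DataFrame,
    y_test: np.ndarray,
    candidates: list[str],
    cfg: SelectionConfig,
) -> tuple[list[str], list[dict]]:
    """Drop the least-important feature until one remains; keep the best set.

    At each iteration a forest is retrained on the current feature set,
    held-out accuracy recorded, features ranked by mean decrease in gini,
    and the lowest-ranked feature removed. The returned subset is the one
    with the highest held-out accuracy; accuracy ties go to the smaller
    set.
    """
    if len(candidates) < 1:
        raise ValueError("no candidate features")
    current = list(candidates)
    records: list[dict] = []
    step = 0
    while True:
        forest = _fit_forest(
            X_train[current].to_numpy(), y_train, cfg, cfg.seed + 1000 * step
        )
        acc = float((forest.predict(X_test[current].to_numpy()) == y_test).mean())
        ranking = _gini_ranking(forest, current)
        records.append({"features": list(current), "accuracy": acc, "ranking": ranking})
        if len(current) == 1:
            break
        current = [f for f in current if f != ranking[-1]]
        step += 1
    # highest accuracy; ties favour the later (smaller) set
    best = max(records, key=lambda r: (r["accuracy"], -len(r["features"])))
    return list(best["features"]), records


def _cv_accuracy(
    feats: list[str],
    X: pd.DataFrame,
    y: np.ndarray,
    folds: list[np.ndarray],
    cfg: SelectionConfig,
    seed_offset: int,
) -> float:
    """Family-aware CV accuracy over all predictions (binary, cutoff 0.5)."""
    correct = 0
    total = 0
    for i, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(len(X)), test_idx)
        forest = _fit_forest(
            X.iloc[train_idx][feats].to_numpy(),
            y[train_idx],
            cfg,
            cfg.seed + seed_offset + i,
        )
        pred = forest.predict(X.iloc[test_idx][feats].to_numpy())
        correct += int((pred == y[test_idx]).sum())
        total += len(test_idx)
    return correct / total


def forward_selection(
    non_redundant: list[str],
    X: pd.DataFrame,
    y: np.ndarray,
    family_ids: pd.Series,
    cfg: SelectionConfig,
) -> tuple[list[str], list[dict]]:
    """Greedy forward selection seeded with the top gini-ranked feature.

    Each round evaluates adding every remaining candidate by k-fold
    family-aware CV accuracy and accepts the best strictly-improving
    addition (largest relative gain by default); stops when no addition
    improves accuracy.
    """
    if not non_redundant:
        raise ValueError("non-redundant set is empty")
    folds = family_kfold(family_ids, k=cfg.k, seed=cfg.seed)
    full_forest = _fit_forest(X[non_redundant].to_numpy(), y, cfg, cfg.seed)
    ranking = _gini_ranking(full_forest, list(non_redundant))
    selected = [ranking[0]]
    remaining = [f for f in non_redundant if f != ranking[0]]
    acc = _cv_accuracy(selected, X, y, folds, cfg, seed_offset=50_000)
    records = [{"selected": list(selected), "accuracy": acc, "added": ranking[0]}]

    round_no = 0
    while remaining:
        round_no += 1
        gains = []
        for f in sorted(remaining):
            trial_acc = _cv_accuracy(
                selected + [f], X, y, folds, cfg, seed_offset=50_000 + 100 * round_no
            )
            if cfg.gain == "relative" and acc > 0:
                gain = (trial_acc - acc) / acc
            else:
                gain = trial_acc - acc
            gains.append((gain, trial_acc, f))
        gain, trial_acc, best = max(gains, key=lambda t: (t[0], t[2]))
        if trial_acc <= acc:
            break
        selected.append(best)
        remaining.remove(best)
        acc = trial_acc
        records.append({"selected": list(selected), "accuracy": acc, "added": best})
    return selected, records


def run_two_step_selection(
    X: pd.DataFrame,
    y,
    family_ids: pd.Series,
    candidates: list[str] | None = None,
    cfg: SelectionConfig | None = None,
) -> SelectionTrace:
    """Backward elimination per fold, union, then forward selection.

    ``y`` may be string labels ("pathogenic"/"neutral") or 0/1. Returns
    the full :class:`SelectionTrace` whose ``selected_feature_set`` is the
    final answer.
    """
    cfg = cfg if cfg is not None else SelectionConfig()
    if candidates is None:
        candidates = list(X.columns)
    y = np.asarray(
        [1 if v in (1, "pathogenic") else 0 for v in y], dtype=int
    )
    folds = family_kfold(family_ids, k=cfg.k, seed=cfg.seed)

    trace = SelectionTrace()
    for i, test_idx in enumerate(folds):
        train_idx = np.setdiff1d(np.arange(len(X)), test_idx)
        # leakage guard: train and test families must be disjoint
        train_fams = set(family_ids.iloc[train_idx])
        test_fams = set(family_ids.iloc[test_idx])
        assert not (train_fams & test_fams), "family leakage across CV folds"
        fold_cfg = SelectionConfig(
            n_trees=cfg.n_trees,
            mtry=cfg.mtry,
            k=cfg.k,
            seed=cfg.seed + 7919 * (i + 1),
            gain=cfg.gain,
        )
        subset, records = backward_elimination(
            X.iloc[train_idx],
            y[train_idx],
            X.iloc[test_idx],
            y[test_idx],
            candidates,
            fold_cfg,
        )
        trace.step1_subsets.append(subset)
        trace.step1_records.append(records)

    non_redundant = sorted(set().union(*trace.step1_subsets))
    trace.non_redundant_set = non_redundant
    selected, records = forward_selection(non_redundant, X, y, family_ids, cfg)
    trace.step2_records = records
    trace.selected_feature_set = selected
    return trace
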