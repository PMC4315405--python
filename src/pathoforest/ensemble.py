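"""Stratified-bootstrap random-forest ensemble with a Chebyshev reject option.

The classifier is an ensemble of random forests: each member is trained on
a stratified bootstrap resample (with replacement, preserving the original
class counts) of the training data. For a query variant, each member
reports the fraction of its trees voting pathogenic; the spread of these
member probabilities quantifies prediction stability. Because the
distribution of bootstrap probabilities is unknown, Chebyshev's
inequality gives a distribution-free reliability interval
``mu +/- k*sigma`` with ``k = 1/sqrt(1 - confidence)`` (so at least
``confidence`` of the mass lies inside). Only when the interval excludes
0.5 is the variant classified (pathogenic or neutral); otherwise it is
reported as unknown.

The API follows the model/results convention: build a
:class:`BootstrapForestClassifier` from a feature table and labels, call
:meth:`~BootstrapForestClassifier.fit` to obtain a
:class:`BootstrapForestResults`, and predict/summarise from the results
object.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import asdict, dataclass, field
from pathlib import Path

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier

from .features import FeatureTable

POSITIVE = "pathogenic"
NEGATIVE = "neutral"
UNKNOWN = "unknown"


@dataclass(frozen=True)
class EnsembleConfig:
    """Hyper-parameters of the bootstrap forest ensemble.

    Defaults: 200 bootstrap members, 300 trees per forest, 2 features
    sampled per split, reject-option confidence 0.95.
    """

    n_bootstrap: int = 200
    n_trees: int = 300
    mtry: int = 2
    confidence: float = 0.95
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_bootstrap < 1 or self.n_trees < 1 or self.mtry < 1:
            raise ValueError("n_bootstrap, n_trees and mtry must be positive")
        if not (0.0 < self.confidence < 1.0):
            raise ValueError("confidence must lie strictly between 0 and 1")


def member_seed(master_seed: int, member_index: int, stream: int = 0) -> int:
    """Deterministic per-member seed, independent of scheduling order."""
    ss = np.random.SeedSequence(entropy=master_seed, spawn_key=(member_index, stream))
    return int(ss.generate_state(1)[0] % (2**31))


def stratified_bootstrap(labels: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """Bootstrap indices preserving the per-class counts of ``labels``.

    The sample has exactly the size of the input, with each class drawn
    with replacement from its own members, so every resample has the same
    class composition as the original data.
    """
    labels = np.asarray(labels)
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("stratified bootstrap requires both classes present")
    parts = []
    for cls in classes:
        idx = np.flatnonzero(labels == cls)
        parts.append(rng.choice(idx, size=len(idx), replace=True))
    out = np.concatenate(parts)
    rng.shuffle(out)
    return out


def chebyshev_k(confidence: float) -> float:
    """Reliability multiplier: k such that 1 - 1/k**2 = confidence."""
    if not (0.0 < confidence < 1.0):
        raise ValueError("confidence must lie strictly between 0 and 1")
    return 1.0 / math.sqrt(1.0 - confidence)


def chebyshev_classify(mu: float, sigma: float, confidence: float) -> str:
    """Tri-class call from the Chebyshev reliability interval.

    pathogenic if mu - k*sigma > 0.5, neutral if mu + k*sigma < 0.5,
    unknown otherwise (strict inequalities: an interval endpoint exactly
    at 0.5 does not exclude it).
    """
    k = chebyshev_k(confidence)
    if mu - k * sigma > 0.5:
        return POSITIVE
    if mu + k * sigma < 0.5:
        return NEGATIVE
    return UNKNOWN


def member_probability(forest: RandomForestClassifier, X: np.ndarray) -> np.ndarray:
    """Fraction of trees voting pathogenic, per query row."""
    votes = np.stack([tree.predict(X) for tree in forest.estimators_])
    return votes.mean(axis=0)


@dataclass
class Predictions:
    """Tri-class predictions with their reliability intervals.

    ``frame`` has one row per variant (mu, sigma, lower, upper, call,
    binary_call, combined); ``member_probs`` is the underlying
    (n_variants, n_members) matrix of per-member pathogenicity
    probabilities.
    """

    frame: pd.DataFrame
    member_probs: np.ndarray
    confidence: float

    @property
    def coverage(self) -> float:
        """Fraction of variants classified (not unknown)."""
        if len(self.frame) == 0:
            return float("nan")
        return float((self.frame["call"] != UNKNOWN).mean())

    def to_tsv(self, path) -> None:
        from .io import write_predictions

        write_predictions(self.frame, path)


class BootstrapForestClassifier:
    """Reject-option pathogenicity model built from features and labels.

    Parameters
    ----------
    features : FeatureTable or DataFrame
        Variants x numeric features; NaN marks missing values.
    labels : sequence of {"pathogenic", "neutral"}
        Training labels aligned with the feature rows.
    config : EnsembleConfig
        Ensemble hyper-parameters.
    go_feature : str or None
        Name of the GO-derived column. Missing values in every other
        column are median-imputed (medians from training data); a variant
        missing the GO feature is instead served by a parallel fallback
        ensemble trained without that column, since a protein without GO
        annotation carries no information to impute from. Set to None
        (or ``go_fallback=False``) for imputation-only behaviour.
    """

    def __init__(
        self,
        features: FeatureTable | pd.DataFrame,
        labels,
        config: EnsembleConfig | None = None,
        go_feature: str | None = "go_lr",
        go_fallback: bool = True,
    ):
        df = features.values if isinstance(features, FeatureTable) else features
        self.features = df.astype(float)
        y = pd.Series(list(labels), index=df.index)
        bad = set(y.unique()) - {POSITIVE, NEGATIVE}
        if bad:
            raise ValueError(f"unsupported label value(s): {sorted(bad)}")
        self.labels = y
        self.config = config if config is not None else EnsembleConfig()
        self.go_feature = go_feature if go_feature in df.columns else None
        self.go_fallback = go_fallback and self.go_feature is not None
        if df.shape[1] < 2:
            raise ValueError("at least 2 features are required")
        fully_missing = [c for c in df.columns if df[c].isna().all()]
        if fully_missing:
            raise ValueError(f"feature column(s) entirely missing: {fully_missing}")
        if y.nunique() < 2:
            raise ValueError("training data must contain both classes")

    @classmethod
    def from_dataframe(
        cls,
        frame: pd.DataFrame,
        label_col: str = "label",
        feature_cols: list[str] | None = None,
        **kwargs,
    ) -> "BootstrapForestClassifier":
        """Build from a single table holding features and a label column."""
        if feature_cols is None:
            feature_cols = [
                c
                for c in frame.columns
                if c != label_col and pd.api.types.is_numeric_dtype(frame[c])
            ]
        return cls(frame[feature_cols], frame[label_col], **kwargs)

    def _fingerprint(self) -> str:
        h = hashlib.sha1()
        h.update(",".join(self.features.columns).encode())
        h.update(str(self.features.shape).encode())
        h.update(",".join(self.labels.astype(str)).encode())
        return h.hexdigest()[:12]

    def _train_members(
        self, X: np.ndarray, y: np.ndarray, stream: int
    ) -> list[RandomForestClassifier]:
        cfg = self.config
        members = []
        for m in range(cfg.n_bootstrap):
            rng = np.random.default_rng(member_seed(cfg.seed, m, stream * 2))
            idx = stratified_bootstrap(y, rng)
            forest = RandomForestClassifier(
                n_estimators=cfg.n_trees,
                max_features=min(cfg.mtry, X.shape[1]),
                random_state=member_seed(cfg.seed, m, stream * 2 + 1),
                bootstrap=False,  # resampling handled by the outer bootstrap
                n_jobs=1,
            )
            forest.fit(X[idx], y[idx])
            members.append(forest)
        return members

    def fit(self) -> "BootstrapForestResults":
        """Train the ensemble (and the GO-less fallback, when configured)."""
        medians = self.features.median(skipna=True)
        X = self.features.fillna(medians)
        y = (self.labels == POSITIVE).astype(int).to_numpy()

        main_cols = list(self.features.columns)
        members = self._train_members(X[main_cols].to_numpy(), y, stream=0)

        fallback = None
        fallback_cols = None
        if self.go_fallback:
            fallback_cols = [c for c in main_cols if c != self.go_feature]
            if len(fallback_cols) >= 2:
                fallback = self._train_members(X[fallback_cols].to_numpy(), y, stream=1)
            else:
                fallback_cols = None
        return BootstrapForestResults(
            model=self,
            members=members,
            fallback_members=fallback,
            feature_names=main_cols,
            fallback_feature_names=fallback_cols,
            medians=medians,
            fingerprint=self._fingerprint(),
        )


@dataclass
class BootstrapForestResults:
    """Fitted ensemble: members, imputation state and prediction methods."""

    model: BootstrapForestClassifier | None
    members: list[RandomForestClassifier]
    feature_names: list[str]
    medians: pd.Series
    fingerprint: str
    fallback_members: list[RandomForestClassifier] | None = None
    fallback_feature_names: list[str] | None = None
    config: EnsembleConfig = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        if self.config is None and self.model is not None:
            self.config = self.model.config

    @property
    def n_members(self) -> int:
        return len(self.members)

    def member_probabilities(self, features: FeatureTable | pd.DataFrame) -> np.ndarray:
        """(n_variants, n_members) matrix of per-member vote fractions.

        Rows missing the GO feature are routed to the fallback ensemble
        when one was trained; all other missing values are median-imputed
        with the training medians.
        """
        df = features.values if isinstance(features, FeatureTable) else features
        missing_cols = [c for c in self.feature_names if c not in df.columns]
        if missing_cols:
            raise ValueError(f"prediction table lacks feature(s) {missing_cols}")
        go = self.model.go_feature if self.model is not None else (
            set(self.feature_names) - set(self.fallback_feature_names or self.feature_names)
        )
        if isinstance(go, set):
            go = next(iter(go)) if go else None
        use_fallback = (
            df[go].isna().to_numpy()
            if go is not None and self.fallback_members is not None
            else np.zeros(len(df), dtype=bool)
        )
        X = df.reindex(columns=self.feature_names).fillna(self.medians)

        probs = np.empty((len(df), self.n_members))
        main_rows = ~use_fallback
        if main_rows.any():
            Xm = X.loc[main_rows, self.feature_names].to_numpy()
            for m, forest in enumerate(self.members):
                probs[main_rows, m] = member_probability(forest, Xm)
        if use_fallback.any():
            Xf = X.loc[use_fallback, self.fallback_feature_names].to_numpy()
            for m, forest in enumerate(self.fallback_members):
                probs[use_fallback, m] = member_probability(forest, Xf)
        return probs

    def predict(
        self,
        features: FeatureTable | pd.DataFrame,
        annotation_pa: pd.Series | None = None,
        confidence: float | None = None,
        combine: str = "per_member",
        combine_mode: str = "noisy_or",
    ) -> Predictions:
        """Tri-class predictions with Chebyshev reliability intervals.

        When ``annotation_pa`` supplies a functional-site prior Pa for a
        variant, the noisy-OR combination is applied to each member's
        probability before the mean and spread are computed (default), so
        the reliability interval itself reflects the annotation; pass
        ``combine="mean_only"`` to shift only the mean. ``combine_mode``
        is forwarded to :func:`~pathoforest.annotations.combine_probability`
        (``"symmetric"`` lets neutral-biased priors push downward).
        """
        from .annotations import combine_probability

        df = features.values if isinstance(features, FeatureTable) else features
        conf = self.config.confidence if confidence is None else confidence
        k = chebyshev_k(conf)
        probs = self.member_probabilities(df)

        combined = np.zeros(len(df), dtype=bool)
        if annotation_pa is not None:
            pa = annotation_pa.reindex(df.index)
            for i, (vid, p) in enumerate(pa.items()):
                if p is None or (isinstance(p, float) and math.isnan(p)):
                    continue
                combined[i] = True
                if combine == "per_member":
                    probs[i, :] = [
                        combine_probability(p, x, mode=combine_mode)
                        for x in probs[i, :]
                    ]

        mu = probs.mean(axis=1)
        # sample standard deviation over the bootstrap members
        sigma = probs.std(axis=1, ddof=1) if probs.shape[1] > 1 else np.zeros(len(df))
        if annotation_pa is not None and combine == "mean_only":
            pa = annotation_pa.reindex(df.index).to_numpy(dtype=float)
            for i in np.flatnonzero(~np.isnan(pa)):
                mu[i] = combine_probability(pa[i], mu[i], mode=combine_mode)

        lower = mu - k * sigma
        upper = mu + k * sigma
        calls = np.where(lower > 0.5, POSITIVE, np.where(upper < 0.5, NEGATIVE, UNKNOWN))
        # binary fallback: threshold 0.5 on mu; exact tie goes neutral to
        # keep false positives low
        binary = np.where(mu > 0.5, POSITIVE, NEGATIVE)

        frame = pd.DataFrame(
            {
                "variant_id": list(df.index),
                "mu": mu,
                "sigma": sigma,
                "lower": lower,
                "upper": upper,
                "call": calls,
                "binary_call": binary,
                "combined": combined,
            },
            index=df.index,
        )
        return Predictions(frame=frame, member_probs=probs, confidence=conf)

    def summary(self) -> str:
        """Plain-text summary of the fitted ensemble."""
        cfg = self.config
        lines = [
            "Bootstrap random-forest reject-option classifier",
            "=" * 48,
            f"members (bootstrap samples): {self.n_members}",
            f"trees per forest:            {cfg.n_trees}",
            f"features per split (mtry):   {cfg.mtry}",
            f"confidence / k:              {cfg.confidence} / {chebyshev_k(cfg.confidence):.4f}",
            f"features ({len(self.feature_names)}): {', '.join(self.feature_names)}",
            f"GO fallback ensemble:        {'yes' if self.fallback_members else 'no'}",
            f"training fingerprint:        {self.fingerprint}",
        ]
        if self.model is not None:
            counts = self.model.labels.value_counts().to_dict()
            lines.append(f"training class counts:       {counts}")
        return "\n".join(lines)

    def save(self, directory) -> None:
        """Persist config + members + feature manifest to a directory."""
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        with open(d / "config.json", "w") as fh:
            json.dump(asdict(self.config), fh, indent=2)
        manifest = {
            "feature_names": self.feature_names,
            "fallback_feature_names": self.fallback_feature_names,
            "medians": {k: float(v) for k, v in self.medians.items()},
            "fingerprint": self.fingerprint,
        }
        with open(d / "manifest.json", "w") as fh:
            json.dump(manifest, fh, indent=2)
        joblib.dump(
            {"members": self.members, "fallback_members": self.fallback_members},
            d / "members.joblib",
        )

    @classmethod
    def load(cls, directory) -> "BootstrapForestResults":
        d = Path(directory)
        with open(d / "config.json") as fh:
            config = EnsembleConfig(**json.load(fh))
        with open(d / "manifest.json") as fh:
            manifest = json.load(fh)
        blobs = joblib.load(d / "members.joblib")
        return cls(
            model=None,
            members=blobs["members"],
            fallback_members=blobs["fallback_members"],
            feature_names=manifest["feature_names"],
            fallback_feature_names=manifest["fallback_feature_names"],
            medians=pd.Series(manifest["medians"]),
            fingerprint=manifest["fingerprint"],
            config=config,
        )
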