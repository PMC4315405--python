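"""Six-measure performance evaluation, nMCC, OPM and performance cuboids.

Binary classifier performance is summarised by the six standard measures
(PPV, NPV, sensitivity, specificity, accuracy, MCC). MCC is rescaled to
[0, 1] as nMCC = (1 + MCC)/2, and the six scores are combined into a
single overall performance measure

    OPM = (PPV + NPV)(Sens + Spec)(Acc + nMCC) / 8,

geometrically the normalised volume of an axis-aligned "performance
cuboid" whose six face distances from the origin are the six scores.

For a reject-option classifier, metrics are computed over the classified
(non-unknown) calls; coverage — the fraction of submitted variants that
received a pathogenic or neutral call — is reported alongside, together
with an optional all-variant binary-fallback table.

Measures with a zero denominator are explicit ``None`` ("undefined"),
never silent NaN.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence

import numpy as np


@dataclass(frozen=True)
class ConfusionTable:
    """TP/TN/FP/FN counts (positive class = pathogenic)."""

    tp: int
    tn: int
    fp: int
    fn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.tn, self.fp, self.fn) < 0:
            raise ValueError("confusion counts must be non-negative")

    @property
    def total(self) -> int:
        return self.tp + self.tn + self.fp + self.fn


@dataclass(frozen=True)
class PerformanceScores:
    """The six measures plus nMCC, OPM and (optionally) coverage.

    Undefined values (zero denominators) are ``None``; OPM is ``None``
    whenever any constituent is.
    """

    ppv: float | None
    npv: float | None
    sensitivity: float | None
    specificity: float | None
    accuracy: float | None
    mcc: float | None
    nmcc: float | None
    opm: float | None
    coverage: float | None = None

    def rounded(self, ndigits: int = 2) -> dict[str, float | None]:
        """Scores at printed-table precision (banker's rounding)."""
        out = {}
        for name in (
            "ppv",
            "npv",
            "sensitivity",
            "specificity",
            "accuracy",
            "mcc",
            "nmcc",
            "opm",
            "coverage",
        ):
            v = getattr(self, name)
            out[name] = None if v is None else round(v, ndigits)
        return out


def _ratio(num: int, den: int) -> float | None:
    return None if den == 0 else num / den


def confusion_metrics(ct: ConfusionTable) -> PerformanceScores:
    """The six measures, nMCC and OPM from a confusion table.

    PPV = TP/(TP+FP); NPV = TN/(TN+FN); sensitivity = TP/(TP+FN);
    specificity = TN/(TN+FP); accuracy = (TP+TN)/total;
    MCC = (TP*TN - FP*FN)/sqrt((TP+FP)(TP+FN)(TN+FP)(TN+FN)).
    """
    if ct.total == 0:
        raise ValueError("empty confusion table")
    ppv = _ratio(ct.tp, ct.tp + ct.fp)
    npv = _ratio(ct.tn, ct.tn + ct.fn)
    sens = _ratio(ct.tp, ct.tp + ct.fn)
    spec = _ratio(ct.tn, ct.tn + ct.fp)
    acc = (ct.tp + ct.tn) / ct.total
    denom = (
        (ct.tp + ct.fp) * (ct.tp + ct.fn) * (ct.tn + ct.fp) * (ct.tn + ct.fn)
    )
    mcc = (
        None
        if denom == 0
        else (ct.tp * ct.tn - ct.fp * ct.fn) / math.sqrt(denom)
    )
    nmcc = None if mcc is None else (1 + mcc) / 2
    if None in (ppv, npv, sens, spec, nmcc):
        opm = None
    else:
        opm = (ppv + npv) * (sens + spec) * (acc + nmcc) / 8
    return PerformanceScores(ppv, npv, sens, spec, acc, mcc, nmcc, opm)


def opm_from_scores(
    ppv: float,
    npv: float,
    sensitivity: float,
    specificity: float,
    accuracy: float,
    mcc: float,
) -> float:
    """OPM from six (possibly table-printed) scores.

    nMCC = (1 + MCC)/2, then
    OPM = (PPV + NPV)(Sens + Spec)(Acc + nMCC)/8.
    """
    for name, v, lo, hi in (
        ("ppv", ppv, 0, 1),
        ("npv", npv, 0, 1),
        ("sensitivity", sensitivity, 0, 1),
        ("specificity", specificity, 0, 1),
        ("accuracy", accuracy, 0, 1),
        ("mcc", mcc, -1, 1),
    ):
        if not (lo <= v <= hi):
            raise ValueError(f"{name}={v} outside [{lo}, {hi}]")
    nmcc = (1 + mcc) / 2
    return (ppv + npv) * (sensitivity + specificity) * (accuracy + nmcc) / 8


@dataclass
class EvaluationResult:
    """Reject-option evaluation: classified-only scores plus coverage.

    ``binary`` holds the all-variant fallback evaluation (every unknown
    replaced by its binary call) when binary calls were supplied — the
    "scores in parentheses" convention of printed comparison tables.
    """

    table: ConfusionTable | None
    scores: PerformanceScores | None
    coverage: float
    binary_table: ConfusionTable | None = None
    binary_scores: PerformanceScores | None = None


def _tabulate(calls: Sequence[str], labels: Sequence[str]) -> ConfusionTable:
    tp = tn = fp = fn = 0
    for c, l in zip(calls, labels):
        if l == "pathogenic":
            if c == "pathogenic":
                tp += 1
            else:
                fn += 1
        else:
            if c == "neutral":
                tn += 1
            else:
                fp += 1
    return ConfusionTable(tp, tn, fp, fn)


def evaluate_predictions(
    calls: Sequence[str],
    labels: Sequence[str],
    binary_calls: Sequence[str] | None = None,
) -> EvaluationResult:
    """Score tri-class calls against labels.

    Unknown calls are excluded from the confusion table but counted in
    coverage's denominator (all submitted labelled variants). When
    ``binary_calls`` are given, the all-variant binary evaluation is
    attached as well.
    """
    if len(calls) != len(labels):
        raise ValueError(f"{len(calls)} calls vs {len(labels)} labels")
    bad = set(labels) - {"pathogenic", "neutral"}
    if bad:
        raise ValueError(f"unsupported label(s): {sorted(bad)}")
    classified = [(c, l) for c, l in zip(calls, labels) if c != "unknown"]
    coverage = len(classified) / len(calls) if calls else float("nan")
    if classified:
        table = _tabulate(*zip(*classified))
        scores = confusion_metrics(table)
        scores = PerformanceScores(
            **{**scores.__dict__, "coverage": coverage}
        )
    else:
        table = None
        scores = None
    result = EvaluationResult(table=table, scores=scores, coverage=coverage)
    if binary_calls is not None:
        if len(binary_calls) != len(labels):
            raise ValueError("binary_calls length mismatch")
        result.binary_table = _tabulate(binary_calls, labels)
        result.binary_scores = confusion_metrics(result.binary_table)
    return result


@dataclass
class Cuboid:
    """Axis-aligned performance cuboid.

    Face distances from the origin: +x PPV, -x NPV, +y sensitivity,
    -y specificity, +z accuracy, -z nMCC. The normalised volume (volume/8)
    equals OPM by construction.
    """

    ppv: float
    npv: float
    sensitivity: float
    specificity: float
    accuracy: float
    nmcc: float

    @property
    def face_distances(self) -> dict[str, float]:
        return {
            "+x": self.ppv,
            "-x": self.npv,
            "+y": self.sensitivity,
            "-y": self.specificity,
            "+z": self.accuracy,
            "-z": self.nmcc,
        }

    @property
    def vertices(self) -> np.ndarray:
        xs = (self.ppv, -self.npv)
        ys = (self.sensitivity, -self.specificity)
        zs = (self.accuracy, -self.nmcc)
        return np.array([[x, y, z] for x in xs for y in ys for z in zs])

    @property
    def volume(self) -> float:
        return (
            (self.ppv + self.npv)
            * (self.sensitivity + self.specificity)
            * (self.accuracy + self.nmcc)
        )

    @property
    def normalized_volume(self) -> float:
        return self.volume / 8.0


def cuboid_geometry(scores: PerformanceScores) -> Cuboid:
    """Build the performance cuboid; errors if any score is undefined.

    The cuboid's normalised volume is re-derived from the geometry and
    asserted to equal the analytic OPM.
    """
    needed = ("ppv", "npv", "sensitivity", "specificity", "accuracy", "nmcc")
    vals = {n: getattr(scores, n) for n in needed}
    undefined = [n for n, v in vals.items() if v is None]
    if undefined:
        raise ValueError(f"undefined score(s) for cuboid: {undefined}")
    cuboid = Cuboid(**vals)
    if scores.opm is not None:
        assert abs(cuboid.normalized_volume - scores.opm) < 1e-12
    return cuboid


def plot_cuboid(cuboid: Cuboid, ax=None, **kwargs):
    """Render the cuboid's edges on a 3-D matplotlib axis (optional extra)."""
    import matplotlib.pyplot as plt

    if ax is None:
        fig = plt.figure()
        ax = fig.add_subplot(projection="3d")
    v = cuboid.vertices
    edges = [
        (a, b)
        for a in range(8)
        for b in range(a + 1, 8)
        if sum(v[a] != v[b]) == 1
    ]
    for a, b in edges:
        ax.plot(*zip(v[a], v[b]), **kwargs)
    ax.set_xlabel("PPV / NPV")
    ax.set_ylabel("Sens / Spec")
    ax.set_zlabel("Acc / nMCC")
    return ax
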