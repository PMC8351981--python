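"""Community-quality metrics and the per-seed benchmark protocol.

A predicted community is compared with its ground-truth community at the
node level over the whole universe, yielding a 2x2 contingency table
(TP/FP/FN/TN) and eight metrics: specificity, precision, recall, accuracy,
F1, Matthews correlation coefficient, false discovery rate, and normalized
mutual information between the two binary membership labelings.

The benchmark protocol seeds the detector at every node of every
ground-truth community, scores each output against the seed's own
community, and reports per-seed metrics plus their mean and median.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .network import GroundTruth, MultilayerNetwork
from .transition import TransitionModel, build_transition_model
from .walker import WalkParams, run_plcdm

__all__ = [
    "ContingencyTable",
    "MetricsReport",
    "contingency",
    "compute_metrics",
    "nmi",
    "score_community",
    "benchmark",
    "METRIC_COLUMNS",
]

METRIC_COLUMNS = [
    "specificity",
    "precision",
    "recall",
    "accuracy",
    "f1",
    "mcc",
    "fdr",
    "nmi",
]


@dataclass(frozen=True)
class ContingencyTable:
    """Node-level confusion counts of a predicted vs. true community."""

    tp: int
    fp: int
    fn: int
    tn: int

    @property
    def universe_size(self) -> int:
        return self.tp + self.fp + self.fn + self.tn

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("contingency counts must be nonnegative")


@dataclass(frozen=True)
class MetricsReport:
    """The eight evaluation metrics plus their contingency table.

    ``degenerate`` is True when any metric hit a zero-denominator convention
    (reported as 0), so aggregations can exclude such seeds if desired.
    """

    specificity: float
    precision: float
    recall: float
    accuracy: float
    f1: float
    mcc: float
    fdr: float
    nmi: float
    table: ContingencyTable
    degenerate: bool = False


def contingency(
    predicted: set[str], truth: set[str], universe: set[str]
) -> ContingencyTable:
    """Contingency table of *predicted* vs. *truth* over *universe*."""
    predicted, truth, universe = set(predicted), set(truth), set(universe)
    if not predicted <= universe or not truth <= universe:
        raise ValueError("predicted and truth must be subsets of the universe")
    tp = len(predicted & truth)
    fp = len(predicted - truth)
    fn = len(truth - predicted)
    tn = len(universe) - tp - fp - fn
    return ContingencyTable(tp=tp, fp=fp, fn=fn, tn=tn)


def _ratio(num: float, den: float) -> tuple[float, bool]:
    if den == 0:
        return 0.0, True
    return num / den, False


def compute_metrics(table: ContingencyTable, nmi_value: float = float("nan")) -> MetricsReport:
    """The seven set-based metrics from a contingency table.

    Zero denominators yield 0 with the report's ``degenerate`` flag set.
    NMI requires the raw sets; pass it via ``nmi_value`` or use
    :func:`score_community`.
    """
    tp, fp, fn, tn = table.tp, table.fp, table.fn, table.tn
    degenerate = False
    specificity, d1 = _ratio(tn, tn + fp)
    precision, d2 = _ratio(tp, tp + fp)
    recall, d3 = _ratio(tp, tp + fn)
    accuracy, d4 = _ratio(tp + tn, table.universe_size)
    f1, d5 = _ratio(2 * tp, 2 * tp + fp + fn)
    fdr, d6 = _ratio(fp, fp + tp)
    mcc_den = math.sqrt(
        float(tp + fp) * (tp + fn) * (tn + fp) * (tn + fn)
    )
    mcc, d7 = _ratio(tp * tn - fp * fn, mcc_den)
    degenerate = any((d1, d2, d3, d4, d5, d6, d7))
    return MetricsReport(
        specificity=specificity,
        precision=precision,
        recall=recall,
        accuracy=accuracy,
        f1=f1,
        mcc=mcc,
        fdr=fdr,
        nmi=nmi_value,
        table=table,
        degenerate=degenerate,
    )


def _entropy(probs: np.ndarray) -> float:
    p = probs[probs > 0]
    return float(-(p * np.log(p)).sum())


def nmi(predicted: set[str], truth: set[str], universe: set[str]) -> float:
    """NMI between the binary membership labelings over the universe.

    NMI(Y, C) = 2·I(Y; C) / (H(Y) + H(C)) with natural-log entropies,
    computed from the 2x2 joint counts; 0 when either labeling is constant.
    """
    if not universe:
        raise ValueError("universe must be non-empty")
    t = contingency(predicted, truth, universe)
    n = t.universe_size
    joint = np.array([[t.tp, t.fp], [t.fn, t.tn]], dtype=np.float64) / n
    py = joint.sum(axis=1)  # predicted: in/out
    pc = joint.sum(axis=0)  # truth: in/out
    hy, hc = _entropy(py), _entropy(pc)
    if hy == 0.0 or hc == 0.0:
        return 0.0
    mi = 0.0
    for a in range(2):
        for b in range(2):
            if joint[a, b] > 0:
                mi += joint[a, b] * math.log(joint[a, b] / (py[a] * pc[b]))
    return max(0.0, 2.0 * mi / (hy + hc))


def score_community(
    predicted: set[str], truth: set[str], universe: set[str]
) -> MetricsReport:
    """All eight metrics for one predicted community."""
    table = contingency(predicted, truth, universe)
    return compute_metrics(table, nmi_value=nmi(predicted, truth, universe))


def benchmark(
    net: MultilayerNetwork,
    truth: GroundTruth,
    params: WalkParams | None = None,
    replicates: int = 1,
    model: TransitionModel | None = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Seed the detector at every ground-truth node and score each run.

    Every node of every ground-truth community is used as a seed;
    the detected community is compared against that node's own community.
    ``replicates`` repeats each seeded walk with a distinct RNG substream.

    Returns ``(per_seed, summary)``: one row per (community, seed,
    replicate) with the contingency counts and all metrics, and a two-row
    mean/median aggregate.
    """
    if len(truth) == 0:
        raise ValueError("ground truth is empty")
    params = params or WalkParams()
    if model is None:
        model = build_transition_model(net)
    universe = set(net.nodes)
    base_seed = int(params.rng_seed)
    rows = []
    for ci, community in enumerate(truth):
        for seed in sorted(community):
            for rep in range(replicates):
                sub = np.random.SeedSequence(
                    [base_seed, ci, model.node_index[seed], rep]
                ).generate_state(1)[0] % (2**31)
                run_params = WalkParams(
                    iteration_count=params.iteration_count,
                    jump_prob=params.jump_prob,
                    layer_change_prob=params.layer_change_prob,
                    rng_seed=int(sub),
                )
                result = run_plcdm(net, model, seed, run_params)
                report = score_community(result.community, community, universe)
                rows.append(
                    {
                        "community": ci,
                        "seed": seed,
                        "replicate": rep,
                        "community_size": len(result.community),
                        "TP": report.table.tp,
                        "FP": report.table.fp,
                        "FN": report.table.fn,
                        "TN": report.table.tn,
                        **{m: getattr(report, m) for m in METRIC_COLUMNS},
                        "degenerate": report.degenerate,
                    }
                )
    per_seed = pd.DataFrame(rows)
    summary = pd.DataFrame(
        {
            "mean": per_seed[METRIC_COLUMNS].mean(),
            "median": per_seed[METRIC_COLUMNS].median(),
        }
    ).T
    return per_seed, summary
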