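"""Evaluation: per-residue and per-protein Q accuracy, segment-overlap
scores (SOV'99 and a refined-allowance variant), and the two-proportion
significance threshold.

Segment-overlap scores treat maximal same-class runs, not single residues,
as the prediction unit.  For every class i, each observed segment s1 is
paired with every predicted segment s2 of the same class that overlaps it;
a pair contributes ``len(s1) * (minov + delta) / maxov`` where minov is the
length of the actual overlap and maxov the span of the union.  SOV'99 uses
the allowance ``delta = min(maxov - minov, minov, len(s1)//2, len(s2)//2)``.
The normalizer sums len(s1) over all pairs plus all unpaired observed
segments, and the overall score pools numerators and normalizers over
classes.

SOV'99's allowance can fully forgive small end deviations: an imperfect
prediction can score exactly 100 (e.g. observed ``HHH`` vs predicted
``HHE``).  The refined variant here keeps the same pair structure but uses
an allowance proportional to both the overlap ratio and the remaining
mismatch, ``delta = lambda * (minov / maxov) * (maxov - minov)``, which is
strictly below ``maxov - minov`` whenever the overlap is imperfect (for
lambda <= 1).  Consequently the refined score is 100 exactly when the two
segmentations coincide, and as lambda -> 0 it approaches the bare overlap
ratio with no allowance.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Sequence


@dataclass(frozen=True)
class SegmentRun:
    """A maximal run of one class: 1-based inclusive [start, end]."""

    label: str
    start: int
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def segments(ss: str) -> list[SegmentRun]:
    """Maximal same-class runs tiling a label string."""
    runs: list[SegmentRun] = []
    if not ss:
        return runs
    start = 0
    for i in range(1, len(ss) + 1):
        if i == len(ss) or ss[i] != ss[start]:
            runs.append(SegmentRun(ss[start], start + 1, i))
            start = i
    return runs


def _as_lists(pred, obs) -> tuple[list[str], list[str]]:
    if isinstance(pred, str):
        pred, obs = [pred], [obs]
    pred, obs = list(pred), list(obs)
    if len(pred) != len(obs):
        raise ValueError("prediction and observation lists differ in length")
    for i, (p, o) in enumerate(zip(pred, obs)):
        if len(p) != len(o):
            raise ValueError(
                f"protein {i}: predicted length {len(p)} != observed {len(o)}"
            )
    return pred, obs


def q_accuracy(pred, obs) -> tuple[float, float]:
    """Fraction of residues predicted in the observed class, as percentages.

    Returns ``(per_aa, per_protein)``: per_aa pools all residues of all
    proteins; per_protein averages the per-protein fractions uniformly, so
    short proteins weigh as much as long ones.
    """
    pred, obs = _as_lists(pred, obs)
    correct = 0
    total = 0
    per_protein = []
    for p, o in zip(pred, obs):
        c = sum(a == b for a, b in zip(p, o))
        correct += c
        total += len(o)
        per_protein.append(100.0 * c / len(o))
    if total == 0:
        raise ValueError("empty evaluation set")
    return 100.0 * correct / total, sum(per_protein) / len(per_protein)


def _overlap(s1: SegmentRun, s2: SegmentRun) -> tuple[int, int]:
    """(minov, maxov): actual overlap and extent of the union span."""
    minov = min(s1.end, s2.end) - max(s1.start, s2.start) + 1
    maxov = max(s1.end, s2.end) - min(s1.start, s2.start) + 1
    return minov, maxov


def _sov_class(pred: str, obs: str, cls: str, delta_fn) -> tuple[float, float]:
    """(numerator, normalizer) of the SOV sum for one class."""
    obs_segs = [s for s in segments(obs) if s.label == cls]
    pred_segs = [s for s in segments(pred) if s.label == cls]
    num = 0.0
    norm = 0.0
    for s1 in obs_segs:
        overlapping = [s2 for s2 in pred_segs if _overlap(s1, s2)[0] > 0]
        if not overlapping:
            norm += s1.length
            continue
        for s2 in overlapping:
            minov, maxov = _overlap(s1, s2)
            delta = delta_fn(s1, s2, minov, maxov)
            num += s1.length * (minov + delta) / maxov
            norm += s1.length
    return num, norm


def _delta_sov99(s1, s2, minov, maxov):
    return min(maxov - minov, minov, s1.length // 2, s2.length // 2)


def _sov(pred, obs, classes, delta_fn) -> float:
    pred, obs = _as_lists(pred, obs)
    if classes is None:
        classes = sorted({c for s in list(pred) + list(obs) for c in s})
    num = 0.0
    norm = 0.0
    for p, o in zip(pred, obs):
        for cls in classes:
            n, d = _sov_class(p, o, cls, delta_fn)
            num += n
            norm += d
    if norm == 0:
        raise ValueError("no observed segments of the requested classes")
    return 100.0 * num / norm


def sov99(pred, obs, classes: Sequence[str] | None = None) -> float:
    """Segment overlap score, 1999 definition, pooled over all classes.

    Accepts single strings or lists of strings.  ``classes`` defaults to
    every symbol present; pass e.g. ``"HEC"`` to fix the class set.
    """
    return _sov(pred, obs, classes, _delta_sov99)


def sov_refine(pred, obs, classes: Sequence[str] | None = None, lam: float = 1.0) -> float:
    """Segment overlap with the refined, overlap-proportional allowance.

    ``lam`` (> 0) scales the allowance; at lam -> 0 the score approaches
    the bare overlap ratio.  For lam <= 1 the score is 100 exactly when the
    segmentations coincide (unlike SOV'99, whose allowance can fully
    forgive small end deviations).
    """
    if lam <= 0:
        raise ValueError("lambda must be positive")

    def delta(s1, s2, minov, maxov):
        return min(maxov - minov, lam * (minov / maxov) * (maxov - minov))

    return _sov(pred, obs, classes, delta)


def significance_threshold(p: float, n_residues: int) -> float:
    """Accuracy difference (percentage points) significant at p = 0.05.

    Two-proportion z test at accuracy fraction ``p`` over ``n_residues``
    residues: ``1.96 * sqrt(2 p (1-p) / n)``, returned in percentage points.
    """
    if not 0.0 < p < 1.0:
        raise ValueError("accuracy fraction must be in (0, 1)")
    if n_residues < 1:
        raise ValueError("need n_residues >= 1")
    return 100.0 * 1.96 * math.sqrt(2.0 * p * (1.0 - p) / n_residues)


@dataclass
class MetricsReport:
    """Evaluation summary over a set of proteins (all scores in percent)."""

    q_per_aa: float
    q_per_protein: float
    sov99: float
    sov_refine: float
    per_class_q: dict[str, float]
    n_residues: int
    n_proteins: int

    def to_tsv(self) -> str:
        lines = ["metric\tvalue"]
        lines.append(f"q_per_aa\t{self.q_per_aa:.2f}")
        lines.append(f"q_per_protein\t{self.q_per_protein:.2f}")
        lines.append(f"sov99\t{self.sov99:.2f}")
        lines.append(f"sov_refine\t{self.sov_refine:.2f}")
        for cls, v in self.per_class_q.items():
            lines.append(f"q_{cls}\t{v:.2f}")
        lines.append(f"n_residues\t{self.n_residues}")
        lines.append(f"n_proteins\t{self.n_proteins}")
        return "\n".join(lines) + "\n"


def evaluate(pred, obs, classes: Sequence[str] | None = None) -> MetricsReport:
    """Full report: Q per AA / per protein, both SOV scores, per-class recall."""
    pred, obs = _as_lists(pred, obs)
    if classes is None:
        classes = sorted({c for s in obs for c in s})
    q_aa, q_prot = q_accuracy(pred, obs)
    per_class = {}
    for cls in classes:
        tot = sum(o.count(cls) for o in obs)
        hit = sum(
            sum(1 for a, b in zip(p, o) if b == cls and a == cls)
            for p, o in zip(pred, obs)
        )
        per_class[cls] = 100.0 * hit / tot if tot else float("nan")
    return MetricsReport(
        q_per_aa=q_aa,
        q_per_protein=q_prot,
        sov99=sov99(pred, obs, classes),
        sov_refine=sov_refine(pred, obs, classes),
        per_class_q=per_class,
        n_residues=sum(len(o) for o in obs),
        n_proteins=len(obs),
    )
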