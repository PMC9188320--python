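"""Segment- and document-level evaluation with paired statistical tests.

Segment level: one-vs-rest recall/precision/F1 and AUROC (Mann-Whitney
concordance with ties counted 1/2) per extraction target. Document
level: the candidate with the highest class score represents the
document; document accuracy = correctly extracted documents / all test
documents (documents whose gold value was never recovered as a candidate
count as failures). AUROCs are compared pairwise with DeLong's
placement-value test, document accuracies with Pearson's chi-squared
(2x2, no continuity correction); families of p-values are Bonferroni
adjusted with an explicit family size.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy import stats as sps

from sleepscan.segmenter import CLASS_ORDER, Candidate, Label
from sleepscan.synth import GoldRecord

__all__ = [
    "EvalReport",
    "PairwiseComparison",
    "DelongResult",
    "segment_metrics",
    "auroc",
    "delong",
    "extract_document",
    "document_accuracy",
    "wald_ci",
    "wilson_ci",
    "chi2_compare",
    "mcnemar_compare",
    "bonferroni",
    "evaluate_predictions",
    "run_experiment",
]


# ---------------------------------------------------------------------------
# segment level


def segment_metrics(
    pred_labels: Sequence[Label], true_labels: Sequence[Label], c: Label
) -> tuple[float, float, float]:
    """One-vs-rest (recall, precision, F1) for class ``c``.

    Precision with zero predicted positives is reported as 0 with a
    warning (F1 likewise when degenerate).
    """
    if len(pred_labels) != len(true_labels):
        raise ValueError("prediction/truth length mismatch")
    pred = np.array([p == c for p in pred_labels])
    true = np.array([t == c for t in true_labels])
    tp = int((pred & true).sum())
    fp = int((pred & ~true).sum())
    fn = int((~pred & true).sum())
    if tp + fp == 0:
        warnings.warn(f"no predicted positives for {c.value}; precision reported as 0", stacklevel=2)
        precision = 0.0
    else:
        precision = tp / (tp + fp)
    recall = tp / (tp + fn) if (tp + fn) else 0.0
    f1 = 0.0 if (precision + recall) == 0 else 2 * precision * recall / (precision + recall)
    return recall, precision, f1


def auroc(scores: np.ndarray, binary_truth: np.ndarray) -> float:
    """Area under the ROC curve = Mann-Whitney concordance (ties count 1/2)."""
    scores = np.asarray(scores, dtype=float)
    truth = np.asarray(binary_truth).astype(bool)
    m = int(truth.sum())
    n = len(truth) - m
    if m == 0 or n == 0:
        raise ValueError("AUROC needs both classes present")
    ranks = sps.rankdata(scores)
    return float((ranks[truth].sum() - m * (m + 1) / 2) / (m * n))


# ---------------------------------------------------------------------------
# DeLong


@dataclass(frozen=True)
class DelongResult:
    auc_a: float
    auc_b: float
    ci_a: tuple[float, float]
    ci_b: tuple[float, float]
    se_a: float
    se_b: float
    z: float
    p: float


def _placements(scores: np.ndarray, truth: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    x = scores[truth]  # positives
    y = scores[~truth]  # negatives
    cmp = (x[:, None] > y[None, :]).astype(float) + 0.5 * (x[:, None] == y[None, :])
    v10 = cmp.mean(axis=1)
    v01 = cmp.mean(axis=0)
    return v10, v01, float(v10.mean())


def delong(scores_a: np.ndarray, scores_b: np.ndarray, binary_truth: np.ndarray) -> DelongResult:
    """DeLong's test for two correlated AUROCs on the same instances.

    95% CIs are auc +/- 1.96 * SE with the placement-value variance
    estimator. Degenerate variance of the difference (e.g. both models
    separate perfectly) yields p = 1 with a warning.
    """
    truth = np.asarray(binary_truth).astype(bool)
    if truth.all() or not truth.any():
        raise ValueError("DeLong needs both classes present")
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    if a.shape != b.shape or a.shape != truth.shape:
        raise ValueError("scores must be paired on identical instances")
    v10a, v01a, auc_a = _placements(a, truth)
    v10b, v01b, auc_b = _placements(b, truth)
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.stack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.stack([v01a, v01b]), ddof=1)
    var_a = s10[0, 0] / m + s01[0, 0] / n
    var_b = s10[1, 1] / m + s01[1, 1] / n
    se_a, se_b = float(np.sqrt(max(var_a, 0))), float(np.sqrt(max(var_b, 0)))
    var_diff = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    if var_diff <= 0:
        if abs(auc_a - auc_b) > 0:
            warnings.warn("degenerate DeLong variance with unequal AUCs; p set to 1", stacklevel=2)
        z, p = 0.0, 1.0
    else:
        z = float((auc_a - auc_b) / np.sqrt(var_diff))
        p = float(2 * sps.norm.sf(abs(z)))
    ci = lambda auc, se: (max(0.0, auc - 1.96 * se), min(1.0, auc + 1.96 * se))
    return DelongResult(
        auc_a=auc_a, auc_b=auc_b, ci_a=ci(auc_a, se_a), ci_b=ci(auc_b, se_b),
        se_a=se_a, se_b=se_b, z=z, p=p,
    )


# ---------------------------------------------------------------------------
# document level


def extract_document(
    doc_candidates: Sequence[Candidate],
    scores: np.ndarray,
    c: Label,
    gold_value: float,
    tol: float = 0.0,
) -> tuple[float | None, bool]:
    """Pick the document's value for class ``c`` and judge correctness.

    Chosen = candidate with the maximum class score (ties -> earliest in
    reading order). A document with no candidates extracts nothing and is
    judged incorrect.
    """
    if len(doc_candidates) == 0:
        return None, False
    col = CLASS_ORDER.index(c)
    s = np.asarray(scores, dtype=float)[:, col]
    order = np.array([cand.order_idx for cand in doc_candidates])
    best = np.lexsort((order, -s))[0]
    chosen = doc_candidates[int(best)].value
    return chosen, bool(abs(chosen - gold_value) <= tol)


def document_accuracy(flags: Sequence[bool]) -> float:
    """# documents correctly extracted / # documents in the test set."""
    if len(flags) == 0:
        raise ValueError("no documents")
    return float(np.mean(np.asarray(flags, dtype=bool)))


def wald_ci(p_hat: float, n: int, level: float = 0.95) -> tuple[float, float]:
    z = sps.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(p_hat * (1 - p_hat) / n)
    return (max(0.0, p_hat - half), min(1.0, p_hat + half))


def wilson_ci(p_hat: float, n: int, level: float = 0.95) -> tuple[float, float]:
    z = sps.norm.ppf(0.5 + level / 2)
    denom = 1 + z**2 / n
    center = (p_hat + z**2 / (2 * n)) / denom
    half = z * np.sqrt(p_hat * (1 - p_hat) / n + z**2 / (4 * n**2)) / denom
    return (max(0.0, center - half), min(1.0, center + half))


# ---------------------------------------------------------------------------
# tests between models


def chi2_compare(acc_a: tuple[int, int], acc_b: tuple[int, int]) -> tuple[float, float]:
    """Pearson chi-squared (no continuity correction) on correct/incorrect x model."""
    (ca, na), (cb, nb) = acc_a, acc_b
    if not (0 <= ca <= na and 0 <= cb <= nb and na > 0 and nb > 0):
        raise ValueError("invalid counts")
    table = np.array([[ca, na - ca], [cb, nb - cb]], dtype=float)
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        warnings.warn("zero margin in 2x2 table; p reported as 1", stacklevel=2)
        return 0.0, 1.0
    stat, p, _, _ = sps.chi2_contingency(table, correction=False)
    return float(stat), float(p)


def mcnemar_compare(both: int, only_a: int, only_b: int, neither: int) -> tuple[float, float]:
    """McNemar's test on paired document outcomes (optional alternative)."""
    if only_a + only_b == 0:
        return 0.0, 1.0
    stat = (only_a - only_b) ** 2 / (only_a + only_b)
    return float(stat), float(sps.chi2.sf(stat, df=1))


def bonferroni(ps: Sequence[float], m: int) -> list[float]:
    """Family-wise adjustment: p -> min(1, m * p); m is explicit."""
    if m < len(ps):
        raise ValueError(f"family size m={m} smaller than number of comparisons {len(ps)}")
    return [min(1.0, m * p) for p in ps]


@dataclass(frozen=True)
class PairwiseComparison:
    model_a: str
    model_b: str
    target: str           # "AHI" or "SaO2"
    metric: str           # "AUROC" or "DOC_ACC"
    raw_p: float
    adjusted_p: float
    family_size: int

    def __post_init__(self):
        if not np.isclose(self.adjusted_p, min(1.0, self.family_size * self.raw_p)):
            raise ValueError("adjusted_p must equal min(1, m * raw_p)")


# ---------------------------------------------------------------------------
# full evaluation


@dataclass
class EvalReport:
    """Per-target segment metrics + AUROC and document accuracy with CIs."""

    name: str
    n_segments: int
    n_documents: int
    per_class: dict = field(default_factory=dict)  # target -> metric dict

    def as_dict(self) -> dict:
        return {"name": self.name, "n_segments": self.n_segments,
                "n_documents": self.n_documents, **{
                    f"{t}_{k}": v for t, d in self.per_class.items() for k, v in d.items()
                }}


def evaluate_predictions(
    cands: Sequence[Candidate],
    scores: np.ndarray,
    golds: Sequence[GoldRecord],
    name: str = "model",
    tol: float = 0.0,
    ci: str = "wald",
) -> EvalReport:
    """Evaluate candidate scores at segment and document level.

    ``golds`` defines the test documents: every gold report counts in the
    document-accuracy denominator even if no candidate was recovered.
    """
    scores = np.asarray(scores, dtype=float)
    if len(cands) != len(scores):
        raise ValueError("candidate/score length mismatch")
    pred = [CLASS_ORDER[int(i)] for i in np.argmax(scores, axis=1)] if len(cands) else []
    true = [c.label for c in cands]

    by_report: dict[str, list[int]] = {}
    for i, c in enumerate(cands):
        by_report.setdefault(c.report_id, []).append(i)

    ci_fn = wald_ci if ci == "wald" else wilson_ci
    report = EvalReport(name=name, n_segments=len(cands), n_documents=len(golds))
    for target, gold_attr in ((Label.AHI, "ahi"), (Label.SAO2, "sao2")):
        col = CLASS_ORDER.index(target)
        recall, precision, f1 = segment_metrics(pred, true, target)
        truth_bin = np.array([t == target for t in true])
        try:
            auc = auroc(scores[:, col], truth_bin)
        except ValueError:
            auc = float("nan")
        flags = []
        for g in golds:
            idx = by_report.get(g.report_id, [])
            _, ok = extract_document(
                [cands[i] for i in idx], scores[idx] if idx else np.zeros((0, 3)),
                target, getattr(g, gold_attr), tol,
            )
            flags.append(ok)
        acc = document_accuracy(flags)
        report.per_class[target.value] = {
            "recall": recall,
            "precision": precision,
            "f1": f1,
            "auroc": auc,
            "doc_accuracy": acc,
            "doc_accuracy_ci": ci_fn(acc, len(flags)),
            "doc_flags": tuple(flags),
        }
    return report


# ---------------------------------------------------------------------------
# experiment matrices


def run_experiment(
    matrix: str,
    reports,
    golds: Sequence[GoldRecord],
    seed: int = 0,
    config: Mapping | None = None,
) -> list[EvalReport]:
    """Run one of the experiment designs on a segmented synthetic corpus.

    ``matrix`` is "models" (7 bag-of-words + 3 sequence networks),
    "prep_methods" (the 6 image-preprocessing methods) or "train_sizes"
    (training subsets of 10/25/50/100 reports). Returns one EvalReport
    per cell. ``config`` tunes problem sizes (epochs, network widths) so
    the matrices run at desk scale; any cell failure propagates with the
    cell named.
    """
    from sleepscan import experiments

    cfg = dict(config or {})
    if matrix == "models":
        return experiments.classifier_matrix(reports, golds, seed, **cfg)
    if matrix == "prep_methods":
        return experiments.preprocessing_matrix(reports, golds, seed, **cfg)
    if matrix == "train_sizes":
        return experiments.training_size_curve(reports, golds, seed, **cfg)
    raise ValueError(f"unknown experiment matrix {matrix!r}")
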