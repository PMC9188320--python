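"""Experiment designs: classifier grid, preprocessing grid, training-size curve.

Each matrix runs on a synthetic corpus at desk scale: problem sizes
(report counts, network widths, epochs) default to values that complete
on a single CPU in minutes while preserving the design's structure —
one evaluation cell per classifier, per preprocessing method, or per
training-subset size.
"""

from __future__ import annotations

from typing import Mapping, Sequence

import numpy as np

from sleepscan import bow as bowmod
from sleepscan.evalstats import (
    EvalReport,
    PairwiseComparison,
    bonferroni,
    chi2_compare,
    delong,
    evaluate_predictions,
)
from sleepscan.imageprep import PrepMethod, apply_method
from sleepscan.segmenter import (
    CLASS_ORDER,
    Candidate,
    Label,
    assign_labels,
    extract_candidates,
    split_documents,
    subsample_training,
)
from sleepscan.synth import GoldRecord, SynthReport, measure_noise_removal, render_page

__all__ = [
    "segment_corpus",
    "train_eval_bow",
    "train_eval_seq",
    "classifier_matrix",
    "preprocessing_matrix",
    "training_size_curve",
    "pairwise_comparisons",
]


def segment_corpus(
    reports: Sequence[SynthReport],
    golds: Sequence[GoldRecord],
    tol: float = 0.0,
    words_by_report: Mapping[str, list] | None = None,
) -> dict[str, list[Candidate]]:
    """Segment every report into labeled candidates (report_id -> candidates)."""
    gold_by_id = {g.report_id: g for g in golds}
    out: dict[str, list[Candidate]] = {}
    for r in reports:
        words = words_by_report[r.report_id] if words_by_report else r.ocr_words
        cands = extract_candidates(words, r.report_id)
        out[r.report_id] = assign_labels(cands, gold_by_id[r.report_id], tol)
    return out


def _gather(cands_by_report: Mapping[str, list[Candidate]], ids: Sequence[str]) -> list[Candidate]:
    return [c for rid in ids for c in cands_by_report[rid]]


def train_eval_bow(
    clf: "bowmod.BowClassifier",
    train_cands: Sequence[Candidate],
    test_cands: Sequence[Candidate],
    test_golds: Sequence[GoldRecord],
    seed: int = 0,
    params: Mapping | None = None,
    name: str | None = None,
) -> tuple[EvalReport, np.ndarray]:
    """Fit one bag-of-words classifier and evaluate on the test candidates."""
    vocab = bowmod.build_vocab([c.window for c in train_cands])
    X_tr = bowmod.featurize_batch(train_cands, vocab)
    model = bowmod.train_bow(X_tr, [c.label for c in train_cands], clf, vocab, params, seed)
    scores = model.predict_proba(list(test_cands))
    report = evaluate_predictions(test_cands, scores, test_golds, name=name or clf.value)
    return report, scores


def train_eval_seq(
    train_cands: Sequence[Candidate],
    val_cands: Sequence[Candidate],
    test_cands: Sequence[Candidate],
    test_golds: Sequence[GoldRecord],
    spec=None,
    seed: int = 0,
    epochs: int = 10,
    lr: float | None = None,
    name: str = "seq",
    cbow_max_windows: int = 1500,
) -> tuple[EvalReport, np.ndarray]:
    """Train the dual-branch network and evaluate on the test candidates.

    The BiLSTM path pretrains CBOW embeddings on (a subsample of) the
    training windows; the transformer path trains its own embeddings.
    """
    from sleepscan.nn import (
        DualBranchNet,
        Encoder,
        NetworkSpec,
        TrainConfig,
        build_token_vocab,
        train_cbow,
        train_seq,
    )
    from sleepscan.nn.embeddings import embedding_matrix
    from sleepscan.nn.train import make_dataset, predict_proba

    spec = spec or NetworkSpec()
    train_windows = [c.window for c in train_cands]
    vocab = build_token_vocab(train_windows)
    pretrained = None
    if spec.encoder is Encoder.BILSTM:
        rng = np.random.default_rng(seed)
        windows = train_windows
        if len(windows) > cbow_max_windows:
            pick = rng.choice(len(windows), size=cbow_max_windows, replace=False)
            windows = [windows[i] for i in pick]
        vectors = train_cbow(windows, dim=spec.emb_dim, seed=seed)
        pretrained = embedding_matrix(vocab, vectors, spec.emb_dim)

    net = DualBranchNet(spec, n_vocab=len(vocab) + 2, seed=seed, pretrained_emb=pretrained)
    cfg = TrainConfig(epochs=epochs, lr=lr, seed=seed)
    tr = make_dataset(train_cands, vocab, spec.max_len)
    va = make_dataset(val_cands, vocab, spec.max_len)
    te = make_dataset(test_cands, vocab, spec.max_len)
    trained = train_seq(net, tr, va, cfg, vocab)
    scores = predict_proba(trained.net, te)
    report = evaluate_predictions(test_cands, scores, test_golds, name=name)
    return report, scores


def classifier_matrix(
    reports: Sequence[SynthReport],
    golds: Sequence[GoldRecord],
    seed: int = 0,
    epochs: int = 8,
    seq_specs: Mapping | None = None,
    bow_models: Sequence | None = None,
) -> list[EvalReport]:
    """The 10-cell classifier grid: 7 bag-of-words + 3 sequence networks."""
    from sleepscan.nn import Encoder, NetworkSpec

    cands_by_report = segment_corpus(reports, golds)
    plan = split_documents([r.report_id for r in reports], seed)
    gold_by_id = {g.report_id: g for g in golds}
    dev = _gather(cands_by_report, plan.dev_ids)
    train = _gather(cands_by_report, plan.train_ids)
    val = _gather(cands_by_report, plan.val_ids)
    test = _gather(cands_by_report, plan.test_ids)
    test_golds = [gold_by_id[rid] for rid in plan.test_ids]

    out: list[EvalReport] = []
    for clf in bow_models if bow_models is not None else list(bowmod.BowClassifier):
        try:
            report, _ = train_eval_bow(clf, dev, test, test_golds, seed)
        except Exception as exc:  # identify the failing cell
            raise RuntimeError(f"classifier matrix cell {clf.value!r} failed") from exc
        out.append(report)

    default_seq = {
        "BiLSTM": NetworkSpec(encoder=Encoder.BILSTM, emb_dim=50, lstm_hidden=32,
                              ffnn_struct=50, ffnn_seq=50, ffnn_head=100),
        "Transformer": NetworkSpec(encoder=Encoder.TRANSFORMER, tf_dim=32, tf_layers=2,
                                   ffnn_struct=50, ffnn_seq=50, ffnn_head=100),
        "Transformer-L": NetworkSpec(encoder=Encoder.TRANSFORMER, tf_dim=48, tf_layers=3,
                                     ffnn_struct=50, ffnn_seq=50, ffnn_head=100),
    }
    for name, spec in (seq_specs or default_seq).items():
        try:
            report, _ = train_eval_seq(train, val, test, test_golds, spec=spec, seed=seed,
                                       epochs=epochs, lr=2e-3, name=name)
        except Exception as exc:
            raise RuntimeError(f"classifier matrix cell {name!r} failed") from exc
        out.append(report)
    return out


def preprocessing_matrix(
    reports: Sequence[SynthReport],
    golds: Sequence[GoldRecord],
    seed: int = 0,
    n_sample_pages: int = 4,
    noise_density: float = 2e-4,
    base_char_error: float = 0.05,
    clf=None,
) -> list[EvalReport]:
    """The 6-cell image-preprocessing grid.

    For each method, a sample of pages is rendered with speckle noise and
    preprocessed; the measured residual-noise fraction scales the
    character-confusion rate of the OCR simulation for the whole corpus
    (worse speckle suppression -> more misread characters), and a
    bag-of-words classifier is evaluated downstream. The image-quality
    measurements ride along on each report.
    """
    from sleepscan.ocr import inject_ocr_noise

    clf = clf or bowmod.BowClassifier.RF
    sample = reports[: max(1, n_sample_pages)]
    out: list[EvalReport] = []
    gold_by_id = {g.report_id: g for g in golds}
    plan = split_documents([r.report_id for r in reports], seed)
    test_golds = [gold_by_id[rid] for rid in plan.test_ids]

    for method in PrepMethod:
        fracs, preserved, total_words = [], 0, 0
        for r in sample:
            img, noise_mask = render_page(r.report_id, 1, r.page_plans[0],
                                          noise_density=noise_density, seed=seed)
            processed = apply_method(img, method)
            m = measure_noise_removal(processed, img, noise_mask, r.page_plans[0])
            fracs.append(m["frac_noise_removed"])
            preserved += m["n_words_connectivity_preserved"]
            total_words += m["n_words"]
        frac_removed = float(np.mean(fracs))
        rate = base_char_error * (1.0 - frac_removed)

        noisy_words = {
            r.report_id: inject_ocr_noise(r.ocr_words, rate, seed=(seed * 977 + 13) % 2**31)
            for r in reports
        }
        cands_by_report = segment_corpus(reports, golds, words_by_report=noisy_words)
        dev = _gather(cands_by_report, plan.dev_ids)
        test = _gather(cands_by_report, plan.test_ids)
        try:
            report, _ = train_eval_bow(clf, dev, test, test_golds, seed, name=method.value)
        except Exception as exc:
            raise RuntimeError(f"preprocessing matrix cell {method.value!r} failed") from exc
        report.per_class["image"] = {
            "frac_noise_removed": frac_removed,
            "char_error_rate": rate,
            "stroke_connectivity_rate": preserved / max(total_words, 1),
        }
        out.append(report)
    return out


def training_size_curve(
    reports: Sequence[SynthReport],
    golds: Sequence[GoldRecord],
    seed: int = 0,
    sizes: Sequence[int] = (10, 25, 50, 100),
    epochs: int = 8,
    spec=None,
) -> list[EvalReport]:
    """Train on subsets of the training reports; one cell per subset size."""
    from sleepscan.nn import Encoder, NetworkSpec

    spec = spec or NetworkSpec(encoder=Encoder.TRANSFORMER, tf_dim=32, tf_layers=2,
                               ffnn_struct=50, ffnn_seq=50, ffnn_head=100)
    cands_by_report = segment_corpus(reports, golds)
    plan = split_documents([r.report_id for r in reports], seed)
    gold_by_id = {g.report_id: g for g in golds}
    subsets = subsample_training(plan.train_ids, sizes, seed)
    val = _gather(cands_by_report, plan.val_ids)
    test = _gather(cands_by_report, plan.test_ids)
    test_golds = [gold_by_id[rid] for rid in plan.test_ids]

    out = []
    for size in sizes:
        train = _gather(cands_by_report, subsets[size])
        try:
            report, _ = train_eval_seq(train, val, test, test_golds, spec=spec, seed=seed,
                                       epochs=epochs, lr=2e-3, name=f"n{size}")
        except Exception as exc:
            raise RuntimeError(f"training-size cell {size} failed") from exc
        out.append(report)
    return out


def pairwise_comparisons(
    results: Mapping[str, tuple[Sequence[Candidate], np.ndarray, EvalReport]],
    ref: str,
    family_size: int | None = None,
) -> list[PairwiseComparison]:
    """Compare a reference model against every other: DeLong on AUROC and
    chi-squared on document accuracy, per target, Bonferroni adjusted.

    ``results`` maps model name -> (test candidates, test scores, report);
    candidates must be identical across models (paired comparisons).
    """
    others = [name for name in results if name != ref]
    comparisons: list[tuple] = []
    cands_ref, scores_ref, report_ref = results[ref]
    for name in others:
        cands_b, scores_b, report_b = results[name]
        if [c.order_idx for c in cands_b] != [c.order_idx for c in cands_ref]:
            raise ValueError(f"model {name!r} scored different candidates than {ref!r}")
        for target in (Label.AHI, Label.SAO2):
            col = CLASS_ORDER.index(target)
            truth = np.array([c.label == target for c in cands_ref])
            res = delong(scores_ref[:, col], scores_b[:, col], truth)
            comparisons.append((ref, name, target.value, "AUROC", res.p))
            fa = report_ref.per_class[target.value]["doc_flags"]
            fb = report_b.per_class[target.value]["doc_flags"]
            _, p = chi2_compare((int(sum(fa)), len(fa)), (int(sum(fb)), len(fb)))
            comparisons.append((ref, name, target.value, "DOC_ACC", p))
    m = family_size if family_size is not None else len(comparisons)
    adjusted = bonferroni([c[4] for c in comparisons], m)
    return [
        PairwiseComparison(model_a=a, model_b=b, target=t, metric=met,
                           raw_p=p, adjusted_p=ap, family_size=m)
        for (a, b, t, met, p), ap in zip(comparisons, adjusted)
    ]
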