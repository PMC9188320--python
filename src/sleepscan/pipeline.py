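"""End-to-end pipeline orchestration with file artifacts and provenance.

Stages run in fixed order — synth/ingest -> (preprocess -> ocr) -> deid
-> segment -> train -> evaluate — and every artifact directory carries a
provenance block (config hash, seed, per-stage timings). Intermediate
artifacts (word TSVs, segments CSV, predictions CSV) are always written
so each stage can be re-run independently; deterministic stages are
bit-identical under the same configuration.
"""

from __future__ import annotations

import csv
import dataclasses
import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

from sleepscan import bow as bowmod
from sleepscan import deid as deidmod
from sleepscan.experiments import _gather, segment_corpus, train_eval_bow, train_eval_seq
from sleepscan.ocr import inject_ocr_noise, parse_ocr_tsv, write_ocr_tsv
from sleepscan.segmenter import split_documents, write_segments_csv
from sleepscan.synth import CorpusSpec, GoldRecord, SynthReport, generate_corpus, phi_lookup

__all__ = ["PipelineConfig", "run_pipeline", "save_corpus", "load_corpus"]


@dataclass(frozen=True)
class PipelineConfig:
    """Structured configuration for a full pipeline run."""

    outdir: str
    seed: int = 0
    n_reports: int = 50
    ocr_backend: str = "perfect"        # perfect | perfect-noise
    ocr_noise_rate: float = 0.02
    deidentify: bool = True
    label_tol: float = 0.0
    model: str = "RF"                   # bow enum name, or "bilstm"/"transformer"
    epochs: int = 8
    no_structured: bool = False
    corpus_overrides: dict = field(default_factory=dict)

    @staticmethod
    def from_yaml(path: str | Path) -> "PipelineConfig":
        import yaml

        with open(path, encoding="utf-8") as fh:
            raw = yaml.safe_load(fh) or {}
        return PipelineConfig(**raw)

    def config_hash(self) -> str:
        blob = json.dumps(dataclasses.asdict(self), sort_keys=True).encode()
        return hashlib.sha256(blob).hexdigest()[:16]


def save_corpus(reports: Sequence[SynthReport], golds: Sequence[GoldRecord], outdir: str | Path) -> None:
    """Write gold.csv, phi.csv and per-report OCR word TSVs."""
    out = Path(outdir)
    (out / "words").mkdir(parents=True, exist_ok=True)
    with open(out / "gold.csv", "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["report_id", "ahi", "sao2"])
        for g in golds:
            writer.writerow([g.report_id, g.ahi, g.sao2])
    deidmod.write_phi_csv(phi_lookup(reports), out / "phi.csv")
    for r in reports:
        write_ocr_tsv(r.ocr_words, out / "words" / f"{r.report_id}.tsv")


def load_corpus(indir: str | Path) -> tuple[list[SynthReport], list[GoldRecord]]:
    """Load a saved corpus (word tables + gold values; page plans not kept)."""
    ind = Path(indir)
    golds = []
    with open(ind / "gold.csv", newline="", encoding="utf-8") as fh:
        for row in csv.DictReader(fh):
            golds.append(GoldRecord(report_id=row["report_id"], ahi=float(row["ahi"]),
                                    sao2=float(row["sao2"])))
    phi = deidmod.read_phi_csv(ind / "phi.csv") if (ind / "phi.csv").exists() else {}
    reports = []
    for g in golds:
        words = parse_ocr_tsv(ind / "words" / f"{g.report_id}.tsv")
        name, mrn = phi.get(g.report_id, ("", ""))
        reports.append(SynthReport(report_id=g.report_id, page_plans=[], ocr_words=words,
                                   patient_name=name, mrn=mrn))
    return reports, golds


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Execute all stages; returns the provenance block (also written to disk)."""
    out = Path(cfg.outdir)
    out.mkdir(parents=True, exist_ok=True)
    timings: dict[str, float] = {}
    provenance = {"config": dataclasses.asdict(cfg), "config_hash": cfg.config_hash(),
                  "seed": cfg.seed}

    def stage(name):
        def deco(fn):
            t0 = time.perf_counter()
            try:
                result = fn()
            except Exception as exc:
                raise RuntimeError(f"pipeline stage {name!r} failed: {exc}") from exc
            timings[name] = round(time.perf_counter() - t0, 3)
            return result
        return deco

    spec = CorpusSpec(n_reports=cfg.n_reports, seed=cfg.seed, **cfg.corpus_overrides)
    reports, golds = stage("synth")(lambda: generate_corpus(spec))

    def ocr_stage():
        if cfg.ocr_backend == "perfect":
            return {r.report_id: r.ocr_words for r in reports}
        if cfg.ocr_backend == "perfect-noise":
            return {
                r.report_id: inject_ocr_noise(
                    r.ocr_words, cfg.ocr_noise_rate, (cfg.seed * 7919 + i) % 2**31
                )
                for i, r in enumerate(reports)
            }
        raise ValueError(f"unknown ocr backend {cfg.ocr_backend!r}")

    words_by_report = stage("ocr")(ocr_stage)

    def deid_stage():
        if not cfg.deidentify:
            return words_by_report
        lookup = phi_lookup(reports)
        return {
            rid: deidmod.deidentify(ws, lookup, rid) for rid, ws in words_by_report.items()
        }

    words_by_report2 = stage("deid")(deid_stage)
    save_corpus(
        [dataclasses.replace(r, ocr_words=words_by_report2[r.report_id]) for r in reports],
        golds, out / "corpus",
    )

    cands_by_report = stage("segment")(
        lambda: segment_corpus(reports, golds, cfg.label_tol, words_by_report2)
    )
    write_segments_csv([c for cs in cands_by_report.values() for c in cs], out / "segments.csv")

    plan = split_documents([r.report_id for r in reports], cfg.seed)
    gold_by_id = {g.report_id: g for g in golds}
    test = _gather(cands_by_report, plan.test_ids)
    test_golds = [gold_by_id[rid] for rid in plan.test_ids]

    def train_stage():
        if cfg.model.lower() in ("bilstm", "transformer"):
            from sleepscan.nn import Encoder, NetworkSpec

            spec_net = NetworkSpec(
                encoder=Encoder.BILSTM if cfg.model.lower() == "bilstm" else Encoder.TRANSFORMER,
                use_structured=not cfg.no_structured,
                emb_dim=50, lstm_hidden=32, tf_dim=32,
                ffnn_struct=50, ffnn_seq=50, ffnn_head=100,
            )
            return train_eval_seq(
                _gather(cands_by_report, plan.train_ids),
                _gather(cands_by_report, plan.val_ids),
                test, test_golds, spec=spec_net, seed=cfg.seed, epochs=cfg.epochs,
                lr=2e-3, name=cfg.model,
            )
        clf = bowmod.BowClassifier[cfg.model.upper()]
        return train_eval_bow(
            clf, _gather(cands_by_report, plan.dev_ids), test, test_golds, cfg.seed
        )

    report, scores = stage("train")(train_stage)

    with open(out / "predictions.csv", "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["report_id", "order_idx", "p_ahi", "p_sao2", "p_other"])
        for c, s in zip(test, scores):
            writer.writerow([c.report_id, c.order_idx, *(f"{v:.6f}" for v in s)])

    def eval_stage():
        d = report.as_dict()
        d.pop("AHI_doc_flags", None)
        d.pop("SaO2_doc_flags", None)
        for k, v in list(d.items()):
            if isinstance(v, tuple):
                d[k] = list(v)
        return d

    metrics = stage("evaluate")(eval_stage)
    with open(out / "metrics.json", "w", encoding="utf-8") as fh:
        json.dump(metrics, fh, indent=2)

    provenance["timings"] = timings
    provenance["split"] = {
        "train": len(plan.train_ids), "val": len(plan.val_ids), "test": len(plan.test_ids)
    }
    with open(out / "provenance.json", "w", encoding="utf-8") as fh:
        json.dump(provenance, fh, indent=2)
    return provenance
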