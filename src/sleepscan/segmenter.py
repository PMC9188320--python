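"""Numeric-candidate segmentation and document-level splitting.

Candidate words are those whose entire text matches ``[0-9.,%]+`` and
parse to a finite number. Each candidate carries a context window of up
to 10 words on each side (21 words total, crossing page boundaries in
reading order but never report boundaries) plus six structured layout
features: the bounding box (left, top, width, height), the page number,
and the parsed value.

Labels are assigned by matching each candidate's parsed value against the
report's recorded gold AHI and SaO2 (AHI takes precedence on the rare
dual match). Splits are always at the report level: 70% development /
30% test (half-up rounding), with the development set further divided
6:1 into training and validation (validation = floor(dev / 7)).
"""

from __future__ import annotations

import csv
import enum
import re
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from sleepscan.ocr import OCRWord
from sleepscan.synth import GoldRecord

__all__ = [
    "Label",
    "Candidate",
    "SplitPlan",
    "CANDIDATE_RE",
    "WINDOW_HALF",
    "WINDOW_LEN",
    "find_candidates",
    "parse_numeric",
    "build_window",
    "extract_candidates",
    "assign_labels",
    "split_documents",
    "subsample_training",
    "write_segments_csv",
    "read_segments_csv",
]

CANDIDATE_RE = re.compile(r"[0-9.,%]+")

#: Context words taken on each side of a candidate; total window = 21.
WINDOW_HALF = 10
WINDOW_LEN = 2 * WINDOW_HALF + 1

_THOUSANDS_RE = re.compile(r"^\d{1,3}(,\d{3})+(\.\d*)?$")


class Label(enum.Enum):
    AHI = "AHI"
    SAO2 = "SaO2"
    OTHER = "Other"


#: Canonical class order for probability columns everywhere downstream.
CLASS_ORDER = (Label.AHI, Label.SAO2, Label.OTHER)


@dataclass(frozen=True)
class Candidate:
    """A numeric token with context window, layout features, and label."""

    report_id: str
    token: str
    value: float
    left: int
    top: int
    width: int
    height: int
    page_num: int
    order_idx: int
    window: tuple[str, ...]
    label: Label = Label.OTHER

    @property
    def structured(self) -> tuple[float, ...]:
        """The 6 structured features: 4 position indicators, page, value."""
        return (
            float(self.left),
            float(self.top),
            float(self.width),
            float(self.height),
            float(self.page_num),
            float(self.value),
        )


@dataclass(frozen=True)
class SplitPlan:
    """Report-level train/validation/test identifiers."""

    train_ids: tuple[str, ...]
    val_ids: tuple[str, ...]
    test_ids: tuple[str, ...]
    seed: int

    @property
    def dev_ids(self) -> tuple[str, ...]:
        return self.train_ids + self.val_ids


def parse_numeric(token: str) -> float | None:
    """Parse a candidate token to a float, or None if nothing parseable.

    Strips percent signs and trailing periods/commas; commas between
    digit triplets are treated as thousands separators.
    """
    t = token.replace("%", "")
    t = t.rstrip(".,")
    if _THOUSANDS_RE.match(t):
        t = t.replace(",", "")
    if not any(c.isdigit() for c in t):
        return None
    try:
        v = float(t)
    except ValueError:
        return None
    return v if np.isfinite(v) else None


def find_candidates(words: Sequence[OCRWord]) -> list[tuple[int, str]]:
    """Indices and tokens of words fully matching the candidate pattern.

    Tokens that parse to no finite number (pure punctuation like "%" or
    ".,") are excluded after the parse attempt.
    """
    out = []
    for i, w in enumerate(words):
        if CANDIDATE_RE.fullmatch(w.text) and parse_numeric(w.text) is not None:
            out.append((i, w.text))
    return out


def build_window(words: Sequence[OCRWord], idx: int, half: int = WINDOW_HALF) -> tuple[str, ...]:
    """Up to ``half`` words each side of ``idx``, truncated at report bounds."""
    if not 0 <= idx < len(words):
        raise IndexError(f"candidate index {idx} out of range")
    lo = max(0, idx - half)
    hi = min(len(words), idx + half + 1)
    return tuple(w.text for w in words[lo:hi])


def extract_candidates(
    words: Sequence[OCRWord], report_id: str, half: int = WINDOW_HALF
) -> list[Candidate]:
    """Segment one report's word sequence into unlabeled candidates.

    ``words`` must be the full report in reading order (windows cross
    page boundaries).
    """
    out = []
    for idx, token in find_candidates(words):
        w = words[idx]
        value = parse_numeric(token)
        assert value is not None
        out.append(
            Candidate(
                report_id=report_id,
                token=token,
                value=value,
                left=w.left,
                top=w.top,
                width=w.width,
                height=w.height,
                page_num=w.page_num,
                order_idx=w.order_idx,
                window=build_window(words, idx, half),
            )
        )
    return out


def assign_labels(
    cands: Sequence[Candidate], gold: GoldRecord, tol: float = 0.0
) -> list[Candidate]:
    """Label candidates by value match against the gold record.

    |value - ahi| <= tol -> AHI; else |value - sao2| <= tol -> SaO2;
    else Other. AHI takes precedence when both match (documented
    tie-break; such collisions are suppressed in the default synthetic
    corpus anyway).
    """
    out = []
    for c in cands:
        if abs(c.value - gold.ahi) <= tol:
            lab = Label.AHI
        elif abs(c.value - gold.sao2) <= tol:
            lab = Label.SAO2
        else:
            lab = Label.OTHER
        out.append(replace(c, label=lab))
    return out


def split_documents(report_ids: Sequence[str], seed: int) -> SplitPlan:
    """70/30 development/test split, then 6:1 train/validation within dev.

    Rounding: development = half-up-round(0.7 N); validation =
    floor(dev / 7); train = dev - validation. For N = 955 this yields
    dev 669 / test 286 and train 574 / validation 95.
    """
    ids = list(report_ids)
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate report ids")
    n = len(ids)
    if n < 10:
        raise ValueError(f"need >= 10 reports to split, got {n}")
    n_dev = int(np.floor(0.7 * n + 0.5))  # half-up
    n_val = n_dev // 7
    rng = np.random.default_rng(seed)
    perm = [ids[i] for i in rng.permutation(n)]
    dev, test = perm[:n_dev], perm[n_dev:]
    val, train = dev[:n_val], dev[n_val:]
    return SplitPlan(train_ids=tuple(train), val_ids=tuple(val), test_ids=tuple(test), seed=seed)


def subsample_training(
    train_ids: Sequence[str], sizes: Iterable[int] = (10, 25, 50, 100), seed: int = 0
) -> dict[int, tuple[str, ...]]:
    """Independent seeded subsets of the training reports, one per size."""
    ids = list(train_ids)
    rng = np.random.default_rng(seed)
    out: dict[int, tuple[str, ...]] = {}
    for size in sizes:
        if size > len(ids):
            raise ValueError(f"subset size {size} exceeds training set size {len(ids)}")
        pick = rng.choice(len(ids), size=size, replace=False)
        out[size] = tuple(ids[i] for i in sorted(pick))
    return out


# ---------------------------------------------------------------------------
# Segments CSV (mirrors the analytical-table layout:
# left, top, width, height, page, value, segment, label, report_id)

_CSV_FIELDS = ["left", "top", "width", "height", "page", "value", "segment", "label", "report_id"]


def write_segments_csv(cands: Sequence[Candidate], path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(_CSV_FIELDS)
        for c in cands:
            writer.writerow(
                [c.left, c.top, c.width, c.height, c.page_num, c.value,
                 " ".join(c.window), c.label.value, c.report_id]
            )


def read_segments_csv(path: str | Path) -> list[Candidate]:
    out = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != _CSV_FIELDS:
            raise ValueError(f"bad segments CSV header: {reader.fieldnames}")
        for i, row in enumerate(reader):
            window = tuple(row["segment"].split(" "))
            token = next(
                (t for t in window if CANDIDATE_RE.fullmatch(t)
                 and parse_numeric(t) == float(row["value"])),
                "",
            )
            out.append(
                Candidate(
                    report_id=row["report_id"],
                    token=token or row["value"],
                    value=float(row["value"]),
                    left=int(row["left"]),
                    top=int(row["top"]),
                    width=int(row["width"]),
                    height=int(row["height"]),
                    page_num=int(row["page"]),
                    order_idx=i,
                    window=window,
                    label=Label(row["label"]),
                )
            )
    return out
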