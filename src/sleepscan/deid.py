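"""Deidentification of OCR word tables.

Patient names and medical record numbers are masked against a lookup
table (report id -> name, MRN) with per-token case-insensitive exact
matching; any word shaped like a date (1-2 digit day/month, 2- or
4-digit year, slash-separated) is masked unconditionally. Masking
replaces only the word text — counts, order, and bounding boxes are
untouched — and is idempotent. The placeholders contain no characters
from the numeric-candidate class, so masked words can never become
extraction candidates downstream.
"""

from __future__ import annotations

import csv
import re
from dataclasses import replace
from pathlib import Path
from typing import Mapping, Sequence

from sleepscan.ocr import OCRWord

__all__ = [
    "PhiLookup",
    "mask_phi",
    "mask_dates",
    "deidentify",
    "read_phi_csv",
    "write_phi_csv",
    "PATNAME_TOKEN",
    "MRN_TOKEN",
    "DATE_TOKEN",
]

PATNAME_TOKEN = "[PATNAME]"
MRN_TOKEN = "[MRN]"
DATE_TOKEN = "[DATE]"

_DATE_RE = re.compile(r"\d{1,2}/\d{1,2}/(\d{4}|\d{2})")

#: report_id -> (patient_name, mrn)
PhiLookup = Mapping[str, tuple[str, str]]


def _validate(lookup: PhiLookup) -> None:
    for rid, (name, mrn) in lookup.items():
        if not name or not mrn:
            raise ValueError(f"report {rid!r}: name and MRN must be nonempty")


def mask_phi(words: Sequence[OCRWord], lookup: PhiLookup, report_id: str) -> list[OCRWord]:
    """Mask name tokens and the MRN of ``report_id`` in the word sequence.

    Fails closed: an unknown report id is an error rather than a silent
    pass-through of identified text.
    """
    if report_id not in lookup:
        raise KeyError(f"report {report_id!r} missing from PHI lookup table")
    _validate({report_id: lookup[report_id]})
    name, mrn = lookup[report_id]
    name_tokens = {t.lower() for t in name.split()}
    mrn_lower = mrn.lower()
    out = []
    for w in words:
        t = w.text.lower()
        if t in name_tokens:
            out.append(replace(w, text=PATNAME_TOKEN))
        elif t == mrn_lower:
            out.append(replace(w, text=MRN_TOKEN))
        else:
            out.append(w)
    return out


def mask_dates(words: Sequence[OCRWord]) -> list[OCRWord]:
    """Replace words fully matching a slash date (e.g. 12/03/2017, 3/4/18)."""
    return [
        replace(w, text=DATE_TOKEN) if _DATE_RE.fullmatch(w.text) else w for w in words
    ]


def deidentify(words: Sequence[OCRWord], lookup: PhiLookup, report_id: str) -> list[OCRWord]:
    """Full deidentification pass: names + MRN, then dates."""
    return mask_dates(mask_phi(words, lookup, report_id))


def read_phi_csv(path: str | Path) -> dict[str, tuple[str, str]]:
    """Read a PHI lookup CSV with header report_id,name,mrn."""
    out: dict[str, tuple[str, str]] = {}
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh)
        if reader.fieldnames != ["report_id", "name", "mrn"]:
            raise ValueError(f"bad PHI CSV header: {reader.fieldnames}")
        for row in reader:
            rid = row["report_id"]
            if rid in out:
                raise ValueError(f"duplicate report_id {rid!r} in PHI table")
            out[rid] = (row["name"], row["mrn"])
    _validate(out)
    return out


def write_phi_csv(lookup: PhiLookup, path: str | Path) -> None:
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["report_id", "name", "mrn"])
        for rid, (name, mrn) in lookup.items():
            writer.writerow([rid, name, mrn])
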