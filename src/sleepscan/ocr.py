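"""Word-level OCR adapter layer.

The pipeline consumes words with pixel bounding boxes, independent of any
particular OCR engine. Three backends are provided:

* ``TesseractBackend`` — adapter to an external Tesseract install (word-level
  TSV output). It fails with an explicit environment error when the engine
  is absent.
* ``PerfectOCRBackend`` — a synthetic backend that recovers exactly the
  words planted by the synthetic report generator (text, bbox, page). This
  decouples the NLP stages from any installed engine.
* ``NoisyOCRBackend`` — wraps another backend and injects seeded
  character-confusion errors (e.g. "I" read as "!" or ")"), emulating
  typical scan-quality OCR mistakes.

The canonical interchange format is a TSV with header
``page_num  left  top  width  height  conf  text`` (top-left pixel origin,
y increasing downward).
"""

from __future__ import annotations

import io
import shutil
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np

from sleepscan.imageprep import PageImage

__all__ = [
    "OCRWord",
    "PlannedWord",
    "OCREngineError",
    "PerfectOCRBackend",
    "NoisyOCRBackend",
    "TesseractBackend",
    "run_ocr",
    "parse_ocr_tsv",
    "write_ocr_tsv",
    "parse_tesseract_tsv",
    "inject_ocr_noise",
    "draw_overlay",
    "assign_reading_order",
    "DEFAULT_CONFUSION_TABLE",
]

TSV_HEADER = ["page_num", "left", "top", "width", "height", "conf", "text"]

#: Character confusions observed in real scanned-report OCR output.
DEFAULT_CONFUSION_TABLE: dict[str, Sequence[str]] = {
    "I": ("!", ")"),
    "l": ("1",),
    "O": ("0",),
    "S": ("5",),
}


class OCREngineError(RuntimeError):
    """Raised when the requested external OCR engine is unavailable."""


@dataclass(frozen=True)
class OCRWord:
    """A recognized word with its pixel bounding box.

    ``left``/``top`` are the top-left corner of the word region; ``conf``
    is the engine confidence in [0, 100] (synthetic backends report 100).
    ``order_idx`` is the 0-based reading-order index within the report.
    """

    text: str
    conf: float
    left: int
    top: int
    width: int
    height: int
    page_num: int
    order_idx: int

    def __post_init__(self) -> None:
        if self.width <= 0 or self.height <= 0:
            raise ValueError(f"word bbox must have positive size, got {self.width}x{self.height}")
        if self.page_num < 1:
            raise ValueError("page_num is 1-based")


@dataclass(frozen=True)
class PlannedWord:
    """A word the synthetic generator placed on a page (ground truth for OCR)."""

    text: str
    left: int
    top: int
    width: int
    height: int
    role: str = "prose"


class PerfectOCRBackend:
    """Recover exactly the planted words of a synthetic page.

    ``plans`` maps ``(report_id, page_num)`` to the planted word sequence in
    reading order.
    """

    name = "perfect"

    def __init__(self, plans: Mapping[tuple[str, int], Sequence[PlannedWord]]):
        self._plans = dict(plans)

    def recognize(self, img: PageImage) -> list[OCRWord]:
        planned = self._plans.get((img.report_id, img.page_num), ())
        out = []
        for i, w in enumerate(planned):
            if not w.text.strip():
                continue
            out.append(
                OCRWord(
                    text=w.text,
                    conf=100.0,
                    left=w.left,
                    top=w.top,
                    width=w.width,
                    height=w.height,
                    page_num=img.page_num,
                    order_idx=i,
                )
            )
        return out


class NoisyOCRBackend:
    """Wrap a backend and corrupt its output with seeded character confusions."""

    name = "perfect-noise"

    def __init__(self, inner, rate: float, seed: int, table: Mapping[str, Sequence[str]] | None = None):
        self.inner = inner
        self.rate = rate
        self.seed = seed
        self.table = dict(table) if table is not None else dict(DEFAULT_CONFUSION_TABLE)

    def recognize(self, img: PageImage) -> list[OCRWord]:
        words = self.inner.recognize(img)
        # derive a per-page seed so pages are independent but reproducible
        page_seed = (self.seed * 1000003 + hash((img.report_id, img.page_num))) % (2**31)
        return inject_ocr_noise(words, self.rate, page_seed, self.table)


class TesseractBackend:
    """Adapter to an external Tesseract engine (word-level TSV output)."""

    name = "tesseract"

    def __init__(self, binary: str = "tesseract"):
        self.binary = binary
        if shutil.which(binary) is None:
            raise OCREngineError(
                f"OCR engine '{binary}' is not installed or not on PATH; "
                "use the 'perfect' or 'perfect-noise' backend, or install Tesseract"
            )

    def recognize(self, img: PageImage) -> list[OCRWord]:  # pragma: no cover - needs engine
        import subprocess
        import tempfile

        from PIL import Image

        with tempfile.TemporaryDirectory() as td:
            png = Path(td) / "page.png"
            Image.fromarray(img.pixels).save(png)
            proc = subprocess.run(
                [self.binary, str(png), "stdout", "tsv"],
                capture_output=True,
                text=True,
                check=True,
            )
        return parse_tesseract_tsv(io.StringIO(proc.stdout), page_num=img.page_num)


def run_ocr(img: PageImage, backend) -> list[OCRWord]:
    """Run a backend on one page; drop empty/whitespace tokens, check bboxes."""
    words = [w for w in backend.recognize(img) if w.text.strip()]
    h, wd = img.pixels.shape[:2]
    for w in words:
        if w.left < 0 or w.top < 0 or w.left + w.width > wd or w.top + w.height > h:
            raise ValueError(f"word {w.text!r} bbox outside page bounds ({wd}x{h})")
    return words


def assign_reading_order(words: Iterable[OCRWord]) -> list[OCRWord]:
    """Concatenate pages in page order and re-number order_idx report-wide."""
    ordered = sorted(words, key=lambda w: (w.page_num, w.order_idx))
    return [replace(w, order_idx=i) for i, w in enumerate(ordered)]


def parse_ocr_tsv(stream, conf_floor: float = -1.0) -> list[OCRWord]:
    """Parse the canonical OCR TSV dialect into OCRWords.

    ``order_idx`` is assigned by row order. Rows with conf < ``conf_floor``
    are dropped (default keeps everything).
    """
    if isinstance(stream, (str, Path)):
        with open(stream, encoding="utf-8") as fh:
            return parse_ocr_tsv(fh, conf_floor)
    header = stream.readline().rstrip("\n").split("\t")
    if header != TSV_HEADER:
        raise ValueError(f"bad OCR TSV header {header!r}; expected {TSV_HEADER!r}")
    out: list[OCRWord] = []
    idx = 0
    for lineno, line in enumerate(stream, start=2):
        if not line.strip():
            continue
        parts = line.rstrip("\n").split("\t")
        if len(parts) != len(TSV_HEADER):
            raise ValueError(f"line {lineno}: expected {len(TSV_HEADER)} fields, got {len(parts)}")
        try:
            page, left, top, width, height = (int(parts[i]) for i in range(5))
            conf = float(parts[5])
        except ValueError as exc:
            raise ValueError(f"line {lineno}: {exc}") from None
        if conf < conf_floor:
            continue
        out.append(
            OCRWord(
                text=parts[6], conf=conf, left=left, top=top,
                width=width, height=height, page_num=page, order_idx=idx,
            )
        )
        idx += 1
    return out


def write_ocr_tsv(words: Iterable[OCRWord], stream) -> None:
    """Write OCRWords in the canonical TSV dialect (inverse of parse_ocr_tsv)."""
    if isinstance(stream, (str, Path)):
        with open(stream, "w", encoding="utf-8") as fh:
            write_ocr_tsv(words, fh)
            return
    stream.write("\t".join(TSV_HEADER) + "\n")
    for w in words:
        stream.write(
            f"{w.page_num}\t{w.left}\t{w.top}\t{w.width}\t{w.height}\t{w.conf}\t{w.text}\n"
        )


def parse_tesseract_tsv(stream, page_num: int = 1, conf_floor: float = -1.0) -> list[OCRWord]:
    """Map Tesseract's native word-level TSV into the canonical dialect.

    Tesseract emits one row per layout element with columns
    level..left,top,width,height,conf,text; word rows are level 5.
    """
    if isinstance(stream, (str, Path)):
        with open(stream, encoding="utf-8") as fh:
            return parse_tesseract_tsv(fh, page_num, conf_floor)
    header = stream.readline().rstrip("\n").split("\t")
    col = {name: i for i, name in enumerate(header)}
    for needed in ("level", "left", "top", "width", "height", "conf", "text"):
        if needed not in col:
            raise ValueError(f"tesseract TSV missing column {needed!r}")
    out: list[OCRWord] = []
    idx = 0
    for line in stream:
        parts = line.rstrip("\n").split("\t")
        if len(parts) < len(header) or parts[col["level"]] != "5":
            continue
        text = parts[col["text"]]
        conf = float(parts[col["conf"]])
        if not text.strip() or conf < conf_floor:
            continue
        out.append(
            OCRWord(
                text=text,
                conf=conf,
                left=int(parts[col["left"]]),
                top=int(parts[col["top"]]),
                width=int(parts[col["width"]]),
                height=int(parts[col["height"]]),
                page_num=page_num,
                order_idx=idx,
            )
        )
        idx += 1
    return out


def inject_ocr_noise(
    words: Sequence[OCRWord],
    rate: float,
    seed: int,
    table: Mapping[str, Sequence[str]] | None = None,
) -> list[OCRWord]:
    """Substitute characters from a confusion table with probability ``rate``.

    Word count, order and bounding boxes are never changed.
    """
    if not 0.0 <= rate <= 1.0:
        raise ValueError("rate must be in [0, 1]")
    table = dict(table) if table is not None else dict(DEFAULT_CONFUSION_TABLE)
    rng = np.random.default_rng(seed)
    out = []
    for w in words:
        chars = []
        for ch in w.text:
            subs = table.get(ch)
            if subs and rng.random() < rate:
                chars.append(subs[int(rng.integers(len(subs)))])
            else:
                chars.append(ch)
        out.append(replace(w, text="".join(chars)))
    return out


def draw_overlay(img: PageImage, words: Sequence[OCRWord], value: int = 0) -> PageImage:
    """Draw a 1-pixel rectangle outline around each word (QA visualisation).

    Pixels outside rectangle perimeters are untouched.
    """
    h, wd = img.pixels.shape[:2]
    out = img.pixels.copy()
    for w in words:
        if w.page_num != img.page_num:
            raise ValueError(f"word {w.text!r} belongs to page {w.page_num}, not {img.page_num}")
        r0, r1 = w.top, w.top + w.height - 1
        c0, c1 = w.left, w.left + w.width - 1
        if r0 < 0 or c0 < 0 or r1 >= h or c1 >= wd:
            raise ValueError(f"word {w.text!r} bbox off-page")
        out[r0, c0 : c1 + 1] = value
        out[r1, c0 : c1 + 1] = value
        out[r0 : r1 + 1, c0] = value
        out[r0 : r1 + 1, c1] = value
    return img.copy_with(out)
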