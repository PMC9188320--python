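"""Synthetic multi-page sleep-study-like reports with known ground truth.

Real polysomnography reports carry protected health information and cannot
be redistributed, so the pipeline is exercised on generated look-alikes.
The generator emulates the reported shape of such a corpus:

* a median of 2 pages per report,
* a median of 44 numeric values per page,
* AHI values from a non-negative truncated normal (mean 34.9, SD 31.3),
* minimum-SaO2 values from a (0, 100]-truncated normal (mean 76.5, SD 15.6),
* 52.8% of reports mention the AHI value more than once, 45.9% the SaO2.

Each report consists of sentence templates in narrative style (the index
sentence, e.g. "The total APNEA/HYPOPNEA INDEX (AHI) was 19.5.", plus
distractor sentences carrying other indices) laid out word by word on a
300-dpi US-Letter page. Every word's bounding box is recorded, so the
corpus can be consumed either directly as OCR word tables (the default,
engine-free path) or rendered to page images for the image-preprocessing
and OCR stages.

By default distractor values that would collide with a gold value are
resampled, so the downstream value-matching label assignment is exact.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from functools import lru_cache
from typing import Sequence

import numpy as np

from sleepscan.imageprep import PageImage
from sleepscan.ocr import OCRWord, PlannedWord, assign_reading_order

__all__ = [
    "CorpusSpec",
    "GoldRecord",
    "SynthReport",
    "CategoricalCount",
    "LognormalCount",
    "TruncNormal",
    "ConfigurationError",
    "LayoutError",
    "generate_corpus",
    "phi_lookup",
    "render_page",
    "corpus_stats",
    "measure_noise_removal",
    "PAGE_SIZE",
]

#: 300 dpi US-Letter page in pixels (width, height).
PAGE_SIZE = (2550, 3300)

_MARGIN = 150
_LINE_HEIGHT = 64
_SPACE_W = 18
_FONT_SIZE = 44
#: Extra outline drawn around glyphs so rendered stroke widths match
#: 300-dpi print (>= 3 px), rather than the thin default vector font.
_STROKE = 2
_BACKGROUND = 235
#: Gold mentions are always placed within the first this-many sentences of
#: their page, which a page layout can always accommodate.
_GOLD_SLOT_CAP = 25


class ConfigurationError(ValueError):
    """Invalid corpus-generator configuration."""


class LayoutError(ValueError):
    """Page layout violation (e.g. overlapping bounding boxes)."""


# ---------------------------------------------------------------------------
# distributions


@dataclass(frozen=True)
class CategoricalCount:
    """Discrete count distribution over ``start, start+1, ...``."""

    probs: tuple
    start: int = 1

    def __post_init__(self):
        p = np.asarray(self.probs, dtype=float)
        if p.ndim != 1 or len(p) == 0 or (p < 0).any() or not math.isclose(p.sum(), 1.0, abs_tol=1e-9):
            raise ConfigurationError(f"probs must be a nonneg vector summing to 1, got {self.probs}")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return self.start + rng.choice(len(self.probs), size=size, p=np.asarray(self.probs, float))


@dataclass(frozen=True)
class LognormalCount:
    """Count distribution: round(lognormal) with the given median, clipped."""

    median: float = 44.0
    sigma: float = 0.35
    lo: int = 8
    hi: int = 120

    def __post_init__(self):
        if self.median <= 0 or self.sigma < 0 or self.lo < 1 or self.hi < self.lo:
            raise ConfigurationError("invalid lognormal count parameters")

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        raw = rng.lognormal(mean=math.log(self.median), sigma=self.sigma, size=size)
        return np.clip(np.rint(raw).astype(int), self.lo, self.hi)


@lru_cache(maxsize=64)
def _solve_truncnorm(mean: float, sd: float, lo: float, hi: float) -> tuple[float, float]:
    """Find underlying (loc, scale) so the truncated law has the target moments.

    Truncating a normal shifts its mean and shrinks its spread, so using
    the target values directly as loc/scale would not reproduce the
    reported sample moments. Solved once per parameter set and cached.
    """
    from scipy import optimize, stats

    def resid(params):
        loc, log_scale = params
        scale = math.exp(log_scale)
        a = (lo - loc) / scale
        b = (hi - loc) / scale
        m, v = stats.truncnorm.stats(a, b, loc=loc, scale=scale, moments="mv")
        return [float(m) - mean, math.sqrt(float(v)) - sd]

    sol, info, ier, msg = optimize.fsolve(
        resid, x0=[mean, math.log(sd)], full_output=True
    )
    if ier != 1 or max(abs(r) for r in resid(sol)) > 1e-6:
        raise ConfigurationError(
            f"cannot realize truncated normal with mean={mean}, sd={sd} on ({lo}, {hi}]: {msg}"
        )
    return float(sol[0]), math.exp(float(sol[1]))


@dataclass(frozen=True)
class TruncNormal:
    """Distribution on (lo, hi] whose *realized* mean and sd match the targets.

    Implemented as a truncated normal whose underlying location/scale are
    solved so that the truncated distribution itself has the requested
    moments (reported corpus statistics are sample moments of the
    observed values, which are necessarily inside the support).
    """

    mean: float
    sd: float
    lo: float
    hi: float

    def __post_init__(self):
        if self.sd <= 0 or self.hi <= self.lo:
            raise ConfigurationError("invalid truncated-normal parameters")
        if not (self.lo < self.mean <= self.hi):
            raise ConfigurationError("target mean must lie inside the support")
        _solve_truncnorm(self.mean, self.sd, self.lo, self.hi)  # fail fast

    def sample(self, rng: np.random.Generator, size: int) -> np.ndarray:
        from scipy import stats

        loc, scale = _solve_truncnorm(self.mean, self.sd, self.lo, self.hi)
        a = (self.lo - loc) / scale
        b = (self.hi - loc) / scale
        u = rng.random(size)
        return stats.truncnorm.ppf(u, a, b, loc=loc, scale=scale)

    def moments(self) -> tuple[float, float]:
        """The realized (mean, sd) — equal to the targets by construction."""
        return self.mean, self.sd


# ---------------------------------------------------------------------------
# templates

AHI_TEMPLATES = (
    "The Medicare scoring rule. The total APNEA/HYPOPNEA INDEX (AHI) was {V}.",
    "The overall apnea hypopnea index (AHI) for the night was {V} events per hour.",
    "An AHI of {V} was recorded during the diagnostic portion of the study.",
    "The AHI was {V}, consistent with the clinical impression.",
)

SAO2_TEMPLATES = (
    "The lowest desaturation was {V}, occurring during REM sleep.",
    "The minimum oxygen saturation recorded overnight was {V}%.",
    "Oxygen saturation reached a nadir of {V} during the study.",
    "The lowest SaO2 observed was {V}.",
)

DISTRACTOR_TEMPLATES = (
    "The respiratory disturbance index (RDI) was {V} for the entire night.",
    "A total of {V} hypopneas met the AASM Version 2 scoring rule.",
    "Total sleep time was {V} minutes with good continuity.",
    "Sleep efficiency was {V}% which is within normal limits.",
    "The arousal index was {V} events per hour of sleep.",
    "The patient also had {V} respiratory event related arousals (RERA).",
    "Mean oxygen saturation was {V}% throughout the recording.",
    "The periodic limb movement index was {V} per hour.",
    "Sleep onset latency was {V} minutes after lights out.",
    "Heart rate averaged {V} beats per minute during sleep.",
    "The snore index was {V} events per hour overnight.",
    "Supine sleep accounted for {V}% of total sleep time.",
)

PROSE_TEMPLATES = (
    "The patient tolerated the study well and slept in the supine position for most of the night.",
    "Interpretation was provided by the attending board certified sleep physician.",
    "Continuous positive airway pressure titration is recommended for further management.",
    "Sleep architecture showed reduced slow wave sleep and fragmented REM periods.",
    "Clinical correlation with daytime symptoms is advised before therapy.",
)

#: Template used when ``positional_labels`` is set: the sentence text is the
#: same for every numeric class, so only layout features separate classes.
_POSITIONAL_TEMPLATE = "The recorded index value for this channel was {V} as noted."

_FIRST_NAMES = ("John", "Mary", "Carlos", "Aisha", "Wei", "Elena", "Samuel", "Priya")
_LAST_NAMES = ("Smith", "Johnson", "Garcia", "Khan", "Chen", "Rossi", "Okafor", "Patel")


# ---------------------------------------------------------------------------
# records


@dataclass(frozen=True)
class CorpusSpec:
    """Configuration of the synthetic corpus generator.

    The defaults are the study conditions the generator emulates; see the
    module docstring. ``render=False`` (default) emits OCR word tables
    directly; ``render=True`` keeps the same plans for later rendering to
    page images.
    """

    n_reports: int = 100
    seed: int = 0
    pages_per_report: CategoricalCount = field(
        default_factory=lambda: CategoricalCount((0.28, 0.34, 0.18, 0.10, 0.06, 0.04))
    )
    numerics_per_page: LognormalCount = field(default_factory=LognormalCount)
    ahi_dist: TruncNormal = field(default_factory=lambda: TruncNormal(34.9, 31.3, 0.0, math.inf))
    sao2_dist: TruncNormal = field(default_factory=lambda: TruncNormal(76.5, 15.6, 0.0, 100.0))
    p_multi_ahi: float = 0.528
    p_multi_sao2: float = 0.459
    suppress_collisions: bool = True
    positional_labels: bool = False
    render: bool = False

    def __post_init__(self):
        if self.n_reports < 1:
            raise ConfigurationError("n_reports must be >= 1")
        for name in ("p_multi_ahi", "p_multi_sao2"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ConfigurationError(f"{name} must be in [0, 1], got {p}")


@dataclass(frozen=True)
class GoldRecord:
    """Ground truth for one report: the gold values and every planted word.

    ``planted_words`` holds (text, page_num, (left, top, width, height),
    role) tuples with role in {"AHI", "SaO2", "distractor", "prose"}.
    """

    report_id: str
    ahi: float
    sao2: float
    planted_words: tuple = ()

    def words_with_role(self, role: str) -> list[tuple]:
        return [w for w in self.planted_words if w[3] == role]


@dataclass
class SynthReport:
    """One generated report: per-page word plans plus the flat OCR table.

    ``patient_name``/``mrn`` are the synthetic identifiers planted in the
    page-1 header; they feed the deidentification lookup table.
    """

    report_id: str
    page_plans: list[list[PlannedWord]]
    ocr_words: list[OCRWord]
    patient_name: str = ""
    mrn: str = ""

    @property
    def n_pages(self) -> int:
        if self.page_plans:
            return len(self.page_plans)
        return max((w.page_num for w in self.ocr_words), default=0)


def phi_lookup(reports: Sequence["SynthReport"]) -> dict[str, tuple[str, str]]:
    """Build the deidentification lookup table (report id -> (name, MRN))."""
    return {r.report_id: (r.patient_name, r.mrn) for r in reports}


# ---------------------------------------------------------------------------
# layout helpers


@lru_cache(maxsize=1)
def _font():
    from PIL import ImageFont

    return ImageFont.load_default(size=_FONT_SIZE)


@lru_cache(maxsize=65536)
def _word_width(text: str) -> int:
    return max(1, int(math.ceil(_font().getlength(text))) + 2 * _STROKE)


def _word_height() -> int:
    ascent, descent = _font().getmetrics()
    return ascent + descent + 2 * _STROKE


def _layout_sentences(sentences: list[list[tuple[str, str]]]) -> list[PlannedWord]:
    """Flow (text, role) tokens onto a page, wrapping at the right margin."""
    page_w, page_h = PAGE_SIZE
    x, y = _MARGIN, _MARGIN
    wh = _word_height()
    out: list[PlannedWord] = []
    for sent in sentences:
        for text, role in sent:
            w = _word_width(text)
            if x + w > page_w - _MARGIN:
                x = _MARGIN
                y += _LINE_HEIGHT
            if y + wh > page_h - _MARGIN:
                # page full: stop placing further words (overflow dropped)
                return out
            out.append(PlannedWord(text=text, left=x, top=y, width=w, height=wh, role=role))
            x += w + _SPACE_W
        # small gap between sentences
        x += _SPACE_W
    return out


def _fill_template(template: str, value_text: str, role: str) -> list[tuple[str, str]]:
    toks = []
    for tok in template.split():
        if "{V}" in tok:
            toks.append((tok.replace("{V}", value_text), role))
        else:
            toks.append((tok, "prose"))
    return toks


def _fmt_value(v: float) -> str:
    """Render a numeric the way reports print them (no trailing .0)."""
    r = round(v, 1)
    return str(int(r)) if r == int(r) else f"{r:.1f}"


# ---------------------------------------------------------------------------
# generation


def _sample_distractor_value(rng: np.random.Generator) -> float:
    kind = rng.random()
    if kind < 0.4:
        return float(int(rng.integers(0, 200)))  # counts, minutes
    if kind < 0.7:
        return round(float(rng.uniform(0, 120)), 1)  # indices with decimals
    return float(int(rng.integers(50, 100)))  # percentages


def _collides(v: float, gold: Sequence[float], tol: float = 0.0) -> bool:
    return any(abs(round(v, 1) - g) <= tol for g in gold)


def generate_corpus(spec: CorpusSpec) -> tuple[list[SynthReport], list[GoldRecord]]:
    """Generate ``spec.n_reports`` synthetic reports with gold records.

    Deterministic for a given spec (identical seed => identical corpus).
    Also returns, on each report, the flat OCR word table (perfect-OCR
    view) in report reading order.
    """
    rng = np.random.default_rng(spec.seed)
    n = spec.n_reports
    pages = spec.pages_per_report.sample(rng, n)
    ahis = np.round(spec.ahi_dist.sample(rng, n), 1)
    saos = np.round(spec.sao2_dist.sample(rng, n), 1)

    reports: list[SynthReport] = []
    golds: list[GoldRecord] = []

    for i in range(n):
        report_id = f"R{i:04d}"
        ahi = float(ahis[i])
        sao2 = float(saos[i])
        if spec.suppress_collisions:
            while abs(sao2 - ahi) == 0.0:
                sao2 = float(np.round(spec.sao2_dist.sample(rng, 1), 1)[0])
        n_pages = int(pages[i])

        n_ahi = 1 if rng.random() >= spec.p_multi_ahi else (2 if rng.random() < 0.8 else 3)
        n_sao2 = 1 if rng.random() >= spec.p_multi_sao2 else (2 if rng.random() < 0.8 else 3)

        name = f"{_FIRST_NAMES[int(rng.integers(len(_FIRST_NAMES)))]} {_LAST_NAMES[int(rng.integers(len(_LAST_NAMES)))]}"
        mrn = f"{int(rng.integers(10**6, 10**7)):07d}"
        date = f"{int(rng.integers(1, 13)):02d}/{int(rng.integers(1, 29)):02d}/{int(rng.integers(2015, 2019))}"

        page_plans = _plan_report(
            rng, spec, report_id, ahi, sao2, n_pages, n_ahi, n_sao2, name, mrn, date
        )
        words = _plans_to_ocr_words(page_plans)
        planted = tuple(
            (w.text, p + 1, (w.left, w.top, w.width, w.height), w.role)
            for p, plan in enumerate(page_plans)
            for w in plan
        )
        reports.append(
            SynthReport(
                report_id=report_id, page_plans=page_plans, ocr_words=words,
                patient_name=name, mrn=mrn,
            )
        )
        golds.append(GoldRecord(report_id=report_id, ahi=ahi, sao2=sao2, planted_words=planted))

    return reports, golds


def _plan_report(rng, spec, report_id, ahi, sao2, n_pages, n_ahi, n_sao2, name, mrn, date):
    gold_vals = (ahi, sao2)
    n_numerics = spec.numerics_per_page.sample(rng, n_pages)

    # assign gold mentions to (page, slot-within-page) positions
    total_slots = [int(k) for k in n_numerics]
    mentions: list[tuple[int, str]] = []  # (page index, role)
    for role, count in (("AHI", n_ahi), ("SaO2", n_sao2)):
        for j in range(count):
            if spec.positional_labels:
                page = 0
            elif j == 0:
                page = 0  # headline value appears on the first page
            else:
                page = int(rng.integers(n_pages))
            mentions.append((page, role))

    pages: list[list[PlannedWord]] = []
    for p in range(n_pages):
        sentences: list[list[tuple[str, str]]] = []
        if p == 0 and not spec.positional_labels:
            header = [
                ("Patient:", "prose"), *[(t, "prose") for t in name.split()],
                ("MRN:", "prose"), (mrn, "prose"),
                ("Study", "prose"), ("Date:", "prose"), (date, "prose"),
            ]
            sentences.append(header)

        page_mentions = [role for (pg, role) in mentions if pg == p]
        n_slots = max(total_slots[p], len(page_mentions))
        if spec.positional_labels:
            n_slots = min(n_slots, _GOLD_SLOT_CAP)
            n_slots = max(n_slots, len(page_mentions))
        slot_roles = page_mentions + ["distractor"] * (n_slots - len(page_mentions))
        if spec.positional_labels:
            # deterministic layout: AHI mentions first (top of page), SaO2
            # mentions last (bottom), distractors between -> vertical
            # position and page carry the class signal, the text does not.
            slot_roles = (
                [r for r in slot_roles if r == "AHI"]
                + [r for r in slot_roles if r == "distractor"]
                + [r for r in slot_roles if r == "SaO2"]
            )
        else:
            perm = rng.permutation(len(slot_roles))
            slot_roles = [slot_roles[int(k)] for k in perm]
            # keep gold mentions among the earliest sentences so a very
            # dense page can never overflow them off the layout (key
            # findings sit in the upper part of real reports anyway)
            cap = min(len(slot_roles), _GOLD_SLOT_CAP)
            for k in range(cap, len(slot_roles)):
                if slot_roles[k] in ("AHI", "SaO2"):
                    j = int(rng.integers(cap))
                    while slot_roles[j] in ("AHI", "SaO2"):
                        j = (j + 1) % cap
                    slot_roles[j], slot_roles[k] = slot_roles[k], slot_roles[j]

        for role in slot_roles:
            if role == "AHI":
                vtext = _fmt_value(ahi)
                pool = AHI_TEMPLATES
            elif role == "SaO2":
                vtext = _fmt_value(sao2)
                pool = SAO2_TEMPLATES
            else:
                v = _sample_distractor_value(rng)
                if spec.suppress_collisions:
                    while _collides(v, gold_vals):
                        v = _sample_distractor_value(rng)
                vtext = _fmt_value(v)
                pool = DISTRACTOR_TEMPLATES
            if spec.positional_labels:
                template = _POSITIONAL_TEMPLATE
            else:
                template = pool[int(rng.integers(len(pool)))]
            sentences.append(_fill_template(template, vtext, role if role != "distractor" else "distractor"))
            if not spec.positional_labels and rng.random() < 0.12:
                prose = PROSE_TEMPLATES[int(rng.integers(len(PROSE_TEMPLATES)))]
                sentences.append([(t, "prose") for t in prose.split()])

        pages.append(_layout_sentences(sentences))
    return pages


def _plans_to_ocr_words(page_plans: list[list[PlannedWord]]) -> list[OCRWord]:
    words = []
    for p, plan in enumerate(page_plans, start=1):
        for i, w in enumerate(plan):
            words.append(
                OCRWord(
                    text=w.text, conf=100.0, left=w.left, top=w.top,
                    width=w.width, height=w.height, page_num=p, order_idx=i,
                )
            )
    return assign_reading_order(words)


# ---------------------------------------------------------------------------
# rendering


def render_page(
    report_id: str,
    page_num: int,
    plan: Sequence[PlannedWord],
    noise_density: float = 0.0,
    seed: int = 0,
    page_size: tuple[int, int] = PAGE_SIZE,
) -> tuple[PageImage, np.ndarray]:
    """Render a page plan to a color page image.

    Each planted word is drawn inside its recorded bounding box on a
    low-contrast light background. ``noise_density`` plants that fraction
    of page pixels as isolated dark speckle dots (away from text), and the
    second return value is the boolean noise mask (True where a noise
    pixel was planted).
    """
    from PIL import Image, ImageDraw

    page_w, page_h = page_size
    # overlap check
    boxes = [(w.left, w.top, w.left + w.width, w.top + w.height) for w in plan]
    order = sorted(range(len(boxes)), key=lambda k: (boxes[k][1], boxes[k][0]))
    for a_i, b_i in zip(order, order[1:]):
        a, b = boxes[a_i], boxes[b_i]
        if a[0] < b[2] and b[0] < a[2] and a[1] < b[3] and b[1] < a[3]:
            raise LayoutError(f"overlapping word boxes {a} and {b}")

    img = Image.new("L", (page_w, page_h), color=_BACKGROUND)
    draw = ImageDraw.Draw(img)
    font = _font()
    for w in plan:
        if w.left + w.width > page_w or w.top + w.height > page_h:
            raise LayoutError(f"word {w.text!r} bbox off-page")
        draw.text((w.left + _STROKE, w.top + _STROKE), w.text, fill=0, font=font,
                  stroke_width=_STROKE, stroke_fill=0)
    gray = np.asarray(img, dtype=np.uint8).copy()

    noise_mask = np.zeros_like(gray, dtype=bool)
    if noise_density > 0:
        rng = np.random.default_rng(seed)
        n_dots = int(noise_density * page_w * page_h)
        # isolated: keep dots whose 5x5 neighborhood is pure background
        ys = rng.integers(2, page_h - 2, size=3 * n_dots)
        xs = rng.integers(2, page_w - 2, size=3 * n_dots)
        placed = 0
        for y, x in zip(ys, xs):
            if placed >= n_dots:
                break
            patch = gray[y - 2 : y + 3, x - 2 : x + 3]
            if (patch == _BACKGROUND).all():
                gray[y, x] = 0
                noise_mask[y, x] = True
                placed += 1

    rgb = np.repeat(gray[:, :, None], 3, axis=2)
    return PageImage(pixels=rgb, report_id=report_id, page_num=page_num), noise_mask


def measure_noise_removal(
    processed: PageImage,
    original: PageImage,
    noise_mask: np.ndarray,
    plan: Sequence[PlannedWord],
    threshold: int = 128,
    min_stroke_px: int = 9,
    retain_frac: float = 0.5,
) -> dict:
    """Quantify speckle removal and word-stroke survival after preprocessing.

    Noise removal: the fraction of planted noise pixels no longer dark.
    Stroke survival: a word is preserved when every glyph-scale stroke
    (connected dark component within its bbox of at least
    ``min_stroke_px`` pixels — the opening kernel's area, so speckle-size
    fragments don't count as strokes) keeps at least ``retain_frac`` of
    its pixels dark after preprocessing. Opening may shave single pixels
    off stroke junctions; it must never erase a stroke.
    """
    from scipy import ndimage as ndi

    before = np.asarray(original.pixels)
    if before.ndim == 3:
        before = np.rint(before @ np.array([0.299, 0.587, 0.114])).astype(np.uint8)
    after = processed.pixels
    if after.ndim == 3:
        raise ValueError("processed image must be gray")

    n_noise = int(noise_mask.sum())
    still_dark = int((after[noise_mask] < threshold).sum()) if n_noise else 0
    frac_removed = 1.0 if n_noise == 0 else 1.0 - still_dark / n_noise

    eight = np.ones((3, 3), dtype=int)
    n_words = 0
    n_preserved = 0
    for w in plan:
        sub_b = before[w.top : w.top + w.height, w.left : w.left + w.width] < threshold
        sub_a = after[w.top : w.top + w.height, w.left : w.left + w.width] < threshold
        if not sub_b.any():
            continue
        n_words += 1
        labels, n_comp = ndi.label(sub_b, structure=eight)
        ok = True
        for comp in range(1, n_comp + 1):
            comp_mask = labels == comp
            size = int(comp_mask.sum())
            if size < min_stroke_px:
                continue
            if int((sub_a & comp_mask).sum()) < retain_frac * size:
                ok = False
                break
        n_preserved += ok
    return {
        "n_noise_pixels": n_noise,
        "frac_noise_removed": frac_removed,
        "n_words": n_words,
        "n_words_connectivity_preserved": n_preserved,
    }


# ---------------------------------------------------------------------------
# statistics


def corpus_stats(golds: Sequence[GoldRecord], reports: Sequence[SynthReport]) -> dict:
    """Summary statistics of a generated corpus (empty corpus is an error)."""
    if not golds or not reports:
        raise ValueError("empty corpus")
    by_id = {r.report_id: r for r in reports}
    pages = np.array([by_id[g.report_id].n_pages for g in golds])
    numerics_per_page = np.array(
        [
            sum(1 for w in plan if w.role in ("AHI", "SaO2", "distractor"))
            for g in golds
            for plan in by_id[g.report_id].page_plans
        ]
    )
    n_ahi = np.array([len(g.words_with_role("AHI")) for g in golds])
    n_sao2 = np.array([len(g.words_with_role("SaO2")) for g in golds])
    ahi_vals = np.array([g.ahi for g in golds])
    sao2_vals = np.array([g.sao2 for g in golds])

    def q(x):
        return (
            float(np.median(x)),
            float(np.percentile(x, 25)),
            float(np.percentile(x, 75)),
        )

    return {
        "n_reports": len(golds),
        "pages_median": q(pages)[0],
        "pages_q1": q(pages)[1],
        "pages_q3": q(pages)[2],
        "numerics_per_page_median": q(numerics_per_page)[0],
        "numerics_per_page_q1": q(numerics_per_page)[1],
        "numerics_per_page_q3": q(numerics_per_page)[2],
        "ahi_mentions_median": float(np.median(n_ahi)),
        "sao2_mentions_median": float(np.median(n_sao2)),
        "frac_multi_ahi": float(np.mean(n_ahi > 1)),
        "frac_multi_sao2": float(np.mean(n_sao2 > 1)),
        "ahi_mean": float(ahi_vals.mean()),
        "ahi_sd": float(ahi_vals.std(ddof=1)) if len(golds) > 1 else 0.0,
        "sao2_mean": float(sao2_vals.mean()),
        "sao2_sd": float(sao2_vals.std(ddof=1)) if len(golds) > 1 else 0.0,
    }
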