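"""Read/write screen tabular and interval formats and validate internal consistency.

The guide quantification dialect is a tab-separated table with a header whose
first nine columns are::

    chrom  pam_start  pam_end  guide_id  score  strand  protospacer  category  specificity

followed by one integer read-count column per sample.  All coordinates are
0-based half-open (BED convention).  Nontargeting guides leave chrom /
pam_start / pam_end / strand empty (or ``.``).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

GUIDE_CATEGORIES = {"targeting", "nontargeting", "safe_targeting", "positive_control"}
MODALITIES = {"cas9", "dcas9", "dcas9_krab", "dcas9_activator"}
READOUTS = {"sorting", "growth"}
SIGN_CONVENTIONS = {"A_enriched_positive", "B_enriched_positive"}

#: score column cap for -log10(FDR), matching the smallest positive float64
SCORE_CAP = 320.0

GUIDE_COLUMNS = [
    "chrom", "pam_start", "pam_end", "guide_id", "score", "strand",
    "protospacer", "category", "specificity",
]

ELEMENT_COLUMNS = [
    "chrom", "start", "end", "name", "score", "strand",
    "mean_effect", "aggregated_p", "fdr", "n_guides",
]


class ScreenFormatError(ValueError):
    """Malformed screen file (schema, value, uniqueness or ordering problems)."""


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open genomic interval with optional BED metadata."""

    chrom: str
    start: int
    end: int
    name: str | None = None
    score: float | None = None
    strand: str | None = None
    summit_offset: int | None = None

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ScreenFormatError(
                f"invalid interval {self.chrom}:{self.start}-{self.end}"
            )
        if self.summit_offset is not None and not (
            0 <= self.summit_offset < self.end - self.start
        ):
            raise ScreenFormatError(
                f"summit offset {self.summit_offset} outside interval of length "
                f"{self.end - self.start}"
            )

    def __len__(self) -> int:
        return self.end - self.start

    @property
    def summit(self) -> int | None:
        if self.summit_offset is None:
            return None
        return self.start + self.summit_offset

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )


@dataclass
class GuideRecord:
    """One sgRNA: PAM interval, strand, category, specificity and read counts."""

    guide_id: str
    chrom: str | None
    pam_start: int | None
    pam_end: int | None
    strand: str | None
    protospacer: str
    category: str
    specificity: float | None
    counts: dict[str, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.category not in GUIDE_CATEGORIES:
            raise ScreenFormatError(
                f"guide {self.guide_id}: unknown category {self.category!r}"
            )
        if self.category == "nontargeting":
            if self.chrom is not None or self.pam_start is not None:
                raise ScreenFormatError(
                    f"nontargeting guide {self.guide_id} must not have coordinates"
                )
        else:
            if self.chrom is None or self.pam_start is None or self.pam_end is None:
                raise ScreenFormatError(
                    f"guide {self.guide_id} ({self.category}) lacks coordinates"
                )
            if self.pam_end - self.pam_start != 3:
                raise ScreenFormatError(
                    f"guide {self.guide_id}: PAM window must be 3 bp, got "
                    f"[{self.pam_start},{self.pam_end})"
                )
        for sample, c in self.counts.items():
            if c < 0:
                raise ScreenFormatError(
                    f"guide {self.guide_id}: negative count in sample {sample}"
                )
        if self.specificity is not None and not (0.0 <= self.specificity <= 1.0):
            raise ScreenFormatError(
                f"guide {self.guide_id}: specificity {self.specificity} outside [0,1]"
            )

    @property
    def has_coordinates(self) -> bool:
        return self.chrom is not None

    def pam_interval(self) -> GenomicInterval:
        if not self.has_coordinates:
            raise ScreenFormatError(f"guide {self.guide_id} has no coordinates")
        return GenomicInterval(
            self.chrom, self.pam_start, self.pam_end,
            name=self.guide_id, strand=self.strand,
        )


@dataclass
class ScreenDesign:
    """Screen metadata: modality, readout and replicate sample comparisons.

    Each comparison is a pair ``(sample_A, sample_B)`` where A is the
    low-expression bin (or earlier time point) and B the high bin (or later
    time point).
    """

    modality: str
    readout: str
    comparisons: list[tuple[str, str]]
    sign_convention: str = "A_enriched_positive"

    def __post_init__(self) -> None:
        if self.modality not in MODALITIES:
            raise ScreenFormatError(f"unknown modality {self.modality!r}")
        if self.readout not in READOUTS:
            raise ScreenFormatError(f"unknown readout {self.readout!r}")
        if self.sign_convention not in SIGN_CONVENTIONS:
            raise ScreenFormatError(
                f"unknown sign convention {self.sign_convention!r}"
            )
        if len(self.comparisons) < 1:
            raise ScreenFormatError("design needs at least one replicate comparison")
        self.comparisons = [tuple(c) for c in self.comparisons]

    @property
    def samples(self) -> list[str]:
        out: list[str] = []
        for a, b in self.comparisons:
            out.extend([a, b])
        return out


def validate_screen(guides: Sequence[GuideRecord], design: ScreenDesign) -> list[str]:
    """Return a list of human-readable consistency problems (empty if valid)."""
    problems: list[str] = []
    seen: set[str] = set()
    for g in guides:
        if g.guide_id in seen:
            problems.append(f"duplicate guide_id {g.guide_id}")
        seen.add(g.guide_id)
        for sample in design.samples:
            if sample not in g.counts:
                problems.append(
                    f"guide {g.guide_id}: missing count for sample {sample}"
                )
    return problems


def _parse_optional_int(token: str) -> int | None:
    token = token.strip()
    if token in ("", ".", "NA", "nan"):
        return None
    return int(token)


def _parse_count(token: str, line_no: int, sample: str) -> int:
    try:
        value = float(token)
    except ValueError as exc:
        raise ScreenFormatError(
            f"line {line_no}: unparsable count {token!r} for sample {sample}"
        ) from exc
    if not value.is_integer():
        raise ScreenFormatError(
            f"line {line_no}: fractional count {token!r} for sample {sample}; "
            "counts must be integers"
        )
    value = int(value)
    if value < 0:
        raise ScreenFormatError(
            f"line {line_no}: negative count {value} for sample {sample}"
        )
    return value


def read_guide_quant(
    path: str | Path, sample_columns: Sequence[str] | None = None
) -> list[GuideRecord]:
    """Read a guide quantification table into GuideRecords.

    ``sample_columns`` selects which header columns are read counts; by
    default every column after the ninth is treated as a sample.
    """
    path = Path(path)
    with open(path) as fh:
        header_line = fh.readline().rstrip("\n")
        if not header_line:
            raise ScreenFormatError(f"{path}: empty file")
        header = header_line.split("\t")
        for col in GUIDE_COLUMNS:
            if col not in header:
                raise ScreenFormatError(f"{path}: missing required column {col!r}")
        if sample_columns is None:
            sample_columns = [c for c in header if c not in GUIDE_COLUMNS]
        else:
            for s in sample_columns:
                if s not in header:
                    raise ScreenFormatError(f"{path}: missing sample column {s!r}")
        idx = {c: header.index(c) for c in header}

        guides: list[GuideRecord] = []
        seen: set[str] = set()
        for line_no, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != len(header):
                raise ScreenFormatError(
                    f"{path} line {line_no}: expected {len(header)} columns, "
                    f"got {len(fields)}"
                )

            def get(col: str) -> str:
                return fields[idx[col]]

            guide_id = get("guide_id")
            if guide_id in seen:
                raise ScreenFormatError(
                    f"{path} line {line_no}: duplicate guide_id {guide_id!r}"
                )
            seen.add(guide_id)
            category = get("category").replace("-", "_")
            if category == "non_targeting":
                category = "nontargeting"
            chrom = get("chrom").strip() or None
            if chrom == ".":
                chrom = None
            try:
                pam_start = _parse_optional_int(get("pam_start"))
                pam_end = _parse_optional_int(get("pam_end"))
            except ValueError as exc:
                raise ScreenFormatError(
                    f"{path} line {line_no}: bad coordinate: {exc}"
                ) from exc
            strand = get("strand").strip() or None
            if strand == ".":
                strand = None
            spec_tok = get("specificity").strip()
            specificity = (
                None if spec_tok in ("", ".", "NA", "nan") else float(spec_tok)
            )
            counts = {
                s: _parse_count(get(s), line_no, s) for s in sample_columns
            }
            try:
                guides.append(
                    GuideRecord(
                        guide_id=guide_id,
                        chrom=chrom,
                        pam_start=pam_start,
                        pam_end=pam_end,
                        strand=strand,
                        protospacer=get("protospacer"),
                        category=category,
                        specificity=specificity,
                        counts=counts,
                    )
                )
            except ScreenFormatError as exc:
                raise ScreenFormatError(f"{path} line {line_no}: {exc}") from exc
    return guides


def write_guide_quant(
    guides: Sequence[GuideRecord], path: str | Path,
    sample_columns: Sequence[str] | None = None,
) -> None:
    """Write GuideRecords back to the tab-separated guide quantification dialect."""
    if sample_columns is None:
        sample_columns = list(guides[0].counts) if guides else []
    with open(path, "w") as fh:
        fh.write("\t".join(GUIDE_COLUMNS + list(sample_columns)) + "\n")
        for g in guides:
            row = [
                g.chrom or "",
                "" if g.pam_start is None else str(g.pam_start),
                "" if g.pam_end is None else str(g.pam_end),
                g.guide_id,
                "0",
                g.strand or "",
                g.protospacer,
                g.category,
                "" if g.specificity is None else repr(g.specificity),
            ] + [str(g.counts[s]) for s in sample_columns]
            fh.write("\t".join(row) + "\n")


def read_design(path: str | Path) -> ScreenDesign:
    """Read a screen design from a YAML (or JSON) key-value file."""
    with open(path) as fh:
        data = yaml.safe_load(fh)
    return ScreenDesign(
        modality=data["modality"],
        readout=data["readout"],
        comparisons=[tuple(c) for c in data["comparisons"]],
        sign_convention=data.get("sign_convention", "A_enriched_positive"),
    )


def write_design(design: ScreenDesign, path: str | Path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(
            {
                "modality": design.modality,
                "readout": design.readout,
                "comparisons": [list(c) for c in design.comparisons],
                "sign_convention": design.sign_convention,
            },
            fh,
        )


_DIALECT_COLUMNS = {"bed3": 3, "bed6": 6, "narrowPeak": 10, "tads": 3}


def read_intervals(path: str | Path, dialect: str = "bed3") -> list[GenomicInterval]:
    """Read BED3/BED6/narrowPeak/TAD interval files.

    narrowPeak rows populate ``summit_offset`` from the 10th column; a summit
    of −1 (the no-summit convention) yields ``summit_offset=None``.
    """
    if dialect not in _DIALECT_COLUMNS:
        raise ScreenFormatError(f"unknown interval dialect {dialect!r}")
    n_min = _DIALECT_COLUMNS[dialect]
    intervals: list[GenomicInterval] = []
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < n_min:
                raise ScreenFormatError(
                    f"{path} line {line_no}: {dialect} needs ≥{n_min} columns"
                )
            chrom, start, end = fields[0], int(fields[1]), int(fields[2])
            if start >= end:
                raise ScreenFormatError(
                    f"{path} line {line_no}: start {start} >= end {end}"
                )
            name = fields[3] if len(fields) > 3 and n_min > 3 else None
            score = (
                float(fields[4]) if len(fields) > 4 and n_min > 4 and fields[4] != "." else None
            )
            strand = (
                fields[5] if len(fields) > 5 and n_min > 5 and fields[5] != "." else None
            )
            summit_offset = None
            if dialect == "narrowPeak":
                summit = int(fields[9])
                summit_offset = None if summit == -1 else summit
            intervals.append(
                GenomicInterval(chrom, start, end, name=name, score=score,
                                strand=strand, summit_offset=summit_offset)
            )
    return intervals


def write_intervals(intervals: Iterable[GenomicInterval], path: str | Path) -> None:
    """Write intervals as BED6 (missing fields as '.')."""
    with open(path, "w") as fh:
        for iv in intervals:
            score = "0" if iv.score is None else f"{iv.score:g}"
            fh.write(
                "\t".join([
                    iv.chrom, str(iv.start), str(iv.end), iv.name or ".",
                    score, iv.strand or ".",
                ]) + "\n"
            )


def write_element_quant(calls: Sequence, path: str | Path) -> None:
    """Write CRE calls as BED6+ element quantification.

    Columns: chrom, start, end, name, score (−log10 FDR capped at 320),
    strand (.), mean_effect, aggregated_p, fdr, n_guides.  Input must be
    sorted by (chrom, start).
    """
    keys = [(c.interval.chrom, c.interval.start) for c in calls]
    if keys != sorted(keys):
        raise ScreenFormatError("element calls must be sorted by (chrom, start)")
    with open(path, "w") as fh:
        fh.write("\t".join(ELEMENT_COLUMNS) + "\n")
        for c in calls:
            if c.fdr <= 0:
                score = SCORE_CAP
            else:
                score = min(-math.log10(c.fdr), SCORE_CAP)
            fh.write(
                "\t".join([
                    c.interval.chrom,
                    str(c.interval.start),
                    str(c.interval.end),
                    c.interval.name or ".",
                    repr(score),
                    ".",
                    repr(c.mean_effect),
                    repr(c.aggregated_p),
                    repr(c.fdr),
                    str(c.n_guides),
                ]) + "\n"
            )


def read_element_quant(path: str | Path) -> pd.DataFrame:
    """Read an element quantification table back as a DataFrame."""
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ELEMENT_COLUMNS if c not in df.columns]
    if missing:
        raise ScreenFormatError(f"{path}: missing element columns {missing}")
    return df
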