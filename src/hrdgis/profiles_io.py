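"""Read, validate and write allele-specific copy-number profiles and results.

The segmentation dialect is a tab-delimited table with header
``sample chromosome start end total_cn minor_cn`` and 1-based inclusive
coordinates on disk (converted to the package's 0-based half-open frame on
load). Optional ``#purity=<x>`` / ``#ploidy=<y>`` comment lines apply to the
single-sample case; multi-sample purity/ploidy comes from a sidecar metadata
table. Purity and ploidy are carried as metadata only: the score operates on
the integer allele-specific states, which are already purity/ploidy-resolved
upstream.
"""

from __future__ import annotations

import csv
import json
import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import TYPE_CHECKING, Iterable, Sequence

from .genome import GenomeBuild, arm_of

if TYPE_CHECKING:  # pragma: no cover
    from .score import GISResult, HRDCall

__all__ = [
    "SegmentationError",
    "AlleleSpecificSegment",
    "CopyNumberProfile",
    "BRCAStatus",
    "LoadReport",
    "read_segmentation",
    "read_brca_table",
    "merge_equal_state_runs",
    "write_results",
    "write_segmentation",
]


class SegmentationError(ValueError):
    """Raised when a segmentation table violates the input contract."""


class BRCAStatus:
    """Per-sample BRCA1/2 pathogenic-mutation flag."""

    PATHOGENIC = "pathogenic"
    WILDTYPE = "wildtype"
    UNKNOWN = "unknown"
    VALUES = (PATHOGENIC, WILDTYPE, UNKNOWN)

    @classmethod
    def validate(cls, value: str) -> str:
        if value not in cls.VALUES:
            raise SegmentationError(
                f"BRCA status must be one of {cls.VALUES}, got {value!r}"
            )
        return value


@dataclass(frozen=True)
class AlleleSpecificSegment:
    """One genomic interval with integer total and minor-allele copy number.

    ``pieces`` are the observed sub-intervals of the span: a freshly loaded
    segment is fully observed (one piece covering [start, end)); segments
    produced by :func:`merge_equal_state_runs` span the fused gap but keep
    the gap out of the observed territory.
    """

    chromosome: str
    start: int
    end: int
    total_cn: int
    minor_cn: int
    pieces: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        if not self.start < self.end:
            raise SegmentationError(
                f"{self.chromosome}:[{self.start},{self.end}): empty segment"
            )
        if self.total_cn < 0 or self.minor_cn < 0:
            raise SegmentationError(
                f"{self.chromosome}:[{self.start},{self.end}): negative copy number"
            )
        if self.minor_cn > self.total_cn - self.minor_cn:
            raise SegmentationError(
                f"{self.chromosome}:[{self.start},{self.end}): minor_cn "
                f"{self.minor_cn} exceeds the major allele of total_cn {self.total_cn}"
            )
        if not self.pieces:
            object.__setattr__(self, "pieces", ((self.start, self.end),))
        else:
            prev = self.start - 1
            for s, e in self.pieces:
                if s >= e or s < self.start or e > self.end or s <= prev:
                    raise SegmentationError(
                        f"{self.chromosome}:[{self.start},{self.end}): "
                        f"malformed observed pieces {self.pieces}"
                    )
                prev = e
            if self.pieces[0][0] != self.start or self.pieces[-1][1] != self.end:
                raise SegmentationError(
                    f"{self.chromosome}:[{self.start},{self.end}): pieces must "
                    "touch both span ends"
                )

    @property
    def state(self) -> tuple[int, int]:
        return (self.total_cn, self.minor_cn)

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def observed_bp(self) -> int:
        return sum(e - s for s, e in self.pieces)


@dataclass(frozen=True)
class CopyNumberProfile:
    """One sample's ordered, non-overlapping allele-specific segments."""

    sample_id: str
    segments: tuple[AlleleSpecificSegment, ...]
    purity: float | None = None
    ploidy: float | None = None

    def __post_init__(self) -> None:
        by_chrom: dict[str, int] = {}
        seen_order: list[str] = []
        for seg in self.segments:
            if seg.chromosome not in by_chrom:
                by_chrom[seg.chromosome] = seg.start - 1
                seen_order.append(seg.chromosome)
            if seg.start <= by_chrom[seg.chromosome] :
                raise SegmentationError(
                    f"{self.sample_id}: segments on {seg.chromosome} overlap or are "
                    f"unsorted near position {seg.start}"
                )
            by_chrom[seg.chromosome] = seg.end - 1
        if self.purity is not None and not 0.0 < self.purity <= 1.0:
            raise SegmentationError(f"{self.sample_id}: purity {self.purity} not in (0, 1]")
        if self.ploidy is not None and self.ploidy <= 0:
            raise SegmentationError(f"{self.sample_id}: non-positive ploidy {self.ploidy}")

    def chromosomes(self) -> list[str]:
        out: list[str] = []
        for seg in self.segments:
            if not out or out[-1] != seg.chromosome:
                out.append(seg.chromosome)
        return out

    def segments_of(self, chromosome: str) -> list[AlleleSpecificSegment]:
        return [s for s in self.segments if s.chromosome == chromosome]

    def observed_genome_bp(self, build: GenomeBuild) -> int:
        """Arm-overlapping observed territory (centromere portions excluded)."""
        total = 0
        for seg in self.segments:
            if seg.chromosome not in build.included_chromosomes:
                continue
            for s, e in seg.pieces:
                ov = arm_of(build, seg.chromosome, s, e)
                total += ov.p_bp + ov.q_bp
        return total

    def validate_against_build(self, build: GenomeBuild) -> None:
        for seg in self.segments:
            if seg.chromosome not in build.included_chromosomes:
                raise SegmentationError(
                    f"{self.sample_id}: segment on chromosome {seg.chromosome!r} "
                    f"not included in build {build.name}"
                )
            length = build.chromosome_length(seg.chromosome)
            if seg.start < 0 or seg.end > length:
                raise SegmentationError(
                    f"{self.sample_id}: {seg.chromosome}:[{seg.start},{seg.end}) "
                    f"outside chromosome (length {length})"
                )


@dataclass
class LoadReport:
    """Accounting of what a segmentation load kept and dropped."""

    n_samples: int = 0
    n_rows: int = 0
    n_rows_kept: int = 0
    dropped_chromosome_rows: dict[str, int] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "n_samples": self.n_samples,
            "n_rows": self.n_rows,
            "n_rows_kept": self.n_rows_kept,
            "dropped_chromosome_rows": dict(self.dropped_chromosome_rows),
        }


_SEG_COLUMNS = ("sample", "chromosome", "start", "end", "total_cn", "minor_cn")


def read_segmentation(
    path: str | Path, build: GenomeBuild
) -> tuple[list[CopyNumberProfile], LoadReport]:
    """Load a segmentation TSV into validated per-sample profiles.

    Rows on chromosomes the build excludes are dropped and counted in the
    returned :class:`LoadReport`; any invariant violation (overlap, minor
    allele exceeding the major one, coordinates outside the build) rejects
    the file naming the offending row. An empty file yields an empty list.
    """
    path = Path(path)
    report = LoadReport()
    rows: dict[str, list[AlleleSpecificSegment]] = {}
    purity: float | None = None
    ploidy: float | None = None
    with path.open(newline="") as fh:
        header: list[str] | None = None
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            if line.startswith("#"):
                body = line[1:].strip()
                if body.startswith("purity="):
                    purity = float(body.split("=", 1)[1])
                elif body.startswith("ploidy="):
                    ploidy = float(body.split("=", 1)[1])
                continue
            parts = line.split("\t")
            if header is None:
                header = [p.strip() for p in parts]
                missing = set(_SEG_COLUMNS) - set(header)
                if missing:
                    raise SegmentationError(
                        f"{path.name}: missing column(s) {sorted(missing)}"
                    )
                continue
            row = dict(zip(header, parts))
            report.n_rows += 1
            where = f"{path.name} line {lineno}"
            sample = row["sample"].strip()
            chrom = row["chromosome"].strip()
            try:
                start = int(row["start"])
                end = int(row["end"])
                total_cn = int(row["total_cn"])
                minor_cn = int(row["minor_cn"])
            except (KeyError, ValueError):
                raise SegmentationError(f"{where}: non-numeric field") from None
            if chrom not in build.included_chromosomes:
                report.dropped_chromosome_rows[chrom] = (
                    report.dropped_chromosome_rows.get(chrom, 0) + 1
                )
                continue
            try:
                seg = AlleleSpecificSegment(
                    chromosome=chrom,
                    start=start - 1,  # 1-based inclusive -> 0-based half-open
                    end=end,
                    total_cn=total_cn,
                    minor_cn=minor_cn,
                )
            except SegmentationError as exc:
                raise SegmentationError(f"{where}: {exc}") from None
            report.n_rows_kept += 1
            rows.setdefault(sample, []).append(seg)

    chrom_order = {name: i for i, (name, _) in enumerate(build.chromosomes)}
    profiles: list[CopyNumberProfile] = []
    for sample, segs in rows.items():
        segs.sort(key=lambda s: (chrom_order.get(s.chromosome, 1 << 30), s.start))
        try:
            profile = CopyNumberProfile(
                sample_id=sample,
                segments=tuple(segs),
                purity=purity if len(rows) == 1 else None,
                ploidy=ploidy if len(rows) == 1 else None,
            )
            profile.validate_against_build(build)
        except SegmentationError as exc:
            raise SegmentationError(f"{path.name}: {exc}") from None
        profiles.append(profile)
    report.n_samples = len(profiles)
    return profiles, report


def read_brca_table(path: str | Path) -> dict[str, str]:
    """Load a two-column TSV ``sample<TAB>brca_status`` into a dict."""
    out: dict[str, str] = {}
    with Path(path).open(newline="") as fh:
        reader = csv.reader(fh, delimiter="\t")
        for row in reader:
            if not row or row[0].startswith("#") or row[0] == "sample":
                continue
            if len(row) < 2:
                raise SegmentationError(f"BRCA table row {row!r}: expected 2 columns")
            out[row[0]] = BRCAStatus.validate(row[1].strip().lower())
    return out


def merge_equal_state_runs(
    profile: CopyNumberProfile, max_gap_bp: int
) -> CopyNumberProfile:
    """Fuse same-chromosome neighbours with identical state across small gaps.

    Consecutive segments with identical ``(total_cn, minor_cn)`` separated by
    an unobserved gap of at most *max_gap_bp* become one segment spanning
    both; the gap counts toward the span but not toward observed territory.
    Idempotent; with ``max_gap_bp=0`` only touching segments fuse.
    """
    merged: list[AlleleSpecificSegment] = []
    for seg in profile.segments:
        prev = merged[-1] if merged else None
        if (
            prev is not None
            and prev.chromosome == seg.chromosome
            and prev.state == seg.state
            and seg.start - prev.end <= max_gap_bp
        ):
            if seg.start == prev.end:
                pieces = prev.pieces[:-1] + ((prev.pieces[-1][0], seg.pieces[0][1]),) + seg.pieces[1:]
            else:
                pieces = prev.pieces + seg.pieces
            merged[-1] = replace(prev, end=seg.end, pieces=pieces)
        else:
            merged.append(seg)
    return replace(profile, segments=tuple(merged))


def write_segmentation(
    profiles: Iterable[CopyNumberProfile], path: str | Path
) -> None:
    """Write profiles back to the 1-based inclusive segmentation dialect.

    Multi-piece (merged) segments are written piece-wise so the round trip
    stays faithful to observed territory.
    """
    path = Path(path)
    profiles = list(profiles)
    with path.open("w", newline="") as fh:
        if len(profiles) == 1 and profiles[0].purity is not None:
            fh.write(f"#purity={profiles[0].purity}\n")
        if len(profiles) == 1 and profiles[0].ploidy is not None:
            fh.write(f"#ploidy={profiles[0].ploidy}\n")
        fh.write("\t".join(_SEG_COLUMNS) + "\n")
        for prof in profiles:
            for seg in prof.segments:
                for s, e in seg.pieces:
                    fh.write(
                        f"{prof.sample_id}\t{seg.chromosome}\t{s + 1}\t{e}\t"
                        f"{seg.total_cn}\t{seg.minor_cn}\n"
                    )


# -- results serialization -------------------------------------------------

_RESULT_COLUMNS = (
    "sample",
    "ploh_pct",
    "pcna_pct",
    "ptcna_pct",
    "gis",
    "evaluable",
    "gi_status",
    "brca_status",
    "hrd_status",
    "observed_genome_bp",
    "observed_fraction",
)


def _fmt(value: float | None) -> str:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return ""
    return f"{value:.4f}"


def write_results(
    results: Sequence[tuple["GISResult", "HRDCall"]],
    path: str | Path,
    format: str = "tsv",
) -> None:
    """Write per-sample scoring results as TSV (flat) or JSON (with detail).

    The JSON form adds per-chromosome expected states, contributing regions
    and telomere verdicts; all numbers are serialized to 4 decimal places.
    """
    path = Path(path)
    if format == "tsv":
        with path.open("w", newline="") as fh:
            fh.write("\t".join(_RESULT_COLUMNS) + "\n")
            for gis, hrd in results:
                gi_status = (
                    "" if gis.gi_positive is None
                    else ("positive" if gis.gi_positive else "negative")
                )
                fh.write(
                    "\t".join(
                        [
                            gis.sample_id,
                            _fmt(gis.ploh_pct),
                            _fmt(gis.pcna_pct),
                            _fmt(gis.ptcna_pct),
                            _fmt(gis.gis),
                            "true" if gis.evaluable else "false",
                            gi_status,
                            hrd.brca,
                            hrd.hrd_status,
                            str(gis.observed_genome_bp),
                            _fmt(gis.observed_fraction),
                        ]
                    )
                    + "\n"
                )
    elif format == "json":
        payload = [_result_json(gis, hrd) for gis, hrd in results]
        with path.open("w") as fh:
            json.dump(payload, fh, indent=2)
            fh.write("\n")
    else:
        raise ValueError(f"unknown results format {format!r}")


def _round4(value: float | None) -> float | None:
    return None if value is None else round(value, 4)


def _result_json(gis: "GISResult", hrd: "HRDCall") -> dict:
    return {
        "sample": gis.sample_id,
        "ploh_pct": _round4(gis.ploh_pct),
        "pcna_pct": _round4(gis.pcna_pct),
        "ptcna_pct": _round4(gis.ptcna_pct),
        "gis": _round4(gis.gis),
        "evaluable": gis.evaluable,
        "gi_positive": gis.gi_positive,
        "brca_status": hrd.brca,
        "hrd_status": hrd.hrd_status,
        "observed_genome_bp": gis.observed_genome_bp,
        "observed_fraction": _round4(gis.observed_fraction),
        "expected_states": [
            {
                "chromosome": st.chromosome,
                "total_cn": st.total_cn,
                "minor_cn": st.minor_cn,
                "covered_bp": st.covered_bp,
            }
            for st in gis.expected_states
        ],
        "contributing_regions": {
            component: [
                {
                    "chromosome": r.chromosome,
                    "start": r.start,
                    "end": r.end,
                    "span_bp": r.span_bp,
                    "observed_bp": r.observed_bp,
                    "contains_homozygous_deletion": r.contains_homozygous_deletion,
                }
                for r in regions
            ]
            for component, regions in gis.contributing_regions.items()
        },
        "telomeres": [
            {
                "chromosome": t.chromosome,
                "arm": t.arm,
                "evaluable": t.evaluable,
                "altered": t.altered,
                "reason": t.reason,
            }
            for t in gis.telomeres
        ],
    }
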