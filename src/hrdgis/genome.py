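"""Genome-build model: chromosomes, arms, centromeres, telomere assembly status.

All internal coordinates are 0-based half-open. The on-disk dialects
(arm-definition TSV, UCSC cytoBand) are 1-based inclusive and 0-based
half-open respectively; conversion happens only in the loaders.

The centromere belongs to neither arm: interval arithmetic against a build
splits any query into its p-arm, q-arm and centromere portions, and scoring
rules only ever see the arm portions.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, NamedTuple

__all__ = [
    "BuildError",
    "ChromosomeArm",
    "GenomeBuild",
    "ArmOverlap",
    "arm_of",
    "load_arm_table",
    "load_cytoband",
    "hg19_build",
    "DEFAULT_ACROCENTRIC_P",
]


class BuildError(ValueError):
    """Raised when a genome-build definition is malformed."""


#: hg19 acrocentric chromosomes whose p-arm telomere is not assembled.
DEFAULT_ACROCENTRIC_P = frozenset(
    {"chr13", "chr14", "chr15", "chr21", "chr22", "13", "14", "15", "21", "22"}
)

_EXCLUDED_BY_DEFAULT = frozenset({"chrY", "Y", "chrM", "MT", "chrMT", "M"})


@dataclass(frozen=True)
class ChromosomeArm:
    """One chromosome arm, 0-based half-open, with its telomere assembly flag."""

    chromosome: str
    arm: str  # "p" or "q"
    start: int
    end: int
    telomere_assembled: bool = True

    def __post_init__(self) -> None:
        if self.arm not in ("p", "q"):
            raise BuildError(f"{self.chromosome}: arm must be 'p' or 'q', got {self.arm!r}")
        if not self.start < self.end:
            raise BuildError(
                f"{self.chromosome}{self.arm}: empty or inverted arm "
                f"[{self.start}, {self.end})"
            )

    @property
    def length(self) -> int:
        return self.end - self.start


class ArmOverlap(NamedTuple):
    """Base-pair overlap of an interval with the p arm, q arm and centromere."""

    p_bp: int
    q_bp: int
    centromere_bp: int


@dataclass(frozen=True)
class GenomeBuild:
    """A coordinate frame for scoring: chromosome lengths, arms, telomere flags.

    Parameters
    ----------
    name
        Build label, e.g. ``"hg19"`` or a toy label in tests.
    chromosomes
        Ordered ``(name, length)`` pairs for every chromosome known to the
        build (including excluded ones).
    arms
        Two :class:`ChromosomeArm` per included chromosome.
    included_chromosomes
        The chromosomes that enter scoring; segments elsewhere are dropped.
    """

    name: str
    chromosomes: tuple[tuple[str, int], ...]
    arms: tuple[ChromosomeArm, ...]
    included_chromosomes: frozenset[str]
    _length: dict = field(init=False, repr=False, compare=False)
    _arm_pair: dict = field(init=False, repr=False, compare=False)

    def __post_init__(self) -> None:
        lengths = dict(self.chromosomes)
        if len(lengths) != len(self.chromosomes):
            raise BuildError("duplicate chromosome names in build")
        pairs: dict[str, dict[str, ChromosomeArm]] = {}
        for arm in self.arms:
            if arm.chromosome not in lengths:
                raise BuildError(f"arm for unknown chromosome {arm.chromosome!r}")
            if arm.end > lengths[arm.chromosome] or arm.start < 0:
                raise BuildError(
                    f"{arm.chromosome}{arm.arm}: arm [{arm.start}, {arm.end}) outside "
                    f"chromosome of length {lengths[arm.chromosome]}"
                )
            slot = pairs.setdefault(arm.chromosome, {})
            if arm.arm in slot:
                raise BuildError(f"{arm.chromosome}: duplicate {arm.arm} arm")
            slot[arm.arm] = arm
        for chrom in self.included_chromosomes:
            if chrom not in lengths or lengths[chrom] <= 0:
                raise BuildError(f"included chromosome {chrom!r} missing or zero-length")
            slot = pairs.get(chrom, {})
            if set(slot) != {"p", "q"}:
                raise BuildError(f"included chromosome {chrom!r} lacks two arms")
            p, q = slot["p"], slot["q"]
            if p.start != 0:
                raise BuildError(f"{chrom}: p arm must start at 0")
            if not p.end <= q.start:
                raise BuildError(f"{chrom}: p and q arms overlap")
        object.__setattr__(self, "_length", lengths)
        object.__setattr__(self, "_arm_pair", pairs)

    # -- lookups ----------------------------------------------------------

    def chromosome_length(self, chromosome: str) -> int:
        try:
            return self._length[chromosome]
        except KeyError:
            raise BuildError(f"unknown chromosome {chromosome!r} in build {self.name}") from None

    def arms_of(self, chromosome: str) -> tuple[ChromosomeArm, ChromosomeArm]:
        """Return the (p, q) arm pair of an included chromosome."""
        if chromosome not in self.included_chromosomes:
            raise BuildError(f"chromosome {chromosome!r} not included in build {self.name}")
        slot = self._arm_pair[chromosome]
        return slot["p"], slot["q"]

    def centromere(self, chromosome: str) -> tuple[int, int]:
        p, q = self.arms_of(chromosome)
        return p.end, q.start

    @property
    def assembled_reference_bp(self) -> int:
        """Total arm territory of the included chromosomes (the score's reference)."""
        return sum(
            arm.length for arm in self.arms if arm.chromosome in self.included_chromosomes
        )

    def sorted_included(self) -> list[str]:
        order = {name: i for i, (name, _) in enumerate(self.chromosomes)}
        return sorted(self.included_chromosomes, key=order.__getitem__)


def arm_of(build: GenomeBuild, chromosome: str, start: int, end: int) -> ArmOverlap:
    """Split an interval into its p-arm / q-arm / centromere base-pair overlaps.

    The three overlaps always sum to ``end - start``.
    """
    if not start < end:
        raise BuildError(f"empty interval [{start}, {end})")
    length = build.chromosome_length(chromosome)
    if start < 0 or end > length:
        raise BuildError(
            f"interval [{start}, {end}) outside {chromosome} (length {length})"
        )
    p, q = build.arms_of(chromosome)
    p_bp = max(0, min(end, p.end) - max(start, p.start))
    q_bp = max(0, min(end, q.end) - max(start, q.start))
    return ArmOverlap(p_bp, q_bp, (end - start) - p_bp - q_bp)


# -- loaders ---------------------------------------------------------------

_ARM_TABLE_COLUMNS = (
    "chromosome",
    "length",
    "centromere_start",
    "centromere_end",
    "p_telomere_assembled",
    "q_telomere_assembled",
)

_TRUTHY = {"true", "1", "yes", "t"}
_FALSY = {"false", "0", "no", "f"}


def _parse_bool(value: str, where: str) -> bool:
    v = value.strip().lower()
    if v in _TRUTHY:
        return True
    if v in _FALSY:
        return False
    raise BuildError(f"{where}: expected boolean, got {value!r}")


def _parse_int(value: str, where: str) -> int:
    try:
        return int(value)
    except ValueError:
        raise BuildError(f"{where}: non-numeric coordinate {value!r}") from None


def load_arm_table(
    path: str | Path,
    *,
    name: str | None = None,
    exclude: Iterable[str] = _EXCLUDED_BY_DEFAULT,
) -> GenomeBuild:
    """Load a purpose-built arm-definition TSV into a :class:`GenomeBuild`.

    The file is tab-delimited with a header row naming the columns
    ``chromosome length centromere_start centromere_end p_telomere_assembled
    q_telomere_assembled``; coordinates are 1-based inclusive on disk and
    converted to 0-based half-open here. Chromosomes listed in *exclude*
    (default: Y and mitochondrial) are kept in the build but left out of
    scoring.
    """
    path = Path(path)
    exclude = frozenset(exclude)
    chromosomes: list[tuple[str, int]] = []
    arms: list[ChromosomeArm] = []
    included: set[str] = set()
    with path.open(newline="") as fh:
        reader = csv.DictReader(fh, delimiter="\t")
        missing = set(_ARM_TABLE_COLUMNS) - set(reader.fieldnames or ())
        if missing:
            raise BuildError(f"{path.name}: missing column(s) {sorted(missing)}")
        for i, row in enumerate(reader, start=2):
            chrom = row["chromosome"].strip()
            where = f"{path.name} row {i} ({chrom})"
            length = _parse_int(row["length"], where)
            cen_start_1 = _parse_int(row["centromere_start"], where)
            cen_end_1 = _parse_int(row["centromere_end"], where)
            # 1-based inclusive -> 0-based half-open
            cen_start, cen_end = cen_start_1 - 1, cen_end_1
            if not (0 < cen_start < cen_end <= length) or cen_end >= length:
                raise BuildError(
                    f"{where}: centromere [{cen_start_1}, {cen_end_1}] does not fall "
                    f"strictly inside the chromosome (length {length})"
                )
            chromosomes.append((chrom, length))
            arms.append(
                ChromosomeArm(
                    chrom, "p", 0, cen_start,
                    _parse_bool(row["p_telomere_assembled"], where),
                )
            )
            arms.append(
                ChromosomeArm(
                    chrom, "q", cen_end, length,
                    _parse_bool(row["q_telomere_assembled"], where),
                )
            )
            if chrom not in exclude:
                included.add(chrom)
    if not chromosomes:
        raise BuildError(f"{path.name}: no chromosomes")
    return GenomeBuild(
        name=name or path.stem,
        chromosomes=tuple(chromosomes),
        arms=tuple(arms),
        included_chromosomes=frozenset(included),
    )


def load_cytoband(
    path: str | Path,
    *,
    name: str | None = None,
    acrocentric_p: Iterable[str] = DEFAULT_ACROCENTRIC_P,
    exclude: Iterable[str] = _EXCLUDED_BY_DEFAULT,
) -> GenomeBuild:
    """Derive a :class:`GenomeBuild` from a UCSC-style cytoband file.

    Arm boundaries come from the union of the two ``acen`` bands per
    chromosome; chromosome length is the maximum band end (cytoBand files are
    0-based half-open already). Telomere-assembly flags default to assembled
    except for p arms of chromosomes in *acrocentric_p*. Chromosomes without
    an ``acen`` band are skipped and recorded in ``build_warnings`` on the
    returned object.
    """
    path = Path(path)
    acro = frozenset(acrocentric_p)
    exclude = frozenset(exclude)
    length: dict[str, int] = {}
    acen: dict[str, list[tuple[int, int]]] = {}
    order: list[str] = []
    with path.open() as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 5:
                raise BuildError(f"{path.name} line {lineno}: expected 5 columns")
            chrom, start_s, end_s, _band, stain = parts[:5]
            start = _parse_int(start_s, f"{path.name} line {lineno}")
            end = _parse_int(end_s, f"{path.name} line {lineno}")
            if chrom not in length:
                order.append(chrom)
                length[chrom] = 0
            length[chrom] = max(length[chrom], end)
            if stain == "acen":
                acen.setdefault(chrom, []).append((start, end))
    chromosomes: list[tuple[str, int]] = []
    arms: list[ChromosomeArm] = []
    included: set[str] = set()
    warnings: list[str] = []
    for chrom in order:
        chromosomes.append((chrom, length[chrom]))
        bands = acen.get(chrom)
        if not bands:
            warnings.append(f"{chrom}: no acen band, excluded from scoring")
            continue
        cen_start = min(s for s, _ in bands)
        cen_end = max(e for _, e in bands)
        arms.append(ChromosomeArm(chrom, "p", 0, cen_start, chrom not in acro))
        arms.append(ChromosomeArm(chrom, "q", cen_end, length[chrom], True))
        if chrom not in exclude:
            included.add(chrom)
    build = GenomeBuild(
        name=name or path.stem,
        chromosomes=tuple(chromosomes),
        arms=tuple(arms),
        included_chromosomes=frozenset(included),
    )
    object.__setattr__(build, "build_warnings", tuple(warnings))
    return build


def hg19_build() -> GenomeBuild:
    """The bundled hg19 build (UCSC lengths and centromere gaps), autosomes + X."""
    with resources.as_file(
        resources.files("hrdgis.data").joinpath("hg19_arms.tsv")
    ) as p:
        return load_arm_table(p, name="hg19")
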