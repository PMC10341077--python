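"""Genomic-instability scoring: PLOH, PCNA, PTCNA, their sum, and HRD calls.

The score quantifies genome-wide scarring from an allele-specific
copy-number profile. Three components, each a percentage, are summed into a
single genomic-instability score (GIS):

* **PLOH** — percent of the observed genome lying in loss-of-heterozygosity
  regions (minor-allele copy number 0) that are larger than 10 Mb yet
  smaller than a complete chromosome arm.
* **PCNA** — percent of the observed genome deviating from each
  chromosome's *expected* allele-specific state (the state covering the
  largest part of the chromosome), counting only deviant regions larger
  than 10 Mb that are not whole-arm events.
* **PTCNA** — percent of evaluable telomeres whose terminal segment (within
  5 Mb of a chromosome end, longer than 1 Mb) deviates from the expected
  state, again excluding whole-arm events.

The *observed genome* is the arm territory actually covered by segments —
FFPE samples lose territory to poor DNA quality, and all denominators adapt
to what could be sequenced. Samples whose observed fraction falls below a
floor, or with no evaluable telomere, are reported unevaluable rather than
scored.

A sample is GI-positive when GIS >= cutoff (default 83), and HRD-positive
when GI-positive and/or carrying a pathogenic BRCA1/2 mutation.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable

from .genome import GenomeBuild
from .profiles_io import AlleleSpecificSegment, BRCAStatus, CopyNumberProfile

__all__ = [
    "ScoreParams",
    "ExpectedState",
    "Region",
    "TelomereVerdict",
    "GISResult",
    "HRDCall",
    "expected_state",
    "compute_ploh",
    "compute_pcna",
    "compute_ptcna",
    "compute_gis",
    "call_hrd",
]


@dataclass(frozen=True)
class ScoreParams:
    """Tunable scoring parameters.

    cutoff
        GI-positive threshold on the summed score (``gis >= cutoff``).
    max_gap_bp
        Unobserved gap across which same-component runs may fuse.
    whole_arm_fraction
        A region is a whole-arm event (excluded) when its observed overlap
        with an arm reaches this fraction of that arm's observed territory.
    min_observed_fraction
        Evaluability floor on observed / assembled-reference territory.
    telomere_window_bp
        Maximum distance of a segment boundary from a chromosome end for
        the segment to represent the telomere (strict ``<``).
    min_region_bp
        Size filter for PLOH and PCNA regions (strict ``>`` on the span).
    min_telomeric_segment_bp
        Size filter for telomeric anchoring segments (strict ``>``).
    fuse_mixed_deviant_states
        Whether PCNA runs fuse adjacent deviant segments of different
        deviant states (default) or require a uniform state per run.
    count_homdel_as_loh
        Whether homozygous deletions (total 0) count as LOH territory;
        regions containing them are flagged either way.
    """

    cutoff: float = 83.0
    max_gap_bp: int = 1_000_000
    whole_arm_fraction: float = 0.9
    min_observed_fraction: float = 0.4
    telomere_window_bp: int = 5_000_000
    min_region_bp: int = 10_000_000
    min_telomeric_segment_bp: int = 1_000_000
    fuse_mixed_deviant_states: bool = True
    count_homdel_as_loh: bool = True


@dataclass(frozen=True)
class ExpectedState:
    """The allele-specific state covering the largest part of one chromosome."""

    chromosome: str
    total_cn: int
    minor_cn: int
    covered_bp: int

    @property
    def state(self) -> tuple[int, int]:
        return (self.total_cn, self.minor_cn)


@dataclass(frozen=True)
class Region:
    """A contributing (qualifying) region for one score component."""

    chromosome: str
    start: int
    end: int
    observed_bp: int
    contains_homozygous_deletion: bool = False

    @property
    def span_bp(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class TelomereVerdict:
    chromosome: str
    arm: str
    evaluable: bool
    altered: bool
    reason: str
    anchor: tuple[int, int] | None = None


@dataclass(frozen=True)
class GISResult:
    sample_id: str
    ploh_pct: float | None
    pcna_pct: float | None
    ptcna_pct: float | None
    gis: float | None
    observed_genome_bp: int
    observed_fraction: float
    evaluable: bool
    gi_positive: bool | None
    expected_states: tuple[ExpectedState, ...] = ()
    contributing_regions: dict = field(default_factory=dict)
    telomeres: tuple[TelomereVerdict, ...] = ()


@dataclass(frozen=True)
class HRDCall:
    sample_id: str
    gi_positive: bool | None
    brca: str
    hrd_status: str  # positive | negative | unevaluable


# -- internal interval machinery ------------------------------------------


@dataclass(frozen=True)
class _Atom:
    """An observed, arm-clipped piece of one segment."""

    start: int
    end: int
    state: tuple[int, int]
    arm: str  # "p" or "q"
    segment: AlleleSpecificSegment

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass
class _Run:
    """A maximal run of flagged atoms, possibly fused across small gaps."""

    atoms: list[_Atom]

    @property
    def start(self) -> int:
        return self.atoms[0].start

    @property
    def end(self) -> int:
        return self.atoms[-1].end

    @property
    def span(self) -> int:
        return self.end - self.start

    @property
    def observed_bp(self) -> int:
        return sum(a.length for a in self.atoms)

    def arm_overlap(self, arm: str) -> int:
        return sum(a.length for a in self.atoms if a.arm == arm)


class _ChromData:
    """Everything the component rules need about one chromosome, computed once."""

    __slots__ = ("chromosome", "segments", "atoms", "arm_obs", "expected", "_dev_runs")

    def __init__(
        self,
        build: GenomeBuild,
        chromosome: str,
        segments: list[AlleleSpecificSegment],
    ) -> None:
        self.chromosome = chromosome
        self.segments = segments
        p, q = build.arms_of(chromosome)
        atoms: list[_Atom] = []
        for seg in segments:
            for s, e in seg.pieces:
                for arm in (p, q):
                    cs, ce = max(s, arm.start), min(e, arm.end)
                    if cs < ce:
                        atoms.append(_Atom(cs, ce, seg.state, arm.arm, seg))
        atoms.sort(key=lambda a: a.start)
        self.atoms = atoms
        self.arm_obs = {"p": 0, "q": 0}
        coverage: dict[tuple[int, int], int] = {}
        for a in atoms:
            self.arm_obs[a.arm] += a.length
            coverage[a.state] = coverage.get(a.state, 0) + a.length
        if coverage:
            # largest coverage; ties toward smaller total, then smaller minor
            best = min(coverage.items(), key=lambda kv: (-kv[1], kv[0][0], kv[0][1]))
            (total, minor), covered = best
            self.expected = ExpectedState(chromosome, total, minor, covered)
        else:
            self.expected = None
        self._dev_runs: list[_Run] | None = None

    @property
    def observed_bp(self) -> int:
        return self.arm_obs["p"] + self.arm_obs["q"]

    def deviation_runs(self, params: ScoreParams) -> list[_Run]:
        if self._dev_runs is None:
            if self.expected is None:
                self._dev_runs = []
            else:
                exp = self.expected.state
                self._dev_runs = _build_runs(
                    self.atoms,
                    [a.state != exp for a in self.atoms],
                    params.max_gap_bp,
                    uniform_state=not params.fuse_mixed_deviant_states,
                )
        return self._dev_runs


def _profile_data(
    profile: CopyNumberProfile, build: GenomeBuild
) -> dict[str, _ChromData]:
    by_chrom: dict[str, list[AlleleSpecificSegment]] = {}
    for seg in profile.segments:
        if seg.chromosome in build.included_chromosomes:
            by_chrom.setdefault(seg.chromosome, []).append(seg)
    order = {name: i for i, (name, _) in enumerate(build.chromosomes)}
    return {
        chrom: _ChromData(build, chrom, segs)
        for chrom, segs in sorted(by_chrom.items(), key=lambda kv: order[kv[0]])
    }


def _build_runs(
    atoms: list[_Atom],
    flagged: list[bool],
    max_gap_bp: int,
    *,
    uniform_state: bool = False,
) -> list[_Run]:
    """Maximal runs of flagged atoms.

    A run extends across an unobserved gap of at most *max_gap_bp*; any
    observed non-flagged atom breaks it. With *uniform_state* a change of
    state between flagged neighbours also breaks the run.
    """
    runs: list[_Run] = []
    current: list[_Atom] | None = None
    for atom, flag in zip(atoms, flagged):
        if not flag:
            if current:
                runs.append(_Run(current))
            current = None
            continue
        if current is not None:
            gap = atom.start - current[-1].end
            if gap > max_gap_bp or (uniform_state and atom.state != current[-1].state):
                runs.append(_Run(current))
                current = None
        if current is None:
            current = [atom]
        else:
            current.append(atom)
    if current:
        runs.append(_Run(current))
    return runs


def _is_whole_arm(run: _Run, arm_observed: dict[str, int], fraction: float) -> bool:
    """A run is a whole-arm event when it saturates either arm's observed territory."""
    for arm in ("p", "q"):
        overlap = run.arm_overlap(arm)
        if overlap > 0 and overlap >= fraction * arm_observed[arm]:
            return True
    return False


def _qualifying_regions(
    cd: _ChromData, runs: Iterable[_Run], params: ScoreParams
) -> list[Region]:
    regions = []
    for run in runs:
        if run.span <= params.min_region_bp:
            continue
        if _is_whole_arm(run, cd.arm_obs, params.whole_arm_fraction):
            continue
        regions.append(
            Region(
                chromosome=cd.chromosome,
                start=run.start,
                end=run.end,
                observed_bp=run.observed_bp,
                contains_homozygous_deletion=any(
                    a.state[0] == 0 for a in run.atoms
                ),
            )
        )
    return regions


# -- operations ------------------------------------------------------------


def expected_state(
    profile: CopyNumberProfile, build: GenomeBuild, chromosome: str
) -> ExpectedState | None:
    """The (total, minor) state covering the largest observed part of a chromosome.

    Coverage is arm-overlapping observed territory. Ties break toward the
    smaller total copy number, then the smaller minor copy number. Returns
    None for a chromosome with no observed arm territory; such a chromosome
    is skipped for PCNA/PTCNA and its telomeres leave the PTCNA denominator.
    """
    segs = profile.segments_of(chromosome)
    if not segs:
        return None
    return _ChromData(build, chromosome, segs).expected


def _loh_flag(state: tuple[int, int], params: ScoreParams) -> bool:
    total, minor = state
    if minor != 0:
        return False
    return True if params.count_homdel_as_loh else total >= 1


def _ploh_regions(
    data: dict[str, _ChromData], params: ScoreParams
) -> list[Region]:
    regions: list[Region] = []
    for cd in data.values():
        flags = [_loh_flag(a.state, params) for a in cd.atoms]
        runs = _build_runs(cd.atoms, flags, params.max_gap_bp)
        regions.extend(_qualifying_regions(cd, runs, params))
    return regions


def _pcna_regions(
    data: dict[str, _ChromData], params: ScoreParams
) -> list[Region]:
    regions: list[Region] = []
    for cd in data.values():
        regions.extend(_qualifying_regions(cd, cd.deviation_runs(params), params))
    return regions


def compute_ploh(
    profile: CopyNumberProfile,
    build: GenomeBuild,
    params: ScoreParams = ScoreParams(),
) -> tuple[float, list[Region]]:
    """Percent of the observed genome in qualifying LOH regions.

    LOH runs fuse segments with minor copy number 0 regardless of total copy
    number and across unobserved gaps up to ``max_gap_bp``; a run qualifies
    when its span exceeds ``min_region_bp`` and it is not a whole-arm event.
    """
    data = _profile_data(profile, build)
    observed = sum(cd.observed_bp for cd in data.values())
    if observed == 0:
        raise ValueError(f"{profile.sample_id}: no observed genome")
    regions = _ploh_regions(data, params)
    return 100.0 * sum(r.observed_bp for r in regions) / observed, regions


def compute_pcna(
    profile: CopyNumberProfile,
    build: GenomeBuild,
    params: ScoreParams = ScoreParams(),
) -> tuple[float, list[Region]]:
    """Percent of the observed genome deviating from the expected states.

    Per chromosome, deviation territory is everything whose state differs
    from the chromosome's expected state; deviant runs fuse across gaps (and,
    by default, across differing deviant states) and qualify under the same
    size and whole-arm rules as PLOH. A chromosome with a single state never
    contributes: it defines its own expectation.
    """
    data = _profile_data(profile, build)
    observed = sum(cd.observed_bp for cd in data.values())
    if observed == 0:
        raise ValueError(f"{profile.sample_id}: no observed genome")
    regions = _pcna_regions(data, params)
    return 100.0 * sum(r.observed_bp for r in regions) / observed, regions


def _telomere_verdicts(
    data: dict[str, _ChromData],
    build: GenomeBuild,
    params: ScoreParams,
) -> list[TelomereVerdict]:
    verdicts: list[TelomereVerdict] = []
    for chrom in build.sorted_included():
        cd = data.get(chrom)
        length = build.chromosome_length(chrom)
        for arm_obj, side in zip(build.arms_of(chrom), ("p", "q")):
            verdicts.append(
                _one_telomere(cd, chrom, side, arm_obj.telomere_assembled, length, params)
            )
    return verdicts


def _one_telomere(
    cd: _ChromData | None,
    chrom: str,
    side: str,
    assembled: bool,
    length: int,
    params: ScoreParams,
) -> TelomereVerdict:
    if not assembled:
        return TelomereVerdict(chrom, side, False, False, "telomere not assembled")
    if cd is None or cd.expected is None:
        return TelomereVerdict(chrom, side, False, False, "no observed territory")
    window = params.telomere_window_bp
    if side == "p":
        candidates = [s for s in cd.segments if s.start < window]
        anchor = min(candidates, key=lambda s: s.start) if candidates else None
    else:
        candidates = [s for s in cd.segments if length - s.end < window]
        anchor = max(candidates, key=lambda s: s.end) if candidates else None
    if anchor is None:
        return TelomereVerdict(chrom, side, False, False, "no segment in telomere window")
    where = (anchor.start, anchor.end)
    if anchor.span <= params.min_telomeric_segment_bp:
        return TelomereVerdict(
            chrom, side, True, False, "anchoring segment too small", where
        )
    if anchor.state == cd.expected.state:
        return TelomereVerdict(
            chrom, side, True, False, "anchoring segment matches expected state", where
        )
    # the deviation run containing the anchor must not be a whole-arm event
    for run in cd.deviation_runs(params):
        if any(a.segment is anchor for a in run.atoms):
            if _is_whole_arm(run, cd.arm_obs, params.whole_arm_fraction):
                return TelomereVerdict(
                    chrom, side, True, False, "whole-arm alteration not counted", where
                )
            return TelomereVerdict(
                chrom, side, True, True, "terminal segment deviates", where
            )
    # anchor deviates but has no arm-observed base (fully centromeric piece)
    return TelomereVerdict(
        chrom, side, True, False, "anchor not observed on arm", where
    )


def compute_ptcna(
    profile: CopyNumberProfile,
    build: GenomeBuild,
    params: ScoreParams = ScoreParams(),
) -> tuple[float | None, list[TelomereVerdict]]:
    """Percent of evaluable telomeres carrying a copy-number alteration.

    A telomere is evaluable when its reference assembly reaches the
    chromosome end and some segment boundary lies within the telomere window
    (5 Mb) of that end; the chromosome must also have an expected state. The
    outermost such segment anchors the telomere, which counts as altered
    when the anchor spans more than 1 Mb, deviates from the expected state,
    and the deviation run containing it is not a whole-arm event. Returns
    ``None`` when no telomere is evaluable (the profile is then
    unevaluable).
    """
    data = _profile_data(profile, build)
    verdicts = _telomere_verdicts(data, build, params)
    n_eval = sum(v.evaluable for v in verdicts)
    n_alt = sum(v.altered for v in verdicts)
    if n_eval == 0:
        return None, verdicts
    return 100.0 * n_alt / n_eval, verdicts


def compute_gis(
    profile: CopyNumberProfile,
    build: GenomeBuild,
    params: ScoreParams = ScoreParams(),
) -> GISResult:
    """Score one profile: components, sum, evaluability, GI classification.

    Unevaluable (observed fraction below the floor, or no evaluable
    telomere) is a result state, not an error: components and classification
    come back empty.
    """
    data = _profile_data(profile, build)
    observed = sum(cd.observed_bp for cd in data.values())
    reference = build.assembled_reference_bp
    fraction = observed / reference if reference else 0.0
    states = tuple(cd.expected for cd in data.values() if cd.expected is not None)
    if observed == 0 or fraction < params.min_observed_fraction:
        return GISResult(
            sample_id=profile.sample_id,
            ploh_pct=None, pcna_pct=None, ptcna_pct=None, gis=None,
            observed_genome_bp=observed,
            observed_fraction=fraction,
            evaluable=False,
            gi_positive=None,
            expected_states=states,
        )
    loh_regions = _ploh_regions(data, params)
    cna_regions = _pcna_regions(data, params)
    ploh = 100.0 * sum(r.observed_bp for r in loh_regions) / observed
    pcna = 100.0 * sum(r.observed_bp for r in cna_regions) / observed
    verdicts = _telomere_verdicts(data, build, params)
    n_eval = sum(v.evaluable for v in verdicts)
    regions = {"ploh": loh_regions, "pcna": cna_regions}
    if n_eval == 0:
        return GISResult(
            sample_id=profile.sample_id,
            ploh_pct=None, pcna_pct=None, ptcna_pct=None, gis=None,
            observed_genome_bp=observed,
            observed_fraction=fraction,
            evaluable=False,
            gi_positive=None,
            expected_states=states,
            contributing_regions=regions,
            telomeres=tuple(verdicts),
        )
    ptcna = 100.0 * sum(v.altered for v in verdicts) / n_eval
    gis = ploh + pcna + ptcna
    return GISResult(
        sample_id=profile.sample_id,
        ploh_pct=ploh,
        pcna_pct=pcna,
        ptcna_pct=ptcna,
        gis=gis,
        observed_genome_bp=observed,
        observed_fraction=fraction,
        evaluable=True,
        gi_positive=gis >= params.cutoff,
        expected_states=states,
        contributing_regions=regions,
        telomeres=tuple(verdicts),
    )


def call_hrd(gis_result: GISResult, brca: str = BRCAStatus.UNKNOWN) -> HRDCall:
    """HRD-positive when GI-positive and/or pathogenic BRCA1/2.

    An unknown BRCA status behaves like wildtype for the call but is
    recorded as given. A sample with undefined GI and no pathogenic
    mutation is unevaluable.
    """
    brca = BRCAStatus.validate(brca)
    if brca == BRCAStatus.PATHOGENIC or gis_result.gi_positive is True:
        status = "positive"
    elif gis_result.gi_positive is None:
        status = "unevaluable"
    else:
        status = "negative"
    return HRDCall(
        sample_id=gis_result.sample_id,
        gi_positive=gis_result.gi_positive,
        brca=brca,
        hrd_status=status,
    )
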