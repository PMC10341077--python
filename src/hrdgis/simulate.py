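"""Synthetic allele-specific copy-number profiles with controlled instability.

The generator emulates the statistical structure of tumor-only segmentation
from FFPE material: a diploid-heterozygous baseline, interstitial LOH
tracts, interstitial copy-number alterations, telomeric alterations, and
patchy coverage (observation dropout). It emits integer allele-specific
states directly — the purity/ploidy-resolved product a segmentation caller
would hand downstream — so every scoring and calibration stage can be
exercised end to end without external data.

Event sizes are log-uniform; placement is uniform over arm interiors with
rejection of overlaps. Interstitial events are kept out of the telomere
windows so the three event classes map cleanly onto the three score
components.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

from .genome import GenomeBuild, hg19_build
from .profiles_io import AlleleSpecificSegment, CopyNumberProfile
from .score import ScoreParams, compute_gis

__all__ = [
    "SimulationError",
    "SimulationParams",
    "PlannedEvent",
    "simulate_profile",
    "simulate_cohort",
    "HRD_LIKE",
    "HRP_LIKE",
]

_MAX_RETRIES = 500


class SimulationError(RuntimeError):
    """Raised when requested events cannot be placed."""


@dataclass(frozen=True)
class SimulationParams:
    """Knobs of the profile generator.

    Defaults describe a quiet (HR-proficient-like) genome; see
    :data:`HRD_LIKE` / :data:`HRP_LIKE` for the cohort presets.
    """

    build: GenomeBuild | None = None
    base_state: tuple[int, int] = (2, 1)
    n_loh_events: int = 0
    n_cna_events: int = 0
    n_telomeric_events: int = 0
    size_min: int = 5_000_000
    size_max: int = 40_000_000
    telomere_window_bp: int = 5_000_000
    dropout_fraction: float = 0.0
    seed: int = 0
    sample_id: str = "sim"

    def __post_init__(self) -> None:
        if self.size_min > self.size_max or self.size_min <= 0:
            raise ValueError("size_min must be positive and <= size_max")
        if not 0.0 <= self.dropout_fraction < 1.0:
            raise ValueError("dropout_fraction must be in [0, 1)")
        t, m = self.base_state
        if m > t - m or m < 0:
            raise ValueError(f"invalid base state {self.base_state}")


@dataclass(frozen=True)
class PlannedEvent:
    """One planted alteration, with its nominal filter verdicts."""

    kind: str  # "loh" | "cna" | "telomeric"
    chromosome: str
    start: int
    end: int
    total_cn: int
    minor_cn: int
    copy_neutral: bool = False
    passes_size_filter: bool = True

    @property
    def span(self) -> int:
        return self.end - self.start

    def to_dict(self) -> dict:
        return {
            "kind": self.kind,
            "chromosome": self.chromosome,
            "start": self.start,
            "end": self.end,
            "total_cn": self.total_cn,
            "minor_cn": self.minor_cn,
            "copy_neutral": self.copy_neutral,
            "passes_size_filter": self.passes_size_filter,
        }


def _draw_size(rng: np.random.Generator, lo: int, hi: int) -> int:
    if lo == hi:
        return lo
    return int(round(math.exp(rng.uniform(math.log(lo), math.log(hi)))))


def _overlaps(events: list[PlannedEvent], chrom: str, start: int, end: int) -> bool:
    return any(
        e.chromosome == chrom and e.start < end and start < e.end for e in events
    )


def _event_states(
    kind: str, base: tuple[int, int], rng: np.random.Generator
) -> tuple[int, int, bool]:
    t, m = base
    if kind == "loh":
        copy_neutral = bool(rng.integers(2))
        total = t if copy_neutral else max(t - 1, 1)
        return total, 0, copy_neutral
    gain = int(rng.integers(1, 3))  # +1 or +2 copies
    return t + gain, m, False


def simulate_profile(
    params: SimulationParams,
) -> tuple[CopyNumberProfile, list[PlannedEvent]]:
    """Generate one profile plus the ledger of planted events.

    Deterministic for a given seed. Telomeric events anchor at assembled
    chromosome termini; interstitial LOH/CNA events land in arm interiors
    (outside the telomere windows) without overlapping each other. Dropout
    then removes randomly placed observation gaps; the ledger keeps the
    planted (pre-dropout) intervals.
    """
    build = params.build if params.build is not None else hg19_build()
    rng = np.random.default_rng(params.seed)
    chroms = build.sorted_included()
    events: list[PlannedEvent] = []

    # telomeric events first: they need the scarce terminal territory
    telomeres = [
        (chrom, arm)
        for chrom in chroms
        for arm in build.arms_of(chrom)
        if arm.telomere_assembled
    ]
    for _ in range(params.n_telomeric_events):
        placed = False
        for _attempt in range(_MAX_RETRIES):
            chrom, arm = telomeres[rng.integers(len(telomeres))]
            size = _draw_size(rng, params.size_min, params.size_max)
            if size > arm.length:
                continue
            if arm.arm == "p":
                start, end = arm.start, arm.start + size
            else:
                start, end = arm.end - size, arm.end
            if _overlaps(events, chrom, start, end):
                continue
            t_cn, m_cn, _ = _event_states("cna", params.base_state, rng)
            events.append(
                PlannedEvent(
                    "telomeric", chrom, start, end, t_cn, m_cn,
                    passes_size_filter=size > 1_000_000,
                )
            )
            placed = True
            break
        if not placed:
            raise SimulationError(
                "could not place a telomeric event without overlap; "
                "reduce n_telomeric_events or event sizes"
            )

    interior: list[tuple[str, int, int]] = []
    for chrom in chroms:
        p, q = build.arms_of(chrom)
        length = build.chromosome_length(chrom)
        w = params.telomere_window_bp
        interior.append((chrom, p.start + w, p.end))
        interior.append((chrom, q.start, max(q.start, length - w)))
    interior = [(c, s, e) for c, s, e in interior if e - s > 0]
    weights = np.asarray([e - s for _, s, e in interior], dtype=float)
    weights /= weights.sum()

    for kind, count in (("loh", params.n_loh_events), ("cna", params.n_cna_events)):
        for _ in range(count):
            placed = False
            for _attempt in range(_MAX_RETRIES):
                idx = rng.choice(len(interior), p=weights)
                chrom, lo, hi = interior[idx]
                size = _draw_size(rng, params.size_min, params.size_max)
                if size > hi - lo:
                    continue
                start = int(rng.integers(lo, hi - size + 1))
                end = start + size
                if _overlaps(events, chrom, start, end):
                    continue
                t_cn, m_cn, neutral = _event_states(kind, params.base_state, rng)
                events.append(
                    PlannedEvent(
                        kind, chrom, start, end, t_cn, m_cn,
                        copy_neutral=neutral,
                        passes_size_filter=size > 10_000_000,
                    )
                )
                placed = True
                break
            if not placed:
                raise SimulationError(
                    f"could not place a {kind} event without overlap; "
                    "reduce event counts or sizes"
                )

    coverage = _dropout_coverage(build, chroms, params, rng)
    segments = _events_to_segments(build, chroms, events, coverage, params)
    profile = CopyNumberProfile(
        sample_id=params.sample_id, segments=tuple(segments)
    )
    return profile, events


def _dropout_coverage(
    build: GenomeBuild,
    chroms: Sequence[str],
    params: SimulationParams,
    rng: np.random.Generator,
) -> dict[str, list[tuple[int, int]]]:
    """Arm territory per chromosome, minus randomly placed observation gaps."""
    coverage = {}
    for chrom in chroms:
        p, q = build.arms_of(chrom)
        coverage[chrom] = [(p.start, p.end), (q.start, q.end)]
    if params.dropout_fraction == 0.0:
        return coverage
    total = sum(e - s for ivs in coverage.values() for s, e in ivs)
    target = params.dropout_fraction * total
    lengths = np.asarray([build.chromosome_length(c) for c in chroms], dtype=float)
    weights = lengths / lengths.sum()
    removed = 0
    # bounded loop: each draw removes territory or hits an existing gap
    for _ in range(100_000):
        if removed >= target:
            break
        gap = _draw_size(rng, 100_000, 5_000_000)
        chrom = chroms[rng.choice(len(chroms), p=weights)]
        length = build.chromosome_length(chrom)
        if gap >= length:
            continue
        start = int(rng.integers(0, length - gap))
        removed += _subtract(coverage[chrom], start, start + gap)
    return coverage


def _subtract(intervals: list[tuple[int, int]], start: int, end: int) -> int:
    """Remove [start, end) from an interval list in place; return bp removed."""
    out: list[tuple[int, int]] = []
    removed = 0
    for s, e in intervals:
        if e <= start or end <= s:
            out.append((s, e))
            continue
        removed += min(e, end) - max(s, start)
        if s < start:
            out.append((s, start))
        if end < e:
            out.append((end, e))
    intervals[:] = out
    return removed


def _events_to_segments(
    build: GenomeBuild,
    chroms: Sequence[str],
    events: list[PlannedEvent],
    coverage: dict[str, list[tuple[int, int]]],
    params: SimulationParams,
) -> list[AlleleSpecificSegment]:
    base_t, base_m = params.base_state
    segments: list[AlleleSpecificSegment] = []
    for chrom in chroms:
        chrom_events = sorted(
            (e for e in events if e.chromosome == chrom), key=lambda e: e.start
        )
        # state partition of the chromosome: events override the base state
        cuts: list[tuple[int, int, tuple[int, int]]] = []
        pos = 0
        length = build.chromosome_length(chrom)
        for ev in chrom_events:
            if pos < ev.start:
                cuts.append((pos, ev.start, (base_t, base_m)))
            cuts.append((ev.start, ev.end, (ev.total_cn, ev.minor_cn)))
            pos = ev.end
        if pos < length:
            cuts.append((pos, length, (base_t, base_m)))
        # intersect with observed coverage
        for cs, ce in coverage[chrom]:
            for s, e, (t_cn, m_cn) in cuts:
                os_, oe = max(s, cs), min(e, ce)
                if os_ < oe:
                    segments.append(
                        AlleleSpecificSegment(chrom, os_, oe, t_cn, m_cn)
                    )
    segments.sort(key=lambda s: (chroms.index(s.chromosome), s.start))
    return segments


#: Event-count presets emulating a heavily scarred HR-deficient genome and a
#: quiet HR-proficient one, under 10% observation dropout (FFPE-like).
HRD_LIKE = dict(n_loh_events=36, n_cna_events=22, n_telomeric_events=26,
                dropout_fraction=0.1)
HRP_LIKE = dict(n_loh_events=3, n_cna_events=3, n_telomeric_events=2,
                dropout_fraction=0.1)


def simulate_cohort(
    n_hrd: int,
    n_hrp: int,
    hrd_params: SimulationParams | None = None,
    hrp_params: SimulationParams | None = None,
    label_noise: float = 0.0,
    seed: int = 0,
    build: GenomeBuild | None = None,
    score_params: ScoreParams = ScoreParams(),
    count_dispersion: float = 0.25,
) -> pd.DataFrame:
    """Simulate a calibration cohort: per-sample GIS plus reference labels.

    Event counts vary per sample: a per-tumor scar-burden multiplier
    (lognormal with sigma *count_dispersion*, clipped to [0.5, 1.5]) scales
    each preset's means before Poisson draws. Real cohorts show continuous
    burden heterogeneity rather than two tight clusters, and the resulting
    score spread is what makes a threshold identifiable at all. The
    reference label is the sample's own GI status at
    ``score_params.cutoff``, flipped with probability *label_noise* —
    emulating an imperfect reference assay. Unevaluable samples keep a NaN
    score and are labeled by their generating group. Deterministic per seed.
    """
    if n_hrd <= 0 or n_hrp <= 0:
        raise ValueError("cohort must contain both classes")
    build = build if build is not None else hg19_build()
    hrd_params = hrd_params if hrd_params is not None else SimulationParams(**HRD_LIKE)
    hrp_params = hrp_params if hrp_params is not None else SimulationParams(**HRP_LIKE)
    rng = np.random.default_rng(seed)
    rows = []
    # one event per telomere at most: cap jittered draws below saturation
    telomere_cap = max(
        1,
        sum(
            arm.telomere_assembled
            for chrom in build.sorted_included()
            for arm in build.arms_of(chrom)
        )
        - 5,
    )
    groups = [("hrd", hrd_params)] * n_hrd + [("hrp", hrp_params)] * n_hrp
    for i, (group, base) in enumerate(groups):
        child_seed = int(rng.integers(0, 2**31 - 1))
        burden = float(np.clip(np.exp(rng.normal(0.0, count_dispersion)), 0.5, 1.5))
        p = replace(
            base,
            build=build,
            seed=child_seed,
            sample_id=f"{group}_{i:04d}",
            n_loh_events=int(rng.poisson(base.n_loh_events * burden)),
            n_cna_events=int(rng.poisson(base.n_cna_events * burden)),
            n_telomeric_events=min(
                int(rng.poisson(base.n_telomeric_events * burden)), telomere_cap
            ),
        )
        profile, _ = simulate_profile(p)
        result = compute_gis(profile, build, score_params)
        if result.gis is not None:
            status = result.gis >= score_params.cutoff
        else:
            status = group == "hrd"
        if label_noise > 0 and rng.random() < label_noise:
            status = not status
        rows.append(
            {
                "sample": p.sample_id,
                "gis": float("nan") if result.gis is None else result.gis,
                "reference_status": "positive" if status else "negative",
            }
        )
    return pd.DataFrame(rows)
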