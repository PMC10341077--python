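"""Shared fixtures: the two-chromosome toy genome and a randomized
toy-case generator used by the per-base equivalence tests."""

from __future__ import annotations

import numpy as np
import pytest

from hrdgis.genome import ChromosomeArm, GenomeBuild
from hrdgis.profiles_io import AlleleSpecificSegment, CopyNumberProfile
from hrdgis.score import ScoreParams

MB = 1_000_000


def make_toy_build() -> GenomeBuild:
    """chrA 100 Mb (centromere [40,41) Mb), chrB 60 Mb (centromere [30,31) Mb)."""
    return GenomeBuild(
        name="toy",
        chromosomes=(("chrA", 100 * MB), ("chrB", 60 * MB)),
        arms=(
            ChromosomeArm("chrA", "p", 0, 40 * MB),
            ChromosomeArm("chrA", "q", 41 * MB, 100 * MB),
            ChromosomeArm("chrB", "p", 0, 30 * MB),
            ChromosomeArm("chrB", "q", 31 * MB, 60 * MB),
        ),
        included_chromosomes=frozenset({"chrA", "chrB"}),
    )


def make_toy_profile(loh_end_mb: int = 15) -> CopyNumberProfile:
    """Diploid-heterozygous toy genome with one terminal copy-neutral LOH on chrA-p."""
    return CopyNumberProfile(
        sample_id="S1",
        segments=(
            AlleleSpecificSegment("chrA", 0, loh_end_mb * MB, 2, 0),
            AlleleSpecificSegment("chrA", loh_end_mb * MB, 100 * MB, 2, 1),
            AlleleSpecificSegment("chrB", 0, 60 * MB, 2, 1),
        ),
    )


@pytest.fixture
def toy_build() -> GenomeBuild:
    return make_toy_build()


@pytest.fixture
def toy_profile() -> CopyNumberProfile:
    return make_toy_profile()


#: Scaled-down parameters for per-base oracle work on small coordinates.
SMALL_PARAMS = ScoreParams(
    max_gap_bp=5,
    min_observed_fraction=0.0,
    telomere_window_bp=30,
    min_region_bp=60,
    min_telomeric_segment_bp=15,
)

_STATES = [(2, 1), (2, 0), (1, 0), (3, 1), (4, 2), (3, 0), (0, 0), (4, 1)]
_WEIGHTS = np.array([0.40, 0.15, 0.10, 0.12, 0.05, 0.05, 0.05, 0.08])


def random_toy_case(
    rng: np.random.Generator,
) -> tuple[GenomeBuild, CopyNumberProfile]:
    """A random small build (<= 5 chromosomes) and a random profile on it.

    Coordinates are a few hundred to a couple of thousand bases so the
    per-base oracle stays cheap; segment states, gaps and telomere-assembly
    flags vary enough to hit every rule branch.
    """
    n_chrom = int(rng.integers(2, 6))
    chromosomes = []
    arms = []
    for i in range(n_chrom):
        name = f"chr{i + 1}"
        length = int(rng.integers(400, 1600))
        cen_start = int(rng.integers(int(0.3 * length), int(0.6 * length)))
        cen_len = int(rng.integers(10, 40))
        chromosomes.append((name, length))
        arms.append(
            ChromosomeArm(name, "p", 0, cen_start, bool(rng.random() < 0.8))
        )
        arms.append(
            ChromosomeArm(
                name, "q", cen_start + cen_len, length, bool(rng.random() < 0.8)
            )
        )
    build = GenomeBuild(
        name="rand",
        chromosomes=tuple(chromosomes),
        arms=tuple(arms),
        included_chromosomes=frozenset(n for n, _ in chromosomes),
    )
    segments: list[AlleleSpecificSegment] = []
    for name, length in chromosomes:
        if rng.random() < 0.1:  # leave whole chromosome unobserved sometimes
            continue
        pos = 0
        while pos < length - 5 and len(segments) < 50:
            if rng.random() < 0.2:
                pos += int(rng.integers(1, 80))
                continue
            seg_len = int(rng.integers(20, 300))
            end = min(pos + seg_len, length)
            state = _STATES[rng.choice(len(_STATES), p=_WEIGHTS / _WEIGHTS.sum())]
            segments.append(
                AlleleSpecificSegment(name, pos, end, state[0], state[1])
            )
            pos = end + (int(rng.integers(1, 30)) if rng.random() < 0.4 else 0)
    profile = CopyNumberProfile(sample_id="rand", segments=tuple(segments))
    return build, profile
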