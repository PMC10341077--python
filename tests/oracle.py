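"""Independent per-base reference implementation of the scoring rules.

Paints every base of a (small) genome with its observed allele-specific
state and applies the component rules positionally with numpy arrays —
no interval arithmetic shared with the package. Intended for toy genomes
(a few chromosomes of a few thousand bases) where per-base work is cheap;
the strict size filters come in through the same ScoreParams object, so
scaled-down coordinates exercise identical logic.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from hrdgis.genome import GenomeBuild
from hrdgis.profiles_io import CopyNumberProfile
from hrdgis.score import ScoreParams


@dataclass
class OracleResult:
    observed_bp: int
    ploh: float | None
    pcna: float | None
    ptcna: float | None
    expected: dict  # chromosome -> (total, minor)
    n_telomeres_evaluable: int
    n_telomeres_altered: int

    @property
    def gis(self) -> float | None:
        if None in (self.ploh, self.pcna, self.ptcna):
            return None
        return self.ploh + self.pcna + self.ptcna


def _paint(profile: CopyNumberProfile, build: GenomeBuild, chrom: str):
    length = build.chromosome_length(chrom)
    p, q = build.arms_of(chrom)
    arm = np.zeros(length, dtype=np.int8)
    arm[p.start:p.end] = 1
    arm[q.start:q.end] = 2
    obs = np.zeros(length, dtype=bool)
    total = np.full(length, -1, dtype=np.int64)
    minor = np.full(length, -1, dtype=np.int64)
    for seg in profile.segments_of(chrom):
        for s, e in seg.pieces:
            obs[s:e] = True
            total[s:e] = seg.total_cn
            minor[s:e] = seg.minor_cn
    return arm, obs, total, minor


def _runs_from_flags(positions: np.ndarray, flags: np.ndarray, max_gap: int):
    """Group flagged observed-arm positions into runs.

    *positions* are all observed arm positions in order; a non-flagged
    position breaks the run, and a jump of more than ``max_gap`` unobserved
    bases between flagged neighbours breaks it too. Returns (first, last,
    member_index_list) per run.
    """
    runs = []
    current: list[int] | None = None
    prev_pos = None
    for pos, flag in zip(positions.tolist(), flags.tolist()):
        if not flag:
            if current is not None:
                runs.append(current)
            current = None
            prev_pos = pos
            continue
        if current is not None and pos - current[-1] - 1 > max_gap:
            runs.append(current)
            current = None
        if current is None:
            current = [pos]
        else:
            current.append(pos)
        prev_pos = pos
    if current is not None:
        runs.append(current)
    return runs


def _qualifying_bp(
    positions: np.ndarray,
    flags: np.ndarray,
    arm_at: np.ndarray,
    params: ScoreParams,
) -> tuple[int, list[dict]]:
    """Summed member count of runs passing the size and whole-arm filters."""
    arm_obs = {1: int(np.sum(arm_at == 1)), 2: int(np.sum(arm_at == 2))}
    pos_to_arm = dict(zip(positions.tolist(), arm_at.tolist()))
    total = 0
    kept = []
    for members in _runs_from_flags(positions, flags, params.max_gap_bp):
        span = members[-1] - members[0] + 1
        if span <= params.min_region_bp:
            continue
        overlap = {1: 0, 2: 0}
        for pos in members:
            overlap[pos_to_arm[pos]] += 1
        whole_arm = any(
            overlap[a] > 0 and overlap[a] >= params.whole_arm_fraction * arm_obs[a]
            for a in (1, 2)
        )
        if whole_arm:
            continue
        total += len(members)
        kept.append({"start": members[0], "end": members[-1] + 1, "bp": len(members)})
    return total, kept


def oracle_components(
    profile: CopyNumberProfile,
    build: GenomeBuild,
    params: ScoreParams = ScoreParams(),
) -> OracleResult:
    observed_total = 0
    loh_bp = 0
    dev_bp = 0
    expected: dict[str, tuple[int, int]] = {}
    n_eval = 0
    n_alt = 0
    chroms = build.sorted_included()
    painted = {}
    for chrom in chroms:
        arm, obs, total, minor = _paint(profile, build, chrom)
        mask = obs & (arm > 0)
        painted[chrom] = (arm, obs, total, minor, mask)
        observed_total += int(mask.sum())
        if not mask.any():
            continue
        # expected state: per-base vote, ties toward smaller (total, minor)
        pairs = np.stack([total[mask], minor[mask]], axis=1)
        uniq, counts = np.unique(pairs, axis=0, return_counts=True)
        order = sorted(
            range(len(uniq)), key=lambda i: (-counts[i], uniq[i][0], uniq[i][1])
        )
        exp = (int(uniq[order[0]][0]), int(uniq[order[0]][1]))
        expected[chrom] = exp

    for chrom in chroms:
        if chrom not in expected:
            continue
        arm, obs, total, minor, mask = painted[chrom]
        positions = np.flatnonzero(mask)
        arm_at = arm[positions]
        loh = minor[positions] == 0
        if not params.count_homdel_as_loh:
            loh &= total[positions] >= 1
        dev = (total[positions] != expected[chrom][0]) | (
            minor[positions] != expected[chrom][1]
        )
        loh_bp += _qualifying_bp(positions, loh, arm_at, params)[0]
        dev_bp += _qualifying_bp(positions, dev, arm_at, params)[0]

        # telomeres, using the same per-base deviation runs for the
        # whole-arm exclusion
        dev_runs = _runs_from_flags(positions, dev, params.max_gap_bp)
        run_whole_arm = []
        arm_obs = {1: int(np.sum(arm_at == 1)), 2: int(np.sum(arm_at == 2))}
        pos_to_arm = dict(zip(positions.tolist(), arm_at.tolist()))
        pos_run: dict[int, int] = {}
        for ridx, members in enumerate(dev_runs):
            overlap = {1: 0, 2: 0}
            for pos in members:
                overlap[pos_to_arm[pos]] += 1
                pos_run[pos] = ridx
            run_whole_arm.append(
                any(
                    overlap[a] > 0
                    and overlap[a] >= params.whole_arm_fraction * arm_obs[a]
                    for a in (1, 2)
                )
            )
        length = build.chromosome_length(chrom)
        p_arm, q_arm = build.arms_of(chrom)
        segs = profile.segments_of(chrom)
        for side, assembled in (("p", p_arm.telomere_assembled),
                                ("q", q_arm.telomere_assembled)):
            if not assembled:
                continue
            if side == "p":
                cands = [s for s in segs if s.start < params.telomere_window_bp]
                anchor = min(cands, key=lambda s: s.start) if cands else None
            else:
                cands = [s for s in segs if length - s.end < params.telomere_window_bp]
                anchor = max(cands, key=lambda s: s.end) if cands else None
            if anchor is None:
                continue
            n_eval += 1
            if anchor.end - anchor.start <= params.min_telomeric_segment_bp:
                continue
            if (anchor.total_cn, anchor.minor_cn) == expected[chrom]:
                continue
            anchor_positions = [
                pos
                for s, e in anchor.pieces
                for pos in range(s, e)
                if mask[pos]
            ]
            if not anchor_positions:
                continue
            ridx = pos_run.get(anchor_positions[0])
            if ridx is not None and not run_whole_arm[ridx]:
                n_alt += 1

    ploh = 100.0 * loh_bp / observed_total if observed_total else None
    pcna = 100.0 * dev_bp / observed_total if observed_total else None
    ptcna = 100.0 * n_alt / n_eval if n_eval else None
    return OracleResult(
        observed_bp=observed_total,
        ploh=ploh,
        pcna=pcna,
        ptcna=ptcna,
        expected=expected,
        n_telomeres_evaluable=n_eval,
        n_telomeres_altered=n_alt,
    )
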