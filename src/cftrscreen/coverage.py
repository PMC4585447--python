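"""Per-base / per-amplicon coverage, quality-metric summaries and the
low-coverage gap report that flags target regions needing confirmatory
(Sanger) sequencing.

Depth counts read bases aligned to a position: deleted read bases add no
depth and soft-clips are ignored, so depth reflects base-callable evidence.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import AlignedRead, AmpliconPanel, GeneModel, TruthVariant, _overlaps

__all__ = [
    "CoverageProfile",
    "CoverageReport",
    "Gap",
    "compute_coverage",
    "summarize_coverage",
    "gap_report",
    "amplicon_read_counts",
    "low_coverage_runs",
]

MIN_CALL_COVERAGE = 50      # below this a target base is a no-call gap
HIGH_COVERAGE = 100         # "covered by more than 100 reads" (strict >)
UNIFORMITY_FRACTION = 0.2   # uniformity: bases >= 0.2 x mean target depth


class InputError(ValueError):
    pass


@dataclass
class CoverageProfile:
    depth: np.ndarray                   # per-base depth over the whole reference
    per_amplicon_depth: dict[str, float]
    n_reads_total: int
    n_reads_mapped: int
    n_reads_on_target: int

    def __post_init__(self) -> None:
        if not (self.n_reads_on_target <= self.n_reads_mapped <= self.n_reads_total):
            raise ValueError("read-count invariant violated")


@dataclass
class Gap:
    interval: tuple[int, int]
    max_depth: int
    reason: str                         # no_coverage | low_coverage


@dataclass
class CoverageReport:
    mean_depth: float
    uniformity: float
    pct_ge_100x: float
    pct_lt_50x: float
    on_target_fraction: float
    gaps: list[Gap] = field(default_factory=list)


def _ref_blocks(read: AlignedRead) -> list[tuple[int, int]]:
    """Reference intervals to which read bases are aligned (M ops only)."""
    blocks = []
    pos = read.start
    for op, n in read.cigar:
        if op == "M":
            blocks.append((pos, pos + n))
            pos += n
        elif op == "D":
            pos += n
    return blocks


def compute_coverage(reads: list[AlignedRead], panel: AmpliconPanel,
                     ref_length: int) -> CoverageProfile:
    """Per-base depth plus mapping/on-target tallies.

    A read is on-target when its alignment overlaps any target region by
    at least one base.
    """
    depth = np.zeros(ref_length, dtype=np.int64)
    on_target = 0
    block_counts: dict[tuple[int, int], int] = {}
    for r in reads:
        if r.end > ref_length or r.start < 0:
            raise InputError(f"read {r.name} outside reference bounds")
        for b in _ref_blocks(r):
            block_counts[b] = block_counts.get(b, 0) + 1
        if any(_overlaps((r.start, r.end), t) for t in panel.target_regions):
            on_target += 1
    for (s, e), n in block_counts.items():
        depth[s:e] += n

    per_amp = {a.id: float(depth[a.insert[0]:a.insert[1]].mean())
               for a in panel.amplicons}
    return CoverageProfile(depth=depth, per_amplicon_depth=per_amp,
                           n_reads_total=len(reads), n_reads_mapped=len(reads),
                           n_reads_on_target=on_target)


def low_coverage_runs(depth: np.ndarray, regions: tuple[tuple[int, int], ...],
                      threshold: int = MIN_CALL_COVERAGE) -> list[Gap]:
    """Maximal runs of target bases with depth < threshold, sorted and disjoint."""
    gaps: list[Gap] = []
    for s, e in sorted(regions):
        low = depth[s:e] < threshold
        if not low.any():
            continue
        edges = np.flatnonzero(np.diff(np.concatenate(([False], low, [False])).astype(int)))
        for lo, hi in zip(edges[::2], edges[1::2]):
            seg = depth[s + lo:s + hi]
            mx = int(seg.max())
            gaps.append(Gap(interval=(int(s + lo), int(s + hi)), max_depth=mx,
                            reason="no_coverage" if mx == 0 else "low_coverage"))
    return gaps


def summarize_coverage(profile: CoverageProfile, panel: AmpliconPanel) -> CoverageReport:
    """Table-1 style metrics over the target bases plus the gap list."""
    if not panel.target_regions:
        raise InputError("empty target set")
    target_depth = np.concatenate([profile.depth[s:e] for s, e in panel.target_regions])
    n = target_depth.size
    mean_depth = float(target_depth.mean())
    uniformity = float((target_depth >= UNIFORMITY_FRACTION * mean_depth).mean()) \
        if mean_depth > 0 else 0.0
    gaps = low_coverage_runs(profile.depth, panel.target_regions)
    gap_len = sum(g.interval[1] - g.interval[0] for g in gaps)
    on_target = (profile.n_reads_on_target / profile.n_reads_mapped
                 if profile.n_reads_mapped else 0.0)
    return CoverageReport(
        mean_depth=mean_depth,
        uniformity=uniformity,
        pct_ge_100x=float((target_depth > HIGH_COVERAGE).mean()),
        pct_lt_50x=gap_len / n,
        on_target_fraction=on_target,
        gaps=gaps,
    )


def amplicon_read_counts(reads: list[AlignedRead], panel: AmpliconPanel) -> np.ndarray:
    """Assign each read to the amplicon with maximal insert overlap (ties to
    the lower amplicon index); returns counts per amplicon."""
    counts = np.zeros(panel.n_amplicons, dtype=np.int64)
    inserts = [a.insert for a in panel.amplicons]
    cache: dict[tuple[int, int], int] = {}
    for r in reads:
        key = (r.start, r.end)
        idx = cache.get(key)
        if idx is None:
            overlaps = [min(e, key[1]) - max(s, key[0]) for s, e in inserts]
            best = max(overlaps)
            idx = overlaps.index(best) if best > 0 else -1
            cache[key] = idx
        if idx >= 0:
            counts[idx] += 1
    return counts


def gap_report(report: CoverageReport, panel: AmpliconPanel, model: GeneModel,
               catalog: list[TruthVariant] | None = None) -> list[dict]:
    """Confirmatory-sequencing worklist: one row per gap with overlapping
    exons, amplicons, and any known variants inside the gap."""
    rows = []
    for g in report.gaps:
        exons = [i + 1 for i, ex in enumerate(model.exons) if _overlaps(g.interval, ex)]
        amps = [a.id for a in panel.amplicons if _overlaps(g.interval, a.insert)]
        variants = []
        if catalog is not None:
            variants = [v.id for v in catalog
                        if v.vtype != "large_deletion" and _overlaps(v.locus, g.interval)]
        rows.append({
            "start": g.interval[0], "end": g.interval[1],
            "max_depth": g.max_depth, "reason": g.reason,
            "exons": exons, "amplicons": amps, "known_variants": variants,
        })
    return rows
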