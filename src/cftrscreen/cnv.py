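"""Multi-exon deletion/duplication detection from normalized amplicon depth.

Per-amplicon read counts are converted to RPKM (reads per kb of insert per
million on-target reads), standardized per amplicon across the cohort with a
robust median/SD z-score (ZRPKM), optionally denoised by removing the top
singular components of the matrix, then thresholded and segmented into runs
of consecutive outlier amplicons.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .simulate import AmpliconPanel, GeneModel, _overlaps

__all__ = [
    "ZrpkmMatrix",
    "CnvCall",
    "CnvThresholds",
    "StandardizationError",
    "compute_rpkm",
    "standardize_zrpkm",
    "call_cnv",
    "default_k_svd",
]

SD_FLOOR = 1e-6


class StandardizationError(ValueError):
    pass


@dataclass
class ZrpkmMatrix:
    amplicon_ids: list[str]
    sample_ids: list[str]
    rpkm: np.ndarray                    # amplicon x sample
    zrpkm: np.ndarray | None = None
    svd_components_removed: int = 0
    pools: np.ndarray | None = None     # per-amplicon primer-pool labels


@dataclass(frozen=True)
class CnvThresholds:
    """Detection cutoffs. The z thresholds sit at ~3x the residual noise left
    after component removal; min_run 3 exploits that any deletion spanning
    two whole exons covers at least six amplicons on this panel, so short
    noise runs can be rejected without losing multi-exon events."""
    del_z: float = -2.0
    dup_z: float = 2.0
    min_run: int = 3
    hom_ratio: float = 0.1      # run rpkm below this x cohort median => homozygous


@dataclass
class CnvCall:
    sample_id: str
    amplicon_run: tuple[int, int]       # inclusive amplicon index range
    exon_span: tuple[int, int]          # 1-based first-last exon touched
    state: str                          # hom_del | het_del | dup
    mean_zrpkm: float
    amplicon_ids: list[str] = field(default_factory=list)


def compute_rpkm(counts: dict[str, np.ndarray], panel: AmpliconPanel) -> ZrpkmMatrix:
    """RPKM matrix from per-sample per-amplicon read counts.

    rpkm[a, s] = count / (insert_kb(a) * on_target_reads(s) / 1e6).
    Samples with zero on-target reads are excluded with a warning.
    """
    if len(counts) < 2:
        raise StandardizationError("need at least 2 samples")
    sample_ids = []
    cols = []
    insert_kb = np.array([a.insert_length / 1000.0 for a in panel.amplicons])
    for sid, c in counts.items():
        c = np.asarray(c, dtype=float)
        total = c.sum()
        if total == 0:
            import warnings
            warnings.warn(f"sample {sid} has zero on-target reads; excluded")
            continue
        cols.append(c / (insert_kb * total / 1e6))
        sample_ids.append(sid)
    rpkm = np.column_stack(cols)
    return ZrpkmMatrix(amplicon_ids=[a.id for a in panel.amplicons],
                       sample_ids=sample_ids, rpkm=rpkm,
                       pools=np.array([a.pool for a in panel.amplicons]))


def default_k_svd(n_samples: int) -> int:
    """Batch-effect removal: no components for small cohorts, one otherwise."""
    return 0 if n_samples < 20 else 1


CLIP_Z = 3.0    # robust component estimation: outliers beyond this cannot
                # define the removed singular components (a rare large CNV
                # would otherwise dominate the decomposition at cohort scale)


DEL_RATIO_FLOOR = 0.4   # amplicons this far below the cohort profile are
                        # treated as copy-number signal, not normalization


def _size_factors(rpkm: np.ndarray, pools: np.ndarray | None = None) -> np.ndarray:
    """Median-of-ratios per-sample scale factors. A sample losing a large
    slice of its reads to a real multi-exon deletion would otherwise have
    its remaining per-million-normalized values inflated; the deleted
    amplicons themselves (ratio below DEL_RATIO_FLOOR) are excluded from
    the median so they cannot skew it either."""
    ref = np.median(rpkm, axis=1, keepdims=True)
    ok = ref[:, 0] > 0
    ratios = rpkm[ok] / ref[ok]
    factors = np.empty(rpkm.shape[1])
    for j in range(rpkm.shape[1]):
        col = ratios[:, j]
        informative = col[col >= DEL_RATIO_FLOOR]
        if informative.size < col.size // 2:
            informative = col
        factors[j] = max(np.median(informative), SD_FLOOR)
    return factors


def standardize_zrpkm(m: ZrpkmMatrix, k_svd: int = 0) -> ZrpkmMatrix:
    """Fill zrpkm: per-amplicon robust z-score across samples, then remove the
    top ``k_svd`` singular components (systematic batch/pool structure).

    Robustness choices: samples are rescaled by median-of-ratios size factors,
    the center is the per-amplicon median, the scale a MAD-based SD estimate
    (an outlying copy-number carrier must not inflate its own denominator),
    and the removed components are estimated on a +/-CLIP_Z-clipped copy so
    that genuine copy-number outliers survive the removal.
    """
    n_samples = m.rpkm.shape[1]
    if n_samples < 3:
        raise StandardizationError("standardization needs >= 3 samples")
    if k_svd > min(m.rpkm.shape):
        raise StandardizationError("k_svd exceeds matrix rank bound")
    x = m.rpkm / _size_factors(m.rpkm, m.pools)
    med = np.median(x, axis=1, keepdims=True)
    mad_sd = 1.4826 * np.median(np.abs(x - med), axis=1, keepdims=True)
    sd = np.maximum(mad_sd, SD_FLOOR)
    z = (x - med) / sd
    if k_svd > 0:
        u, s, vt = np.linalg.svd(np.clip(z, -CLIP_Z, CLIP_Z), full_matrices=False)
        s[k_svd:] = 0.0
        z = z - (u * s) @ vt
    m.zrpkm = z
    m.svd_components_removed = k_svd
    return m


def _runs(mask: np.ndarray) -> list[tuple[int, int]]:
    """Maximal runs of True as inclusive index ranges."""
    edges = np.flatnonzero(np.diff(np.concatenate(([False], mask, [False])).astype(int)))
    return [(int(lo), int(hi - 1)) for lo, hi in zip(edges[::2], edges[1::2])]


def call_cnv(m: ZrpkmMatrix, panel: AmpliconPanel, model: GeneModel,
             thresholds: CnvThresholds = CnvThresholds()) -> list[CnvCall]:
    """Threshold + segment the ZRPKM matrix into per-sample CNV calls."""
    if m.zrpkm is None:
        raise StandardizationError("zrpkm not filled; run standardize_zrpkm first")
    t = thresholds
    cohort_median = np.median(m.rpkm, axis=1)
    calls: list[CnvCall] = []
    for j, sid in enumerate(m.sample_ids):
        z = m.zrpkm[:, j]
        for sign, mask, state_base in (("del", z <= t.del_z, "del"),
                                       ("dup", z >= t.dup_z, "dup")):
            for lo, hi in _runs(mask):
                if hi - lo + 1 < t.min_run:
                    continue
                run_rpkm = m.rpkm[lo:hi + 1, j]
                run_med = cohort_median[lo:hi + 1]
                if state_base == "del":
                    hom = np.mean(run_rpkm) < t.hom_ratio * np.mean(run_med)
                    state = "hom_del" if hom else "het_del"
                else:
                    state = "dup"
                exons = [i + 1 for i, ex in enumerate(model.exons)
                         if any(_overlaps(panel.amplicons[k].insert, ex)
                                for k in range(lo, hi + 1))]
                if not exons:
                    continue
                calls.append(CnvCall(
                    sample_id=sid, amplicon_run=(lo, hi),
                    exon_span=(min(exons), max(exons)), state=state,
                    mean_zrpkm=float(z[lo:hi + 1].mean()),
                    amplicon_ids=m.amplicon_ids[lo:hi + 1]))
    return calls
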