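"""Diagnostic-accuracy validation: variant-level and site-level concordance
between calls and per-sample truth, with sensitivity / specificity / PPV /
NPV and 95% confidence intervals.

CI policy: the normal (SD-based) binomial approximation for metrics with a
nonzero error count; the Wilson score method whenever the error count is
zero (where the SD-based interval degenerates).

Percentage formatting rounds half-up to two decimals, except NPV which is
truncated toward zero at two decimals (so 99.998% is reported as 99.99%,
never inflated to 100%).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from decimal import ROUND_DOWN, ROUND_HALF_UP, Decimal

from .calling import ScreenResult
from .cnv import CnvCall
from .simulate import SampleTruth, TruthVariant, _overlaps

__all__ = [
    "ConfusionCounts",
    "PerformanceEstimate",
    "UndefinedMetricError",
    "build_confusion",
    "sensitivity",
    "specificity",
    "ppv",
    "npv",
    "confidence_interval",
    "wilson_interval",
    "normal_interval",
    "format_percent",
    "validation_report",
]

Z95 = 1.96


class UndefinedMetricError(ZeroDivisionError):
    pass


@dataclass
class ConfusionCounts:
    tp_variants: int
    fn_variants: int
    fp_variants: int
    tn_sites: int
    total_known_variants: int
    total_sites: int
    fn_records: list[dict] = field(default_factory=list)    # sample, variant, reason, in_gap

    def __post_init__(self) -> None:
        if self.tp_variants + self.fn_variants != self.total_known_variants:
            raise ValueError("tp + fn must equal total_known_variants")
        if min(self.tp_variants, self.fn_variants, self.fp_variants,
               self.tn_sites, self.total_sites) < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class PerformanceEstimate:
    metric: str
    estimate: float
    ci_low: float
    ci_high: float
    ci_method: str              # normal_sd | wilson
    n: int

    def __post_init__(self) -> None:
        if not (0 <= self.ci_low <= self.estimate + 1e-12
                and self.estimate <= self.ci_high + 1e-12 and self.ci_high <= 1):
            raise ValueError("CI must bracket the estimate within [0, 1]")


# ---------------------------------------------------------------------------
# Confusion assembly
# ---------------------------------------------------------------------------

def build_confusion(truths: list[SampleTruth],
                    screens: dict[str, ScreenResult],
                    catalog: list[TruthVariant],
                    cnv_calls: list[CnvCall] | None = None) -> ConfusionCounts:
    """Variant-level TP/FN/FP and site-level TN counts.

    A truth variant is recovered only by a PASS call with identical
    left-aligned (pos, ref, alt) AND identical zygosity. FP are PASS calls
    absent from truth (calls inside no-call regions cannot occur: those sites
    are not genotyped). TN sites are the genotyped target sites minus the
    variant-positive sites, summed over samples.
    """
    by_id = {v.id: v for v in catalog}
    call_sample_ids = set(screens)
    truth_sample_ids = {t.sample_id for t in truths}
    if call_sample_ids != truth_sample_ids:
        raise ValueError(f"sample-id mismatch between truth and calls: "
                         f"{sorted(truth_sample_ids ^ call_sample_ids)}")
    cnv_by_sample: dict[str, list[CnvCall]] = {}
    for c in cnv_calls or []:
        cnv_by_sample.setdefault(c.sample_id, []).append(c)

    tp = fn = fp = 0
    total_known = 0
    total_sites = 0
    positive_sites = 0
    fn_records: list[dict] = []

    for truth in truths:
        screen = screens[truth.sample_id]
        total_sites += screen.n_sites_genotyped
        pass_calls = {c.key: c for c in screen.calls if c.filter_status == "PASS"}
        matched_keys: set[tuple] = set()
        for vid, geno in sorted(truth.genotypes.items()):
            v = by_id[vid]
            total_known += 1
            if v.vtype == "large_deletion":
                want_state = "hom_del" if geno == "hom" else "het_del"
                hit = any(c.state == want_state and c.exon_span == v.exon_span
                          for c in cnv_by_sample.get(truth.sample_id, []))
                if hit:
                    tp += 1
                else:
                    fn += 1
                    fn_records.append({"sample": truth.sample_id, "variant": vid,
                                       "reason": "cnv_not_detected",
                                       "in_gap": True})
                continue
            key = (v.pos, v.ref_allele, v.alt_allele)
            positive_sites += 1
            call = pass_calls.get(key)
            if call is not None and call.genotype == geno:
                tp += 1
                matched_keys.add(key)
            else:
                fn += 1
                in_gap = any(_overlaps(v.locus, g) for g in screen.no_call_regions)
                reason = ("zygosity_mismatch" if call is not None
                          else "no_coverage" if in_gap else "not_called")
                if call is not None:
                    matched_keys.add(key)
                fn_records.append({"sample": truth.sample_id, "variant": vid,
                                   "reason": reason, "in_gap": in_gap})
        for key, call in pass_calls.items():
            if key not in matched_keys:
                fp += 1
                positive_sites += 1
        for c in cnv_by_sample.get(truth.sample_id, []):
            truth_cnv_ids = {vid for vid, _ in truth.genotypes.items()
                             if by_id[vid].vtype == "large_deletion"}
            if not any(by_id[vid].exon_span == c.exon_span for vid in truth_cnv_ids):
                fp += 1

    tn = total_sites - positive_sites
    return ConfusionCounts(tp_variants=tp, fn_variants=fn, fp_variants=fp,
                           tn_sites=tn, total_known_variants=tp + fn,
                           total_sites=total_sites, fn_records=fn_records)


# ---------------------------------------------------------------------------
# Accuracy metrics and confidence intervals
# ---------------------------------------------------------------------------

def wilson_interval(p: float, n: int, z: float = Z95) -> tuple[float, float]:
    denom = 1 + z * z / n
    center = (p + z * z / (2 * n)) / denom
    half = z * math.sqrt(p * (1 - p) / n + z * z / (4 * n * n)) / denom
    lo, hi = max(0.0, center - half), min(1.0, center + half)
    if p >= 1.0:        # algebraically exact endpoints at the extremes
        hi = 1.0
    if p <= 0.0:
        lo = 0.0
    return lo, hi


def normal_interval(p: float, n: int, z: float = Z95) -> tuple[float, float]:
    half = z * math.sqrt(p * (1 - p) / n)
    return (max(0.0, p - half), min(1.0, p + half))


def confidence_interval(estimate: float, n: int, errors: int) -> tuple[float, float, str]:
    """95% CI: Wilson score when the error count is zero (SD = 0), else the
    normal approximation."""
    if n <= 0:
        raise UndefinedMetricError("n must be positive")
    if errors == 0:
        lo, hi = wilson_interval(estimate, n)
        return lo, hi, "wilson"
    lo, hi = normal_interval(estimate, n)
    return lo, hi, "normal_sd"


def _estimate(metric: str, num: int, den: int, errors: int) -> PerformanceEstimate:
    if den <= 0:
        raise UndefinedMetricError(f"{metric}: zero denominator")
    p = num / den
    lo, hi, method = confidence_interval(p, den, errors)
    return PerformanceEstimate(metric=metric, estimate=p, ci_low=lo, ci_high=hi,
                               ci_method=method, n=den)


def sensitivity(c: ConfusionCounts) -> PerformanceEstimate:
    return _estimate("sensitivity", c.tp_variants,
                     c.tp_variants + c.fn_variants, c.fn_variants)


def specificity(c: ConfusionCounts) -> PerformanceEstimate:
    return _estimate("specificity", c.tn_sites,
                     c.tn_sites + c.fp_variants, c.fp_variants)


def ppv(c: ConfusionCounts) -> PerformanceEstimate:
    return _estimate("ppv", c.tp_variants,
                     c.tp_variants + c.fp_variants, c.fp_variants)


def npv(c: ConfusionCounts) -> PerformanceEstimate:
    return _estimate("npv", c.tn_sites,
                     c.tn_sites + c.fn_variants, c.fn_variants)


def format_percent(value: float, metric: str = "") -> float:
    """Two-decimal percentage. NPV truncates toward zero (99.998 -> 99.99);
    everything else rounds half-up."""
    pct = Decimal(repr(value * 100))
    mode = ROUND_DOWN if metric == "npv" else ROUND_HALF_UP
    return float(pct.quantize(Decimal("0.01"), rounding=mode))


def validation_report(c: ConfusionCounts) -> dict:
    """Machine-readable report: the four accuracy metrics with CIs, the
    confusion counts, and the per-variant false-negative breakdown with gap
    cross-references."""
    metrics = {}
    for fn_ in (sensitivity, specificity, ppv, npv):
        try:
            est = fn_(c)
        except UndefinedMetricError:
            continue
        metrics[est.metric] = {
            "estimate": est.estimate,
            "percent": format_percent(est.estimate, est.metric),
            "ci_low": est.ci_low,
            "ci_high": est.ci_high,
            "ci_low_percent": format_percent(est.ci_low, est.metric),
            "ci_high_percent": format_percent(est.ci_high, est.metric),
            "ci_method": est.ci_method,
            "n": est.n,
        }
    breakdown: dict[str, dict] = {}
    for rec in c.fn_records:
        b = breakdown.setdefault(rec["variant"],
                                 {"samples": [], "n": 0, "in_gap": []})
        b["samples"].append(rec["sample"])
        b["n"] += 1
        b["in_gap"].append(rec["in_gap"])
    assert sum(b["n"] for b in breakdown.values()) == c.fn_variants
    return {
        "counts": {
            "tp_variants": c.tp_variants,
            "fn_variants": c.fn_variants,
            "fp_variants": c.fp_variants,
            "tn_sites": c.tn_sites,
            "total_known_variants": c.total_known_variants,
            "total_sites": c.total_sites,
        },
        "metrics": metrics,
        "fn_breakdown": breakdown,
    }
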