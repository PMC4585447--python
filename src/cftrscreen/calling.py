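"""Pileup-based germline genotyping with the thresholded filter cascade.

A candidate variant passes only when it is seen on both sequenced DNA
strands, accounts for >=20% of total reads at its site, and the site depth is
at least 80X; sites under 50X are no-call regions (the minimum depth required
to perform variant calling at all). Sites with depth in [50, 80) are
reference-callable but variant-suppressed (flagged ``low_depth``).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .coverage import low_coverage_runs
from .simulate import AlignedRead, AmpliconPanel, normalize_variant

__all__ = [
    "FilterThresholds",
    "SiteCounts",
    "VariantCall",
    "ScreenResult",
    "pileup",
    "call_site",
    "screen_sample",
    "normalize_variant",
]

_BASE_IDX = {"A": 0, "C": 1, "G": 2, "T": 3}


@dataclass(frozen=True)
class FilterThresholds:
    min_alt_fraction: float = 0.20
    min_call_depth: int = 80
    min_site_depth: int = 50
    require_both_strands: bool = True
    min_per_strand: int = 1
    hom_fraction: float = 0.80

    def __post_init__(self) -> None:
        if not 0 < self.min_alt_fraction <= self.hom_fraction <= 1:
            raise ValueError("need 0 < min_alt_fraction <= hom_fraction <= 1")
        if self.min_site_depth > self.min_call_depth:
            raise ValueError("min_site_depth must be <= min_call_depth")


@dataclass
class SiteCounts:
    """Stranded allele tallies at one reference position.

    Allele keys: ``A/C/G/T`` base calls, ``D:<k>`` a k-base deletion whose
    first deleted base is this position, ``I:<seq>`` an insertion of seq
    immediately after this position (the carrying read's base at this
    position is folded into the insertion allele, so depth remains the sum
    of allele counts).
    """
    pos: int
    ref: str
    allele_counts: dict[str, tuple[int, int]] = field(default_factory=dict)

    @property
    def depth(self) -> int:
        return sum(f + r for f, r in self.allele_counts.values())


@dataclass
class VariantCall:
    pos: int                    # 0-based anchored position (VCF pos - 1)
    ref: str
    alt: str
    genotype: str | None        # het | hom | None when filtered
    alt_fraction: float
    depth: int
    strand_counts: tuple[int, int]
    filter_status: str          # PASS | low_fraction | single_strand | low_depth | no_call_region

    @property
    def key(self) -> tuple[int, str, str]:
        return (self.pos, self.ref, self.alt)


@dataclass
class ScreenResult:
    sample_id: str
    calls: list[VariantCall]
    no_call_regions: list[tuple[int, int]]
    n_sites_genotyped: int


# ---------------------------------------------------------------------------
# Pileup
# ---------------------------------------------------------------------------

def _cigar_layout(cigar: tuple[tuple[str, int], ...], start: int, read_len: int):
    """Per-cigar-shape layout: aligned (ref_pos, read_idx) pairs for M ops,
    plus indel allele events. Shared by every read with the same placement."""
    ref, qi = start, 0
    pairs: list[tuple[int, int]] = []
    events: list[tuple[int, str]] = []      # (keyed ref pos, allele)
    skip_base: set[int] = set()             # ref positions folded into an I allele
    n_ops = len(cigar)
    for oi, (op, n) in enumerate(cigar):
        if op == "M":
            pairs.extend(zip(range(ref, ref + n), range(qi, qi + n)))
            ref += n
            qi += n
        elif op == "D":
            events.append((ref, f"D:{n}"))
            ref += n
        elif op == "I":
            anchor = ref - 1
            events.append((anchor, None))   # allele filled in per read (needs seq)
            skip_base.add(anchor)
            qi += n
        else:
            raise ValueError(f"unsupported cigar op {op}")
    if qi != read_len:
        raise ValueError("cigar inconsistent with read length")
    pairs = [(rp, ri) for rp, ri in pairs if rp not in skip_base]
    return pairs, events, skip_base


def pileup(reads: list[AlignedRead], refseq: str,
           regions: tuple[tuple[int, int], ...] | None = None) -> dict[int, SiteCounts]:
    """Stranded per-site allele counts over ``regions`` (default: every
    covered position). Insertions are keyed to the base before the event,
    deletions to their first deleted base."""
    L = len(refseq)
    fwd = np.zeros((L, 4), dtype=np.int64)
    rev = np.zeros((L, 4), dtype=np.int64)
    indels: dict[tuple[int, str], list[int]] = {}

    groups: dict[tuple[int, tuple], list[AlignedRead]] = {}
    for r in reads:
        groups.setdefault((r.start, r.cigar), []).append(r)

    for (start, cigar), grp in groups.items():
        pairs, events, skip = _cigar_layout(cigar, start, len(grp[0].seq))
        ref_pos = np.array([p for p, _ in pairs], dtype=np.int64)
        read_idx = np.array([i for _, i in pairs], dtype=np.int64)
        for strand, mat in (("+", fwd), ("-", rev)):
            sub = [r for r in grp if r.strand == strand]
            if not sub:
                continue
            si = 0 if strand == "+" else 1
            seqs = np.frombuffer("".join(r.seq for r in sub).encode(), dtype=np.uint8)
            seqs = seqs.reshape(len(sub), -1)
            codes = np.full(seqs.shape, -1, dtype=np.int8)
            for b, i in _BASE_IDX.items():
                codes[seqs == ord(b)] = i
            cols = codes[:, read_idx]
            valid = cols >= 0
            flat = ref_pos[None, :] * 4 + cols
            np.add.at(mat.reshape(-1), flat[valid], 1)
            for pos, allele in events:
                if allele is None:      # insertion: allele sequence varies per read
                    for r in sub:
                        ins = _insertion_seq(r, pos)
                        k = (pos, f"I:{ins}")
                        indels.setdefault(k, [0, 0])[si] += 1
                else:
                    indels.setdefault((pos, allele), [0, 0])[si] += len(sub)

    if regions is None:
        covered = set(np.flatnonzero(fwd.sum(1) + rev.sum(1)).tolist())
        covered.update(pos for pos, _ in indels)
        positions = sorted(covered)
    else:
        positions = [p for s, e in regions for p in range(s, e)]

    indels_by_pos: dict[int, list[tuple[str, list[int]]]] = {}
    for (pos, allele), cnt in indels.items():
        indels_by_pos.setdefault(pos, []).append((allele, cnt))

    sites: dict[int, SiteCounts] = {}
    for p in positions:
        counts: dict[str, tuple[int, int]] = {}
        for b, i in _BASE_IDX.items():
            f, r_ = int(fwd[p, i]), int(rev[p, i])
            if f or r_:
                counts[b] = (f, r_)
        for allele, (f, r_) in indels_by_pos.get(p, ()):
            counts[allele] = (f, r_)
        sites[p] = SiteCounts(pos=p, ref=refseq[p], allele_counts=counts)
    return sites


def _insertion_seq(read: AlignedRead, anchor: int) -> str:
    ref, qi = read.start, 0
    for op, n in read.cigar:
        if op == "M":
            ref += n
            qi += n
        elif op == "D":
            ref += n
        elif op == "I":
            if ref - 1 == anchor:
                return read.seq[qi:qi + n]
            qi += n
    raise ValueError("no insertion at anchor")


# ---------------------------------------------------------------------------
# Filter cascade
# ---------------------------------------------------------------------------

def _anchored(sc: SiteCounts, allele: str, refseq: str) -> tuple[int, str, str]:
    if allele.startswith("D:"):
        k = int(allele[2:])
        a = sc.pos - 1
        return (a, refseq[a:sc.pos + k], refseq[a])
    if allele.startswith("I:"):
        return (sc.pos, refseq[sc.pos], refseq[sc.pos] + allele[2:])
    return (sc.pos, sc.ref, allele)


def call_site(sc: SiteCounts, t: FilterThresholds, refseq: str,
              report_floor: float = 0.0) -> list[VariantCall]:
    """Apply the filter cascade to one site.

    Returns PASS calls plus (when ``report_floor`` < 1) non-PASS records for
    alt alleles above that fraction; an empty list for reference-only or
    sub-``min_site_depth`` sites.
    """
    depth = sc.depth
    out: list[VariantCall] = []
    alts = [(a, c) for a, c in sc.allele_counts.items() if a != sc.ref and a != "N"]
    alts.sort(key=lambda ac: -(ac[1][0] + ac[1][1]))
    for allele, (f, r) in alts:
        n_alt = f + r
        if n_alt == 0:
            continue
        frac = n_alt / depth if depth else 0.0
        if depth < t.min_site_depth:
            status = "no_call_region"
        elif depth < t.min_call_depth:
            status = "low_depth"
        elif frac < t.min_alt_fraction:
            status = "low_fraction"
        elif t.require_both_strands and (f < t.min_per_strand or r < t.min_per_strand):
            status = "single_strand"
        else:
            status = "PASS"
        if status != "PASS" and frac < report_floor:
            continue
        genotype = None
        if status == "PASS":
            genotype = "hom" if frac >= t.hom_fraction else "het"
        pos, ref, alt = _anchored(sc, allele, refseq)
        pos, ref, alt = normalize_variant(pos, ref, alt, refseq)
        out.append(VariantCall(pos=pos, ref=ref, alt=alt, genotype=genotype,
                               alt_fraction=frac, depth=depth,
                               strand_counts=(f, r), filter_status=status))
    passing = [c for c in out if c.filter_status == "PASS"]
    for c in passing[2:]:       # diploid: at most two PASS alts
        c.filter_status = "excess_alleles"
        c.genotype = None
    return out


def screen_sample(reads: list[AlignedRead], panel: AmpliconPanel,
                  t: FilterThresholds, refseq: str,
                  sample_id: str = "sample",
                  report_floor: float = 0.10) -> ScreenResult:
    """Pileup + filter cascade over the target regions; also emits the
    no-call regions (target runs under ``min_site_depth``), which match the
    coverage-QC gap set computed from the same reads."""
    from .coverage import compute_coverage
    sites = pileup(reads, refseq, regions=panel.target_regions)
    calls: list[VariantCall] = []
    for p in sorted(sites):
        calls.extend(call_site(sites[p], t, refseq, report_floor=report_floor))
    profile = compute_coverage(reads, panel, len(refseq))
    gaps = low_coverage_runs(profile.depth, panel.target_regions,
                             threshold=t.min_site_depth)
    no_call = [g.interval for g in gaps]
    n_geno = panel.target_length() - sum(e - s for s, e in no_call)
    return ScreenResult(sample_id=sample_id, calls=calls,
                        no_call_regions=no_call, n_sites_genotyped=n_geno)
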