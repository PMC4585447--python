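"""Synthetic amplicon-sequencing cohort generator.

Builds a toy 27-exon gene with an intronic poly-TG/poly-T tract, designs a
two-pool overlapping amplicon panel over the coding exons (default 102
amplicons of 150 bp), draws per-sample truth genotypes from a variant catalog
patterned on a clinical CFTR screening cohort, and emits gaplessly placed
aligned reads at a configurable mean depth (default 852X).

Coordinates are 0-based half-open throughout; emitted VCF/SAM are 1-based per
those standards (see :mod:`cftrscreen.io`).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "SimulationConfig",
    "GeneModel",
    "TgtTract",
    "Amplicon",
    "AmpliconPanel",
    "TruthVariant",
    "SampleTruth",
    "AlignedRead",
    "SizingError",
    "DesignError",
    "AssignmentError",
    "build_reference",
    "design_panel",
    "build_catalog",
    "sample_cohort",
    "simulate_reads",
    "simulate_amplicon_counts",
    "amplicon_efficiencies",
    "panel_redundancy",
    "variant_edit",
    "anchored_alleles",
    "normalize_variant",
]

BASES = "ACGT"

# -- toy gene geometry -------------------------------------------------------
# 27 exons scaled so that minimal two-pool tiling of exon +/- 15 bp flanks with
# 150 bp inserts (plus the TG-T tract extension on exon 10) caps out at 102
# amplicons with at most 2x redundancy (two primer pools).
N_EXONS = 27
EXON_LEN_LONG = 390
EXON_LEN_SHORT = 300
SHORT_EXON_IDX = frozenset({2, 6, 13, 17, 21, 25})
INTRON_LEN = 150
END_PAD = 300
FLANK = 15
INSERT_LEN = 150

# TG-T tract: placed in the intron upstream of exon 10 (0-based exon index 9),
# mimicking the c.1210-34TG[m]T[n] locus. Reference tract is (TG)11(T)7.
TRACT_EXON = 9
TRACT_GAP = 11          # bases between tract end and exon start
ANCHOR_LEFT = "GACCTAGCAT"
ANCHOR_RIGHT = "CAGGCTACAG"   # must not begin with T or G (would extend the run)
TRACT_TG_REF = 11
TRACT_T_REF = 7


class SizingError(ValueError):
    """Configured geometry does not fit the reference."""


class DesignError(ValueError):
    """Amplicon panel cannot be tiled under the pool constraints."""


class AssignmentError(RuntimeError):
    """Could not assign compatible variant phases to a sample."""


@dataclass(frozen=True)
class SimulationConfig:
    n_samples: int = 10
    mean_depth: float = 852.0
    depth_dispersion: float = 400.0  # negative-binomial size (residual count noise)
    strand_balance: float = 0.5
    base_error_rate: float = 0.0
    read_length: int = 150
    seed: int = 0
    n_deletion_carriers: int = 0     # samples carrying the exons 4-11 hom deletion
    dropout: bool = False            # plant coverage dropout over designated loci
    # systematic depth structure: per-amplicon PCR efficiency (shared by all
    # samples) and per-sample relative yield of the two primer pools
    amplicon_efficiency_sigma: float = 0.3
    pool_imbalance_sigma: float = 0.15

    def __post_init__(self) -> None:
        for name in ("strand_balance", "base_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must be in [0, 1], got {v}")
        if self.mean_depth <= 0:
            raise ValueError("mean_depth must be positive")


@dataclass(frozen=True)
class TgtTract:
    """Intronic (TG)n(T)m tract location and its fixed flanking anchors."""
    repeat_start: int
    repeat_end: int
    anchor_left: str = ANCHOR_LEFT
    anchor_right: str = ANCHOR_RIGHT
    tg_ref: int = TRACT_TG_REF
    t_ref: int = TRACT_T_REF

    @property
    def region(self) -> tuple[int, int]:
        return (self.repeat_start - len(self.anchor_left),
                self.repeat_end + len(self.anchor_right))


@dataclass(frozen=True)
class GeneModel:
    name: str
    sequence_length: int
    exons: tuple[tuple[int, int], ...]
    strand: str = "+"
    coding_offset: int = 0
    tgt_tract: TgtTract | None = None

    def __post_init__(self) -> None:
        prev_end = 0
        for s, e in self.exons:
            if not (0 <= s < e <= self.sequence_length):
                raise ValueError(f"exon ({s},{e}) outside [0,{self.sequence_length})")
            if s < prev_end:
                raise ValueError("exons overlap or are unsorted")
            prev_end = e

    @property
    def n_exons(self) -> int:
        return len(self.exons)

    def exon_of(self, pos: int) -> int | None:
        """0-based exon index containing pos, or None if intronic/flanking."""
        for i, (s, e) in enumerate(self.exons):
            if s <= pos < e:
                return i
        return None


@dataclass(frozen=True)
class Amplicon:
    id: str
    pool: int
    insert: tuple[int, int]
    primer_len_5p: int = 20
    primer_len_3p: int = 20

    @property
    def insert_length(self) -> int:
        return self.insert[1] - self.insert[0]


@dataclass(frozen=True)
class AmpliconPanel:
    amplicons: tuple[Amplicon, ...]
    target_regions: tuple[tuple[int, int], ...]

    @property
    def n_amplicons(self) -> int:
        return len(self.amplicons)

    def target_length(self) -> int:
        return sum(e - s for s, e in self.target_regions)


@dataclass(frozen=True)
class TruthVariant:
    id: str
    locus: tuple[int, int]          # affected reference span (anchored, VCF-style)
    ref_allele: str
    alt_allele: str
    vtype: str                      # SNV | insertion | deletion | large_deletion | TGT
    cdna_name: str
    tier: str
    population_freq: float | None
    in_mutation_db: bool
    hom_freq: float = 0.0
    het_freq: float = 0.0
    exon_span: tuple[int, int] | None = None   # 1-based inclusive, large_deletion only
    predictor_verdicts: tuple[bool, ...] = ()

    @property
    def pos(self) -> int:
        return self.locus[0]


@dataclass
class SampleTruth:
    sample_id: str
    genotypes: dict[str, str] = field(default_factory=dict)     # variant id -> het|hom
    phases: dict[str, int] = field(default_factory=dict)        # variant id -> 0|1|2 (2 = both)
    cnv: dict | None = None          # {"exon_span": (lo, hi) 1-based, "copies": 0|1|3}
    tgt_diplotype: tuple[tuple[int, int], tuple[int, int]] = ((TRACT_TG_REF, TRACT_T_REF),) * 2
    dropout_regions: list[tuple[int, int]] = field(default_factory=list)


@dataclass(frozen=True)
class AlignedRead:
    name: str
    sample_id: str
    start: int                      # 0-based leftmost reference position
    strand: str                     # + | -
    cigar: tuple[tuple[str, int], ...]
    seq: str

    @property
    def end(self) -> int:
        """Past-the-end reference coordinate of the alignment."""
        return self.start + sum(n for op, n in self.cigar if op in "MD")

    @property
    def cigar_string(self) -> str:
        return "".join(f"{n}{op}" for op, n in self.cigar)


def sample_rng(config: SimulationConfig, sample_id: str, stream: int) -> np.random.Generator:
    """Per-sample random stream derived from the master seed by stable hashing."""
    return np.random.default_rng(
        [config.seed & 0x7FFFFFFF, zlib.crc32(sample_id.encode()), stream])


# ---------------------------------------------------------------------------
# Reference construction
# ---------------------------------------------------------------------------

def build_reference(config: SimulationConfig,
                    n_exons: int = N_EXONS,
                    max_length: int | None = None) -> tuple[GeneModel, str]:
    """Generate the toy gene model and its reference sequence.

    Deterministic for a fixed ``config.seed``. The TG-T tract with its fixed
    anchors is embedded upstream of exon ``TRACT_EXON + 1`` and recorded in the
    returned :class:`GeneModel`.
    """
    exon_lens = [EXON_LEN_SHORT if i in SHORT_EXON_IDX else EXON_LEN_LONG
                 for i in range(n_exons)]
    exons = []
    pos = END_PAD
    for ln in exon_lens:
        exons.append((pos, pos + ln))
        pos += ln + INTRON_LEN
    total = pos - INTRON_LEN + END_PAD
    if max_length is not None and total > max_length:
        raise SizingError(f"geometry needs {total} bases > limit {max_length}")

    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, 0xC0FFEE])
    seq = rng.choice(list(BASES), size=total)

    tract = None
    if n_exons > TRACT_EXON:
        exon_start = exons[TRACT_EXON][0]
        repeat = "TG" * TRACT_TG_REF + "T" * TRACT_T_REF
        block = ANCHOR_LEFT + repeat + ANCHOR_RIGHT
        block_end = exon_start - TRACT_GAP
        block_start = block_end - len(block)
        if block_start < exons[TRACT_EXON - 1][1]:
            raise SizingError("intron too short for TG-T tract")
        seq[block_start:block_end] = list(block)
        tract = TgtTract(repeat_start=block_start + len(ANCHOR_LEFT),
                         repeat_end=block_end - len(ANCHOR_RIGHT))
        _make_anchors_unique(seq, tract)

    sequence = "".join(seq)
    model = GeneModel(name="CFTR_toy", sequence_length=total,
                      exons=tuple(exons), tgt_tract=tract)
    return model, sequence


def _make_anchors_unique(seq: np.ndarray, tract: TgtTract) -> None:
    """Mutate spurious anchor occurrences so each anchor is unique in the reference."""
    text = "".join(seq)
    for anchor, home in ((tract.anchor_left, tract.region[0]),
                        (tract.anchor_right, tract.repeat_end)):
        start = 0
        while (i := text.find(anchor, start)) != -1:
            if i != home:
                mid = i + len(anchor) // 2
                seq[mid] = BASES[(BASES.index(seq[mid]) + 1) % 4]
                text = text[:mid] + seq[mid] + text[mid + 1:]
            start = i + 1


# ---------------------------------------------------------------------------
# Panel design
# ---------------------------------------------------------------------------

def design_panel(model: GeneModel, n_amplicons: int = 102,
                 insert_len: int = INSERT_LEN, flank: int = FLANK) -> AmpliconPanel:
    """Tile every coding exon +/- flank with two-pool overlapping amplicons.

    Each exon is tiled with evenly spaced ``insert_len`` inserts; minimal
    counts guarantee >=1 bp overlap between neighbours, extra amplicons are
    distributed to the exons with the sparsest tiling until exactly
    ``n_amplicons`` are placed. Overlapping inserts never share a pool
    (enforced by keeping the tiling step above ``insert_len / 2`` and
    alternating pools within an exon).
    """
    spans = []
    for i, (s, e) in enumerate(model.exons):
        lo, hi = s - flank, e + flank
        if model.tgt_tract is not None and i == TRACT_EXON:
            lo = min(lo, model.tgt_tract.region[0] - 2)
        spans.append((max(lo, 0), min(hi, model.sequence_length)))

    def n_min(span: int) -> int:
        if span <= insert_len:
            return 1
        return 1 + int(np.ceil((span - insert_len) / (insert_len - 1)))

    def n_cap(span: int) -> int:
        if span <= insert_len:
            return 1
        k = 1
        while (span - insert_len) / (k + 1) > insert_len / 2:
            k += 1
        return k + 1

    lengths = [hi - lo for lo, hi in spans]
    counts = [n_min(L) for L in lengths]
    caps = [n_cap(L) for L in lengths]
    if any(c > cap for c, cap in zip(counts, caps)):
        raise DesignError("an exon cannot be tiled without triple overlap")
    if sum(counts) > n_amplicons:
        raise DesignError(f"minimal tiling needs {sum(counts)} > {n_amplicons} amplicons")
    if sum(caps) < n_amplicons:
        raise DesignError(f"panel capacity {sum(caps)} < requested {n_amplicons}")
    while sum(counts) < n_amplicons:
        # densify where each amplicon currently covers the most span
        candidates = [i for i in range(len(counts)) if counts[i] < caps[i]]
        j = max(candidates, key=lambda i: lengths[i] / counts[i])
        counts[j] += 1

    amplicons: list[Amplicon] = []
    k = 0
    for (lo, hi), n in zip(spans, counts):
        span = hi - lo
        if span <= insert_len:
            mid = (lo + hi) // 2
            start = max(0, min(mid - insert_len // 2, model.sequence_length - insert_len))
            starts = [start]
        else:
            starts = np.round(np.linspace(lo, hi - insert_len, n)).astype(int).tolist()
        for st in starts:
            k += 1
            # global alternation: overlapping neighbours always differ in pool
            amplicons.append(Amplicon(id=f"AMP{k:03d}", pool=1 + (k - 1) % 2,
                                      insert=(st, st + insert_len)))

    for a in amplicons:
        for b in amplicons:
            if a.id < b.id and a.pool == b.pool and \
                    a.insert[0] < b.insert[1] and b.insert[0] < a.insert[1]:
                raise DesignError(f"overlapping amplicons {a.id},{b.id} share pool {a.pool}")

    targets = _merge_intervals([(max(s - flank, 0), min(e + flank, model.sequence_length))
                                for s, e in model.exons])
    panel = AmpliconPanel(amplicons=tuple(amplicons), target_regions=tuple(targets))
    _check_target_coverage(panel)
    return panel


def _merge_intervals(ivals: list[tuple[int, int]]) -> list[tuple[int, int]]:
    out: list[tuple[int, int]] = []
    for s, e in sorted(ivals):
        if out and s <= out[-1][1]:
            out[-1] = (out[-1][0], max(out[-1][1], e))
        else:
            out.append((s, e))
    return out


def _check_target_coverage(panel: AmpliconPanel) -> None:
    for s, e in panel.target_regions:
        covered = np.zeros(e - s, dtype=bool)
        for a in panel.amplicons:
            lo, hi = max(a.insert[0], s), min(a.insert[1], e)
            if lo < hi:
                covered[lo - s:hi - s] = True
        if not covered.all():
            raise DesignError(f"target ({s},{e}) not fully covered by amplicon inserts")


# ---------------------------------------------------------------------------
# Variant catalog
# ---------------------------------------------------------------------------

def _cdna_pos(model: GeneModel, pos: int) -> str:
    """Simplified c.-notation for a genomic position (coding positions 1-based)."""
    cum = 0
    for i, (s, e) in enumerate(model.exons):
        if s <= pos < e:
            return str(cum + (pos - s) + 1 - model.coding_offset)
        if pos < s:
            if i == 0:
                return f"1-{s - pos}"
            prev_end = model.exons[i - 1][1]
            d_prev, d_next = pos - prev_end + 1, s - pos
            if d_prev <= d_next:
                return f"{cum}+{d_prev}"
            return f"{cum + 1}-{d_next}"
        cum += e - s
    return f"*{pos - model.exons[-1][1] + 1}"


def cdna_name(model: GeneModel, pos: int, ref: str, alt: str) -> str:
    """Simplified HGVS-like cDNA label for an anchored (pos, ref, alt) variant."""
    if len(ref) == 1 and len(alt) == 1:
        return f"c.{_cdna_pos(model, pos)}{ref}>{alt}"
    if len(ref) > len(alt):     # deletion, anchored
        lo, hi = pos + 1, pos + len(ref) - 1
        if lo == hi:
            return f"c.{_cdna_pos(model, lo)}del"
        return f"c.{_cdna_pos(model, lo)}_{_cdna_pos(model, hi)}del"
    ins = alt[len(ref):]
    return f"c.{_cdna_pos(model, pos)}_{_cdna_pos(model, pos + 1)}ins{ins}"


def variant_edit(v: TruthVariant) -> tuple[int, int, str]:
    """Raw (span_start, span_end, replacement) edit for a small variant."""
    if len(v.ref_allele) == 1 and len(v.alt_allele) == 1:
        return (v.pos, v.pos + 1, v.alt_allele)
    if len(v.ref_allele) > len(v.alt_allele):       # anchored deletion
        k = len(v.ref_allele) - len(v.alt_allele)
        return (v.pos + 1, v.pos + 1 + k, "")
    ins = v.alt_allele[len(v.ref_allele):]          # anchored insertion
    return (v.pos + 1, v.pos + 1, ins)


def anchored_alleles(seq: str, span: tuple[int, int], replacement: str) -> tuple[int, str, str]:
    """Convert a raw edit to VCF-style anchored (pos, ref, alt)."""
    s, e = span
    if replacement and e - s == len(replacement):   # substitution
        return s, seq[s:e], replacement
    a = s - 1
    return a, seq[a:e], seq[a] + replacement


def normalize_variant(pos: int, ref: str, alt: str, refseq: str) -> tuple[int, str, str]:
    """Left-align and parsimony-trim an anchored (pos, ref, alt) pair.

    Canonical representation shared by the truth catalog, the caller and the
    database keys, so exact (pos, ref, alt) matching is well defined.
    """
    ref, alt = ref.upper(), alt.upper()
    # trim common suffix (keep at least one base each)
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    # trim common prefix
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    # left-rotate anchored indels while ref and alt share their last base
    while len(ref) != len(alt) and ref[-1] == alt[-1] and pos > 0:
        pos -= 1
        b = refseq[pos]
        ref = b + ref[:-1]
        alt = b + alt[:-1]
    return pos, ref, alt


_STOP_CODONS = {"TAA", "TAG", "TGA"}


def _find_snv(model: GeneModel, seq: str, exon: int, offset: int, kind: str) -> tuple[int, str, str]:
    """Search forward from exon offset for a substitution of the requested
    coding consequence (nonsense / missense / synonymous)."""
    from Bio.Seq import Seq
    s, e = model.exons[exon]
    cds_before = sum(model.exons[i][1] - model.exons[i][0] for i in range(exon))
    for pos in range(s + offset, e):
        cds_i = cds_before + (pos - s)
        frame = cds_i % 3
        codon_pos = [pos - frame + k for k in range(3)]
        if codon_pos[0] < s or codon_pos[2] >= e:
            continue        # codon split across exons: skip for the toy catalog
        codon = "".join(seq[p] for p in codon_pos)
        if codon in _STOP_CODONS:
            continue
        aa = str(Seq(codon).translate())
        for alt in BASES:
            if alt == seq[pos]:
                continue
            mut = list(codon)
            mut[frame] = alt
            mcodon = "".join(mut)
            maa = str(Seq(mcodon).translate())
            if kind == "nonsense" and maa == "*":
                return pos, seq[pos], alt
            if kind == "missense" and maa != aa and maa != "*":
                return pos, seq[pos], alt
            if kind == "synonymous" and maa == aa:
                return pos, seq[pos], alt
    raise ValueError(f"no {kind} substitution found in exon {exon}")


def _clear_of_boundaries(panel: AmpliconPanel, s: int, e: int) -> bool:
    """True if [s, e) straddles no amplicon insert boundary (a variant must
    lie fully inside every insert it touches)."""
    return all(not (a.insert[0] < e and s < a.insert[1]) or
               (a.insert[0] <= s and e <= a.insert[1])
               for a in panel.amplicons)


def _in_targets(panel: AmpliconPanel, s: int, e: int) -> bool:
    return any(ts <= s and e <= te for ts, te in panel.target_regions)


def _avoid_boundaries(panel: AmpliconPanel, span_start: int, span_end: int) -> int:
    """Shift amount so [span_start, span_end) straddles no insert boundary."""
    for shift in range(0, 30):
        for sign in (1, -1):
            if _clear_of_boundaries(panel, span_start + sign * shift,
                                    span_end + sign * shift):
                return sign * shift
    raise DesignError("could not place variant clear of insert boundaries")


def build_catalog(model: GeneModel, seq: str, panel: AmpliconPanel) -> list[TruthVariant]:
    """Synthetic truth-variant catalog patterned on the screening cohort's
    spectrum: recurrent pathogenic SNVs/indels, truncating and splice changes,
    common neutral polymorphisms, four dropout-prone loci and one multi-exon
    deletion. Frequencies are hom/het carrier counts per 177 samples.
    """
    E = model.exons
    out: list[TruthVariant] = []

    def add_snv(vid, exon, offset, kind, tier, in_db, popfreq, hom, het, verdicts=()):
        pos, ref, alt = _find_snv(model, seq, exon, offset, kind)
        shift = _avoid_boundaries(panel, pos, pos + 1)
        if shift:
            pos, ref, alt = _find_snv(model, seq, exon, offset + shift, kind)
        out.append(TruthVariant(
            id=vid, locus=(pos, pos + 1), ref_allele=ref, alt_allele=alt,
            vtype="SNV", cdna_name=cdna_name(model, pos, ref, alt), tier=tier,
            population_freq=popfreq, in_mutation_db=in_db,
            hom_freq=hom / 177, het_freq=het / 177, predictor_verdicts=tuple(verdicts)))

    def add_intron_snv(vid, exon, offset, tier, in_db, popfreq, hom, het):
        # offset < 0: upstream of exon start; > 0: downstream of exon end
        pos = E[exon][0] + offset if offset < 0 else E[exon][1] + offset - 1
        ref = seq[pos]
        alt = BASES[(BASES.index(ref) + 1) % 4]
        pos += _avoid_boundaries(panel, pos, pos + 1)
        ref = seq[pos]
        alt = BASES[(BASES.index(ref) + 1) % 4]
        out.append(TruthVariant(
            id=vid, locus=(pos, pos + 1), ref_allele=ref, alt_allele=alt,
            vtype="SNV", cdna_name=cdna_name(model, pos, ref, alt), tier=tier,
            population_freq=popfreq, in_mutation_db=in_db,
            hom_freq=hom / 177, het_freq=het / 177))

    def _place_indel(start, length, insseq="", window=None):
        """First placement near ``start`` whose left-aligned representation
        stays inside a target region, inside ``window`` (same regional class:
        a given exon, or a given intronic flank), and clear of amplicon
        insert boundaries."""
        for delta in sorted(range(-20, 21), key=abs):
            s = start + delta
            span = (s, s + length) if insseq == "" else (s + 1, s + 1)
            if span[0] < 1:
                continue
            a, ref, alt = anchored_alleles(seq, span, insseq)
            a, ref, alt = normalize_variant(a, ref, alt, seq)
            if window is not None and not (window[0] <= a and a + len(ref) <= window[1]):
                continue
            if _clear_of_boundaries(panel, a, a + max(len(ref), 2)) and \
                    _in_targets(panel, a, a + len(ref)):
                return a, ref, alt
        raise DesignError("no valid indel placement near position %d" % start)

    def add_del(vid, start, length, tier, in_db, popfreq, hom, het,
                verdicts=(), window=None):
        a, ref, alt = _place_indel(start, length, window=window)
        out.append(TruthVariant(
            id=vid, locus=(a, a + len(ref)), ref_allele=ref, alt_allele=alt,
            vtype="deletion", cdna_name=cdna_name(model, a, ref, alt), tier=tier,
            population_freq=popfreq, in_mutation_db=in_db,
            hom_freq=hom / 177, het_freq=het / 177, predictor_verdicts=tuple(verdicts)))

    def add_ins(vid, after, insseq, tier, in_db, popfreq, hom, het, window=None):
        a, ref, alt = _place_indel(after, 0, insseq, window=window)
        out.append(TruthVariant(
            id=vid, locus=(a, a + 1), ref_allele=ref, alt_allele=alt,
            vtype="insertion", cdna_name=cdna_name(model, a, ref, alt), tier=tier,
            population_freq=popfreq, in_mutation_db=in_db,
            hom_freq=hom / 177, het_freq=het / 177))

    # recurrent definitely pathogenic changes (DB-listed)
    # F508del analog: 3 bp in-frame deletion on a codon boundary in exon 11
    fs = E[10][0] + 99
    fs -= (sum(E[i][1] - E[i][0] for i in range(10)) + 99) % 3
    add_del("CFv01", fs, 3, "definitely_pathogenic", True, None, 13, 10,
            verdicts=(True, True, True, True), window=E[10])
    add_snv("CFv02", 11, 60, "nonsense", "definitely_pathogenic", True, None, 1, 1)
    add_snv("CFv03", 2, 40, "missense", "definitely_pathogenic", True, None, 0, 1,
            verdicts=(True, True, True, True))
    add_intron_snv("CFv04", 18, -1, "definitely_pathogenic", True, None, 1, 0)  # splice acceptor
    add_snv("CFv05", 22, 120, "nonsense", "definitely_pathogenic", True, None, 0, 2)
    add_snv("CFv06", 23, 200, "missense", "definitely_pathogenic", True, None, 1, 1,
            verdicts=(True, True, True, True))
    add_del("CFv07", E[13][0] + 151, 1, "definitely_pathogenic", True, None, 1, 0,
            window=E[13])
    # novel truncating (DB-absent): tier forced by the truncating rule
    add_del("CFv08", E[10][0] + 210, 2, "definitely_pathogenic", False, None, 1, 0,
            window=E[10])
    add_ins("CFv19", E[6][0] + 130, "A", "definitely_pathogenic", False, None, 0, 1,
            window=E[6])
    # missense spectrum resolved by predictor vote
    add_snv("CFv09", 15, 80, "missense", "likely_pathogenic", False, None, 1, 0,
            verdicts=(True, True, True, True))
    add_snv("CFv10", 2, 150, "missense", "uncertain", True, None, 0, 2,
            verdicts=(True, False, True, False))
    add_snv("CFv11", 3, 90, "missense", "uncertain", True, None, 0, 3,
            verdicts=(True, True, False, False))
    add_snv("CFv12", 19, 110, "missense", "uncertain", False, None, 0, 1,
            verdicts=(True, False, False, True))
    add_snv("CFv14", 10, 18, "missense", "neutral", False, 0.40, 61, 64,
            verdicts=(False, False, False, False))
    # common neutral polymorphisms
    add_snv("CFv13", 14, 60, "synonymous", "neutral", False, 0.25, 27, 49)
    add_intron_snv("CFv15", 9, -11, "neutral", False, 0.35, 33, 45)
    add_del("CFv16", E[7][0] - 13, 4, "neutral", False, 0.15, 17, 13,
            verdicts=(False,) * 4, window=(E[7][0] - 15, E[7][0] - 2))
    # noncanonical splice region change, DB-listed
    add_intron_snv("CFv20", 16, +5, "definitely_pathogenic", True, None, 1, 1)
    # dropout-prone loci (coverage-loss false-negative mechanism)
    add_del("CFd01", E[5][0] - 12, 4, "neutral", False, 0.02, 0, 2,
            verdicts=(False,) * 4, window=(E[5][0] - 15, E[5][0] - 8))
    add_del("CFd02", E[5][0] - 6, 3, "neutral", False, 0.10, 0, 30,
            verdicts=(False,) * 4, window=(E[5][0] - 9, E[5][0] - 2))
    add_snv("CFd03", 11, 260, "missense", "definitely_pathogenic", True, None, 0, 1,
            verdicts=(True, True, True, True))
    add_intron_snv("CFd04", 21, +13, "neutral", False, 0.01, 0, 4)
    # homozygous multi-exon deletion, exons 4-11 (1-based)
    del_span = (E[3][0], E[10][1])
    out.append(TruthVariant(
        id="CFv18", locus=del_span, ref_allele="<REF>", alt_allele="<DEL>",
        vtype="large_deletion",
        cdna_name=f"c.{_cdna_pos(model, E[3][0])}_{_cdna_pos(model, E[10][1] - 1)}del",
        tier="definitely_pathogenic", population_freq=None, in_mutation_db=True,
        hom_freq=1 / 177, het_freq=0.0, exon_span=(4, 11)))

    _check_catalog(out, seq)
    return out


DROPOUT_VARIANTS = ("CFd01", "CFd02", "CFd03", "CFd04")
# carriers forced when SimulationConfig.dropout is set, patterned on the
# four-variant / 2+30+1+4-patient coverage-loss false-negative breakdown
DROPOUT_CARRIERS = {"CFd01": 2, "CFd02": 30, "CFd03": 1, "CFd04": 4}


def _check_catalog(catalog: list[TruthVariant], seq: str) -> None:
    for v in catalog:
        if v.vtype in ("SNV", "insertion", "deletion"):
            if seq[v.locus[0]:v.locus[0] + len(v.ref_allele)] != v.ref_allele:
                raise ValueError(f"{v.id}: ref allele does not match reference")


# ---------------------------------------------------------------------------
# Cohort sampling
# ---------------------------------------------------------------------------

# TG-T allele distribution: bulk of alleles benign TG11-T7 / TG10-T9; the
# CBAVD-risk T5 alleles at roughly the cohort's reported allele rates
TGT_ALLELE_FREQS: dict[tuple[int, int], float] = {
    (11, 7): 0.60,
    (10, 9): 0.14,
    (11, 9): 0.08,
    (12, 7): 0.05,
    (10, 5): 0.034,
    (11, 5): 0.031,
    (12, 5): 0.020,
    (13, 5): 0.010,
    (9, 4): 0.015,
    (14, 6): 0.020,
}


def sample_cohort(catalog: list[TruthVariant], config: SimulationConfig,
                  max_attempts: int = 50) -> list[SampleTruth]:
    """Draw per-sample truth genotypes, phases, CNV state, TG-T diplotypes and
    dropout regions. Deterministic for a fixed config."""
    by_id = {v.id: v for v in catalog}
    small = [v for v in catalog if v.vtype in ("SNV", "insertion", "deletion")]
    large = [v for v in catalog if v.vtype == "large_deletion"]
    tgt_alleles = list(TGT_ALLELE_FREQS)
    tgt_p = np.array(list(TGT_ALLELE_FREQS.values()))
    tgt_p = tgt_p / tgt_p.sum()

    samples: list[SampleTruth] = []
    master = np.random.default_rng([config.seed & 0x7FFFFFFF, 0x5A5A])
    del_carriers = set(master.choice(config.n_samples,
                                     size=min(config.n_deletion_carriers, config.n_samples),
                                     replace=False)) if large and config.n_deletion_carriers else set()
    forced: dict[int, list[str]] = {}
    if config.dropout:
        nxt = 0
        for vid in DROPOUT_VARIANTS:
            n = min(DROPOUT_CARRIERS[vid], config.n_samples)
            for _ in range(n):
                forced.setdefault(nxt % config.n_samples, []).append(vid)
                nxt += 1

    for si in range(config.n_samples):
        sid = f"S{si + 1:03d}"
        rng = sample_rng(config, sid, stream=0)
        for _attempt in range(max_attempts):
            genotypes: dict[str, str] = {}
            for v in small:
                u = rng.random()
                if u < v.hom_freq:
                    genotypes[v.id] = "hom"
                elif u < v.hom_freq + v.het_freq:
                    genotypes[v.id] = "het"
            for vid in forced.get(si, ()):
                genotypes.setdefault(vid, "het")
            cnv = None
            if si in del_carriers:
                ld = large[0]
                cnv = {"exon_span": ld.exon_span, "copies": 0, "variant_id": ld.id}
                genotypes = {vid: g for vid, g in genotypes.items()
                             if not _overlaps(by_id[vid].locus, ld.locus)}
                genotypes[ld.id] = "hom"
            phases = _assign_phases(genotypes, by_id, rng)
            if phases is not None:
                break
        else:
            raise AssignmentError(f"{sid}: no compatible phase assignment "
                                  f"after {max_attempts} attempts")

        ai, aj = rng.choice(len(tgt_alleles), size=2, p=tgt_p)
        truth = SampleTruth(sample_id=sid, genotypes=genotypes, phases=phases,
                            cnv=cnv, tgt_diplotype=(tgt_alleles[ai], tgt_alleles[aj]))
        for vid in forced.get(si, ()):
            lo, hi = by_id[vid].locus
            truth.dropout_regions.append((lo, hi))
        samples.append(truth)
    return samples


def _overlaps(a: tuple[int, int], b: tuple[int, int]) -> bool:
    return a[0] < b[1] and b[0] < a[1]


def _assign_phases(genotypes: dict[str, str], by_id: dict[str, TruthVariant],
                   rng: np.random.Generator) -> dict[str, int] | None:
    """Random haplotype assignment; None if overlapping variants collide on a
    haplotype (caller retries the whole genotype draw)."""
    phases: dict[str, int] = {}
    spans: dict[int, list[tuple[int, int]]] = {0: [], 1: []}
    for vid, g in sorted(genotypes.items()):
        v = by_id[vid]
        if v.vtype == "large_deletion":
            phases[vid] = 2
            continue
        haps = (0, 1) if g == "hom" else (int(rng.integers(2)),)
        for h in haps:
            if any(_overlaps(v.locus, s) for s in spans[h]):
                return None
            spans[h].append(v.locus)
        phases[vid] = 2 if g == "hom" else haps[0]
    return phases


# ---------------------------------------------------------------------------
# Read simulation
# ---------------------------------------------------------------------------

def panel_redundancy(panel: AmpliconPanel) -> float:
    """Mean number of amplicon inserts covering a target base (the overlap
    redundancy of the tiling); used so ``mean_depth`` is the observed mean
    per-base target depth rather than the per-amplicon read count."""
    footprint = 0
    for a in panel.amplicons:
        for s, e in panel.target_regions:
            lo, hi = max(a.insert[0], s), min(a.insert[1], e)
            if lo < hi:
                footprint += hi - lo
    return footprint / panel.target_length()


def amplicon_efficiencies(panel: AmpliconPanel, config: SimulationConfig) -> np.ndarray:
    """Per-amplicon PCR efficiency factors (log-normal, normalized to mean 1),
    a property of the panel + reference build shared by every sample."""
    rng = np.random.default_rng([config.seed & 0x7FFFFFFF, 0xEFF])
    eff = rng.lognormal(0.0, config.amplicon_efficiency_sigma, size=panel.n_amplicons)
    return eff / eff.mean()


def simulate_amplicon_counts(truth: SampleTruth, panel: AmpliconPanel,
                             config: SimulationConfig,
                             model: GeneModel) -> np.ndarray:
    """Per-amplicon read counts for one sample.

    Counts are negative binomial around mean_depth corrected for tiling
    redundancy, scaled by the shared per-amplicon efficiency, a per-sample
    pool-1/pool-2 yield imbalance, and the CNV copy state; amplicons over
    dropout regions emit zero reads.

    Shares its random stream with :func:`simulate_reads`, which draws the same
    counts before materializing reads.
    """
    rng = sample_rng(config, truth.sample_id, stream=1)
    r = config.depth_dispersion
    counts = np.empty(panel.n_amplicons, dtype=int)
    redundancy = panel_redundancy(panel)
    eff = amplicon_efficiencies(panel, config)
    pool_factor = rng.lognormal(0.0, config.pool_imbalance_sigma) \
        / np.exp(config.pool_imbalance_sigma ** 2 / 2)
    del_region = None
    copies = 2
    if truth.cnv is not None:
        lo, hi = truth.cnv["exon_span"]
        del_region = (model.exons[lo - 1][0], model.exons[hi - 1][1])
        copies = truth.cnv["copies"]
    for i, a in enumerate(panel.amplicons):
        m = config.mean_depth * a.insert_length / config.read_length / redundancy
        m *= eff[i]
        if a.pool == 1:
            m *= pool_factor
        if del_region is not None and _overlaps(a.insert, del_region):
            m *= copies / 2.0
        if any(_overlaps(a.insert, d) for d in truth.dropout_regions):
            m = 0.0
        counts[i] = 0 if m == 0 else rng.negative_binomial(r, r / (r + m))
    return counts


def build_haplotype(seq: str, insert: tuple[int, int],
                    edits: list[tuple[int, int, str]]) -> tuple[str, tuple[tuple[str, int], ...]]:
    """Apply raw edits (all fully inside the insert) to the reference insert;
    return (haplotype sequence, CIGAR vs reference)."""
    s, e = insert
    parts: list[str] = []
    cig: list[tuple[str, int]] = []

    def emit(op: str, n: int) -> None:
        if n <= 0:
            return
        if cig and cig[-1][0] == op:
            cig[-1] = (op, cig[-1][1] + n)
        else:
            cig.append((op, n))

    pos = s
    for es, ee, rep in sorted(edits):
        parts.append(seq[pos:es])
        emit("M", es - pos)
        span = ee - es
        ref_piece = seq[es:ee]
        c = 0
        while c < min(span, len(rep)) and ref_piece[c] == rep[c]:
            c += 1
        if span == len(rep):            # length-preserving substitution
            parts.append(rep)
            emit("M", span)
        else:
            parts.append(rep[:c])
            emit("M", c)
            emit("D", span - c)
            parts.append(rep[c:])
            emit("I", len(rep) - c)
        pos = ee
    parts.append(seq[pos:e])
    emit("M", e - pos)
    return "".join(parts), tuple(cig)


def _sample_edits(truth: SampleTruth, catalog_by_id: dict[str, TruthVariant],
                  model: GeneModel) -> dict[int, list[tuple[int, int, str]]]:
    """Raw edits per haplotype (0/1), including the TG-T tract replacement."""
    edits: dict[int, list[tuple[int, int, str]]] = {0: [], 1: []}
    for vid, phase in truth.phases.items():
        v = catalog_by_id[vid]
        if v.vtype == "large_deletion":
            continue
        ed = variant_edit(v)
        for h in ((0, 1) if phase == 2 else (phase,)):
            edits[h].append(ed)
    tract = model.tgt_tract
    if tract is not None:
        for h, (tg, t) in enumerate(truth.tgt_diplotype):
            if (tg, t) != (tract.tg_ref, tract.t_ref):
                edits[h].append((tract.repeat_start, tract.repeat_end,
                                 "TG" * tg + "T" * t))
    return edits


def simulate_reads(truth: SampleTruth, panel: AmpliconPanel,
                   config: SimulationConfig, model: GeneModel,
                   seq: str, catalog: list[TruthVariant]) -> list[AlignedRead]:
    """Emit gaplessly placed aligned reads for one sample.

    Each read spans its amplicon insert exactly; het variants alternate
    haplotypes read-by-read (alt fraction exactly 0.5 before error), strands
    are i.i.d. at ``strand_balance``, substitution errors are applied at
    ``base_error_rate`` per base.
    """
    if any(a.insert_length > config.read_length for a in panel.amplicons):
        raise SizingError("read_length shorter than an amplicon insert")
    by_id = {v.id: v for v in catalog}
    counts = simulate_amplicon_counts(truth, panel, config, model)
    rng = sample_rng(config, truth.sample_id, stream=2)
    edits = _sample_edits(truth, by_id, model)

    reads: list[AlignedRead] = []
    for a, n in zip(panel.amplicons, counts):
        if n == 0:
            continue
        haps = []
        for h in (0, 1):
            inside = [ed for ed in edits[h] if ed[0] >= a.insert[0] and ed[1] <= a.insert[1]]
            haps.append(build_haplotype(seq, a.insert, inside))
        strands = np.where(rng.random(n) < config.strand_balance, "+", "-")
        identical = haps[0] == haps[1]
        for i in range(int(n)):
            hseq, hcig = haps[0] if (identical or i % 2 == 0) else haps[1]
            if config.base_error_rate > 0:
                arr = np.frombuffer(hseq.encode(), dtype=np.uint8).copy()
                mask = rng.random(arr.size) < config.base_error_rate
                if mask.any():
                    idx = np.flatnonzero(mask)
                    offs = rng.integers(1, 4, size=idx.size)
                    lut = {65: "ACGT", 67: "CGTA", 71: "GTAC", 84: "TACG"}
                    for j, o in zip(idx, offs):
                        arr[j] = ord("ACGT"[("ACGT".index(chr(arr[j])) + o) % 4])
                hseq = arr.tobytes().decode()
            reads.append(AlignedRead(
                name=f"{truth.sample_id}:{a.id}:{i}", sample_id=truth.sample_id,
                start=a.insert[0], strand=str(strands[i]), cigar=hcig, seq=hseq))
    return reads
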