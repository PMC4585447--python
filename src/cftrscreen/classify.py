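"""Variant annotation against toy population/mutation databases and the
four-tier pathogenicity classification.

Tier rules, in order of precedence:

1. a mutation-database entry fixes the tier (previously described changes are
   directly annotated; a conflict with rule 2 is flagged, the DB wins);
2. truncating classes — nonsense, frameshift, large rearrangements and
   canonical (+/-1,2) splice-site changes — are definitely pathogenic;
3. missense / in-frame / noncanonical-splice changes are put to a vote over
   in-silico predictor verdicts: >= 3/4 deleterious -> likely pathogenic,
   <= 1/4 -> neutral, otherwise uncertain (as is any variant with previously
   conflicting published evidence);
4. synonymous and deep-intronic changes with no DB entry are neutral.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from .calling import VariantCall
from .simulate import GeneModel, TruthVariant, cdna_name

__all__ = [
    "VariantAnnotation",
    "ClassifiedVariant",
    "PopDB",
    "MutDB",
    "annotate",
    "frequency_filter",
    "classify",
    "consequence_of",
    "build_databases",
    "COMMON_FREQ",
]

COMMON_FREQ = 0.05              # >=5% population frequency => common polymorphism
CANONICAL_SPLICE_BP = 2         # +/-1,2 intronic bases
NONCANONICAL_SPLICE_BP = 8      # 3..8 intronic bases
VOTE_HI = 0.75
VOTE_LO = 0.25

TIERS = ("definitely_pathogenic", "likely_pathogenic", "uncertain", "neutral")

PopDB = dict[tuple[int, str, str], float]       # (pos, ref, alt) -> population freq
MutDB = dict[tuple[int, str, str], str]         # (pos, ref, alt) -> tier


class AnnotationError(ValueError):
    pass


@dataclass
class VariantAnnotation:
    call: VariantCall
    consequence: str
    cdna_name: str
    population_freq: float | None = None
    db_tier: str | None = None
    predictor_scores: tuple[bool, ...] = ()
    conflicting_evidence: bool = False


@dataclass
class ClassifiedVariant:
    annotation: VariantAnnotation
    tier: str
    evidence: list[str] = field(default_factory=list)


def _coding_map(model: GeneModel) -> dict[int, int]:
    cds: dict[int, int] = {}
    i = 0
    for s, e in model.exons:
        for p in range(s, e):
            cds[p] = i
            i += 1
    return cds


def _intron_distance(model: GeneModel, pos: int) -> int | None:
    """1-based distance into the nearest intron, None if pos is exonic."""
    if model.exon_of(pos) is not None:
        return None
    best = None
    for s, e in model.exons:
        for d in (s - pos, pos - e + 1):
            if d > 0:
                best = d if best is None else min(best, d)
    return best


def consequence_of(pos: int, ref: str, alt: str, model: GeneModel, seq: str) -> str:
    """Positional/codon-level consequence of a normalized (pos, ref, alt)."""
    if not (0 <= pos < model.sequence_length):
        raise AnnotationError(f"position {pos} outside gene bounds")
    if len(ref) == len(alt) == 1:
        span = (pos, pos + 1)
    elif len(ref) > len(alt):
        span = (pos + 1, pos + len(ref))        # deleted bases
    else:
        span = (pos, pos + 2)                   # insertion between pos and pos+1

    exonic = any(s < span[1] and span[0] < e for s, e in model.exons)
    if not exonic:
        d = min(x for x in (_intron_distance(model, p) for p in range(*span))
                if x is not None)
        if d <= CANONICAL_SPLICE_BP:
            return "canonical_splice"
        if d <= NONCANONICAL_SPLICE_BP:
            return "noncanonical_splice"
        return "intronic"

    cds_start = model.exons[0][0] + model.coding_offset
    if span[1] <= cds_start:
        return "utr"

    if len(ref) != len(alt):
        return "frameshift" if abs(len(ref) - len(alt)) % 3 else "missense"

    cds = _coding_map(model)
    if pos not in cds:
        return "intronic"
    i = cds[pos] - model.coding_offset
    frame = i % 3
    codon_positions = []
    j = 0
    for s, e in model.exons:
        for p in range(s, e):
            if (j - model.coding_offset) // 3 == i // 3 and j >= model.coding_offset:
                codon_positions.append(p)
            j += 1
    if len(codon_positions) != 3:
        return "missense"       # partial codon at gene edge
    codon = "".join(seq[p] for p in codon_positions)
    mut = list(codon)
    mut[frame] = alt
    aa_ref = str(Seq(codon).translate())
    aa_alt = str(Seq("".join(mut)).translate())
    if aa_alt == aa_ref:
        return "synonymous"
    if aa_alt == "*":
        return "nonsense"
    return "missense"


def annotate(call: VariantCall, model: GeneModel, seq: str,
             popdb: PopDB | None = None, mutdb: MutDB | None = None,
             predictors: dict[tuple[int, str, str], tuple[bool, ...]] | None = None,
             consequence: str | None = None) -> VariantAnnotation:
    """Annotate a PASS call: consequence from gene geometry + allele, cDNA
    label, and normalized-key lookups in the toy databases."""
    key = call.key
    cons = consequence if consequence is not None else \
        consequence_of(call.pos, call.ref, call.alt, model, seq)
    return VariantAnnotation(
        call=call,
        consequence=cons,
        cdna_name=cdna_name(model, call.pos, call.ref, call.alt),
        population_freq=(popdb or {}).get(key),
        db_tier=(mutdb or {}).get(key),
        predictor_scores=(predictors or {}).get(key, ()),
    )


def frequency_filter(ann: VariantAnnotation) -> bool:
    """True = keep. Common polymorphisms (>=5% population frequency) are
    discarded unless the mutation database lists them (those databases also
    contain known disease-associated mutations)."""
    if ann.population_freq is not None and ann.population_freq >= COMMON_FREQ \
            and ann.db_tier is None:
        return False
    return True


_TRUNCATING = {"nonsense", "frameshift", "large_rearrangement", "canonical_splice"}
_VOTED = {"missense", "noncanonical_splice"}


def classify(ann: VariantAnnotation,
             vote_hi: float = VOTE_HI, vote_lo: float = VOTE_LO) -> ClassifiedVariant:
    """Assign the pathogenicity tier by the ordered rules (module docstring)."""
    evidence: list[str] = []
    if ann.db_tier is not None:
        evidence.append("mutation_db")
        if ann.consequence in _TRUNCATING and ann.db_tier != "definitely_pathogenic":
            evidence.append("db_overrides_truncating_rule")
        return ClassifiedVariant(annotation=ann, tier=ann.db_tier, evidence=evidence)
    if ann.consequence in _TRUNCATING:
        return ClassifiedVariant(annotation=ann, tier="definitely_pathogenic",
                                 evidence=["truncating_class"])
    if ann.consequence in _VOTED:
        if ann.conflicting_evidence:
            return ClassifiedVariant(annotation=ann, tier="uncertain",
                                     evidence=["conflicting_published_evidence"])
        votes = ann.predictor_scores
        if not votes:
            return ClassifiedVariant(annotation=ann, tier="uncertain",
                                     evidence=["no_predictor_data"])
        frac = sum(votes) / len(votes)
        if frac >= vote_hi:
            return ClassifiedVariant(annotation=ann, tier="likely_pathogenic",
                                     evidence=[f"predictor_vote_{sum(votes)}_of_{len(votes)}"])
        if frac <= vote_lo:
            return ClassifiedVariant(annotation=ann, tier="neutral",
                                     evidence=[f"predictor_vote_{sum(votes)}_of_{len(votes)}"])
        return ClassifiedVariant(annotation=ann, tier="uncertain",
                                 evidence=[f"predictor_vote_{sum(votes)}_of_{len(votes)}"])
    return ClassifiedVariant(annotation=ann, tier="neutral",
                             evidence=["no_functional_class"])


def build_databases(catalog: list[TruthVariant]) -> tuple[PopDB, MutDB, dict]:
    """Toy population-frequency and mutation databases plus packaged predictor
    verdicts, keyed by normalized (pos, ref, alt)."""
    popdb: PopDB = {}
    mutdb: MutDB = {}
    predictors: dict[tuple[int, str, str], tuple[bool, ...]] = {}
    for v in catalog:
        if v.vtype == "large_deletion":
            continue
        key = (v.pos, v.ref_allele, v.alt_allele)
        if v.population_freq is not None:
            popdb[key] = v.population_freq
        if v.in_mutation_db:
            mutdb[key] = v.tier
        if v.predictor_verdicts:
            predictors[key] = v.predictor_verdicts
    return popdb, mutdb, predictors
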