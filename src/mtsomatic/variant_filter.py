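"""Union-merge of two callers' chrM calls and the full somatic filter stack.

The filter chain evaluates, for every candidate variant, in a fixed audit
order and without short-circuiting:

* position blacklist (NUMT / homopolymer regions; one region is indel-only),
* read-evidence criteria — support >=10 reads, base quality >=20, forward
  strand fraction strictly inside (0.1, 0.9), mean read position strictly
  inside (0.15, 0.85) measured from both read ends, reference-minus-variant
  read length < 25, reference-minus-variant mapping quality < 10, normal
  sequence context on > 80% of variant reads (waived next to a germline
  variant), variant-minus-reference edit distance <= 3,
* germline removal against a cohort/panel resource (VAF > 95%), a population
  database (frequency > 1%) and the sample's own paired normal (VAF > 95%),
* a panel-of-normals noise filter: VAF strictly below the per-position noise
  level (mean + 3 SD of normal-sample non-reference fraction, floored) fails.

Variants that pass every criterion are classified as somatic (no signal in
the paired normal) or tumour-specific dysplastic (low-level normal signal
expanded in the tumour). Every verdict carries the complete list of violated
criteria so that the audit table can reconcile pass + fail counts with the
union size.
"""

from __future__ import annotations

import enum
import logging
import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

from .io_formats import (
    ADJACENT_FLAG,
    ANNOTATION_FIELDS,
    BLACKLIST_INDEL,
    SOURCE_COHORT,
    SOURCE_PANEL,
    SOURCE_POPDB,
    BlacklistRegion,
    GermlineResourceEntry,
    RawVariantRecord,
)

logger = logging.getLogger(__name__)


class Reason(str, enum.Enum):
    """Filter reason codes, in canonical audit order."""

    BLACKLIST = "BLACKLIST"
    SUPPORT = "SUPPORT"
    BASE_QUALITY = "BASE_QUALITY"
    STRAND = "STRAND"
    READ_POSITION = "READ_POSITION"
    LENGTH_DIFF = "LENGTH_DIFF"
    MAPQ_DIFF = "MAPQ_DIFF"
    NORMAL_CONTEXT = "NORMAL_CONTEXT"
    NM_DIFF = "NM_DIFF"
    GERMLINE = "GERMLINE"
    BELOW_NOISE = "BELOW_NOISE"
    MISSING_ANNOTATION = "MISSING_ANNOTATION"

    def __str__(self) -> str:  # keep VCF INFO rendering clean
        return self.value


REASON_ORDER = {reason: i for i, reason in enumerate(Reason)}


def _order(reasons: Iterable["Reason"]) -> list:
    return sorted(set(reasons), key=REASON_ORDER.__getitem__)


@dataclass
class MtVariantCall:
    """One candidate chrM variant with the per-read summaries every criterion needs.

    Any evidence field may be ``None`` when the caller did not report it; the
    filter then fails the call with MISSING_ANNOTATION rather than letting it
    pass by default.
    """

    sample_id: str
    position: int
    ref_allele: str
    alt_allele: str
    total_depth: Optional[int] = None
    variant_reads: Optional[int] = None
    forward_variant_reads: Optional[int] = None
    variant_base_quality: Optional[float] = None
    mean_read_position: Optional[float] = None
    ref_read_length: Optional[float] = None
    var_read_length: Optional[float] = None
    ref_mapq: Optional[float] = None
    var_mapq: Optional[float] = None
    normal_context_fraction: Optional[float] = None
    ref_nm: Optional[float] = None
    var_nm: Optional[float] = None
    adjacent_to_germline: bool = False
    callers: frozenset = frozenset()
    provenance: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.ref_allele = self.ref_allele.upper()
        self.alt_allele = self.alt_allele.upper()
        self.callers = frozenset(self.callers)
        if self.variant_reads is not None and self.total_depth is not None:
            if not 0 <= self.variant_reads <= self.total_depth:
                raise ValueError(
                    f"{self.sample_id}:{self.position} variant_reads {self.variant_reads} "
                    f"outside [0, total_depth={self.total_depth}]"
                )
        if (self.forward_variant_reads is not None and self.variant_reads is not None
                and not 0 <= self.forward_variant_reads <= self.variant_reads):
            raise ValueError(
                f"{self.sample_id}:{self.position} forward_variant_reads out of range"
            )

    @property
    def is_indel(self) -> bool:
        return len(self.ref_allele) != len(self.alt_allele)

    @property
    def key(self) -> tuple:
        return (self.position, self.ref_allele, self.alt_allele)

    @property
    def vaf(self) -> Optional[float]:
        if self.variant_reads is None or not self.total_depth:
            return None
        return self.variant_reads / self.total_depth

    @classmethod
    def from_raw(cls, raw: RawVariantRecord, sample_id: str) -> "MtVariantCall":
        kwargs = {}
        for vcf_key, (attr, vtype) in ANNOTATION_FIELDS.items():
            value = raw.annotations.get(vcf_key)
            if value is not None:
                kwargs[attr] = int(round(value)) if vtype == "Integer" else float(value)
        return cls(
            sample_id=sample_id,
            position=raw.position,
            ref_allele=raw.ref_allele,
            alt_allele=raw.alt_allele,
            adjacent_to_germline=bool(raw.annotations.get(ADJACENT_FLAG, False)),
            callers=frozenset({raw.caller_id}),
            **kwargs,
        )


@dataclass
class FilterConfig:
    """Thresholds of the filter chain; defaults are the published recipe."""

    min_variant_reads: int = 10          # inclusive
    min_base_quality: float = 20.0       # inclusive
    strand_fraction_bounds: tuple = (0.1, 0.9)      # open interval
    read_position_bounds: tuple = (0.15, 0.85)      # open interval
    max_len_diff: float = 25.0           # exclusive, ref minus variant
    max_mapq_diff: float = 10.0          # exclusive, ref minus variant
    min_normal_context: float = 0.80     # exclusive
    max_nm_diff: float = 3.0             # inclusive, variant minus ref
    germline_vaf_threshold: float = 0.95       # exclusive
    germline_popfreq_threshold: float = 0.01   # exclusive
    adjacency_window: int = 2            # bp, "next to germline" waiver
    noise_floor: float = 0.005

    def __post_init__(self) -> None:
        for lo, hi in (self.strand_fraction_bounds, self.read_position_bounds):
            if not lo < hi:
                raise ValueError(f"interval ({lo}, {hi}) is empty")


@dataclass
class ClassifyConfig:
    """Interpretive thresholds for the somatic / dysplastic split."""

    somatic_max_normal_vaf: float = 0.01     # strict upper bound for somatic
    dysplastic_max_normal_vaf: float = 0.95  # inclusive upper bound
    min_vaf_difference: float = 0.05         # tumour VAF minus normal VAF, inclusive


@dataclass
class Verdict:
    call: MtVariantCall
    failed_reasons: list

    @property
    def passed(self) -> bool:
        return not self.failed_reasons


@dataclass
class NoiseModel:
    """Per-position VAF noise floor estimated from a panel of normals."""

    per_position: dict
    floor: float = 0.005

    def __post_init__(self) -> None:
        if self.floor < 0:
            raise ValueError("noise floor must be >= 0")
        bad = {p: v for p, v in self.per_position.items() if v < self.floor}
        if bad:
            raise ValueError(f"noise below floor at positions {sorted(bad)}")

    def level(self, position: int) -> float:
        return self.per_position.get(position, self.floor)


LABEL_SOMATIC = "somatic"
LABEL_DYSPLASTIC = "tumour_specific_dysplastic"


@dataclass
class ClassifiedVariant:
    verdict: Verdict
    label: str
    tumour_vaf: float
    normal_vaf: float

    @property
    def call(self) -> MtVariantCall:
        return self.verdict.call


# ---------------------------------------------------------------------------
# caller union
# ---------------------------------------------------------------------------

def union_calls(calls_a: Sequence[MtVariantCall],
                calls_b: Sequence[MtVariantCall]) -> list:
    """Union of two callers' call sets, one record per (position, ref, alt).

    When both callers report a key, the first list's per-read summaries are
    kept and the second's are recorded under ``provenance['secondary']`` —
    deterministic and auditable. Commutative on keys and caller sets.
    """
    samples = {c.sample_id for c in calls_a} | {c.sample_id for c in calls_b}
    if len(samples) > 1:
        raise ValueError(f"union across different samples: {sorted(samples)}")
    merged: dict = {}
    for call in list(calls_a) + list(calls_b):
        prev = merged.get(call.key)
        if prev is None:
            merged[call.key] = call
            continue
        if prev.is_indel != call.is_indel:
            raise ValueError(f"inconsistent indel status at {call.key}")
        provenance = dict(prev.provenance)
        provenance.setdefault("secondary", {})[",".join(sorted(call.callers))] = {
            attr: getattr(call, attr) for _, (attr, _t) in ANNOTATION_FIELDS.items()
        }
        merged[call.key] = replace(
            prev,
            callers=prev.callers | call.callers,
            adjacent_to_germline=prev.adjacent_to_germline or call.adjacent_to_germline,
            provenance=provenance,
        )
    return [merged[k] for k in sorted(merged)]


# ---------------------------------------------------------------------------
# individual criteria
# ---------------------------------------------------------------------------

def check_position_blacklist(call: MtVariantCall,
                             regions: Sequence[BlacklistRegion]) -> Optional[Reason]:
    """BLACKLIST when the position falls in a listed region (boundaries inclusive).

    Indel-only regions reject only indels; all-variant regions reject everything.
    """
    for region in regions:
        if not region.contains(call.position):
            continue
        if region.applies_to == BLACKLIST_INDEL and not call.is_indel:
            continue
        return Reason.BLACKLIST
    return None


#: evidence criteria: reason -> fields required to evaluate it
_EVIDENCE_REQUIREMENTS = {
    Reason.SUPPORT: ("variant_reads",),
    Reason.BASE_QUALITY: ("variant_base_quality",),
    Reason.STRAND: ("forward_variant_reads", "variant_reads"),
    Reason.READ_POSITION: ("mean_read_position",),
    Reason.LENGTH_DIFF: ("ref_read_length", "var_read_length"),
    Reason.MAPQ_DIFF: ("ref_mapq", "var_mapq"),
    Reason.NORMAL_CONTEXT: ("normal_context_fraction",),
    Reason.NM_DIFF: ("ref_nm", "var_nm"),
}


def check_read_evidence(call: MtVariantCall, config: FilterConfig) -> list:
    """Evaluate the seven read-evidence criteria independently.

    Returns every violated reason; criteria whose inputs are absent
    contribute MISSING_ANNOTATION (fail-closed). The strand-ratio criterion
    is skipped (SUPPORT already fails) when there are no variant reads.
    """
    reasons = []
    missing = False

    def have(reason: Reason) -> bool:
        nonlocal missing
        if any(getattr(call, f) is None for f in _EVIDENCE_REQUIREMENTS[reason]):
            missing = True
            return False
        return True

    if have(Reason.SUPPORT) and call.variant_reads < config.min_variant_reads:
        reasons.append(Reason.SUPPORT)
    if have(Reason.BASE_QUALITY) and call.variant_base_quality < config.min_base_quality:
        reasons.append(Reason.BASE_QUALITY)
    if have(Reason.STRAND) and call.variant_reads > 0:
        lo, hi = config.strand_fraction_bounds
        ratio = call.forward_variant_reads / call.variant_reads
        if not lo < ratio < hi:
            reasons.append(Reason.STRAND)
    if have(Reason.READ_POSITION):
        lo, hi = config.read_position_bounds
        if not lo < call.mean_read_position < hi:
            reasons.append(Reason.READ_POSITION)
    if have(Reason.LENGTH_DIFF) and not (
            call.ref_read_length - call.var_read_length < config.max_len_diff):
        reasons.append(Reason.LENGTH_DIFF)
    if have(Reason.MAPQ_DIFF) and not (
            call.ref_mapq - call.var_mapq < config.max_mapq_diff):
        reasons.append(Reason.MAPQ_DIFF)
    if not call.adjacent_to_germline and have(Reason.NORMAL_CONTEXT) and not (
            call.normal_context_fraction > config.min_normal_context):
        reasons.append(Reason.NORMAL_CONTEXT)
    if have(Reason.NM_DIFF) and not (call.var_nm - call.ref_nm <= config.max_nm_diff):
        reasons.append(Reason.NM_DIFF)

    if missing:
        reasons.append(Reason.MISSING_ANNOTATION)
    return _order(reasons)


# ---------------------------------------------------------------------------
# germline removal
# ---------------------------------------------------------------------------

class GermlineIndex:
    """Lookup structure over the germline resource and a sample's paired normal."""

    def __init__(self, resource: Iterable[GermlineResourceEntry],
                 normal_calls: Iterable[MtVariantCall] = (),
                 config: Optional[FilterConfig] = None) -> None:
        self.config = config or FilterConfig()
        self._panel: dict = {}
        self._popdb: dict = {}
        for entry in resource:
            key = (entry.position, entry.allele)
            target = self._popdb if entry.source == SOURCE_POPDB else self._panel
            target[key] = max(target.get(key, 0.0), entry.frequency_or_vaf)
        self._normal_vaf: dict = {}
        for call in normal_calls:
            if call.vaf is not None:
                key = (call.position, call.alt_allele)
                self._normal_vaf[key] = max(self._normal_vaf.get(key, 0.0), call.vaf)
        self._germline_positions = sorted(
            {p for (p, _a), v in self._panel.items()
             if v > self.config.germline_vaf_threshold}
            | {p for (p, _a), v in self._popdb.items()
               if v > self.config.germline_popfreq_threshold}
            | {p for (p, _a), v in self._normal_vaf.items()
               if v > self.config.germline_vaf_threshold}
        )

    def is_germline(self, position: int, allele: str) -> bool:
        key = (position, allele)
        cfg = self.config
        if self._panel.get(key, 0.0) > cfg.germline_vaf_threshold:
            return True
        if self._popdb.get(key, 0.0) > cfg.germline_popfreq_threshold:
            return True
        return self._normal_vaf.get(key, 0.0) > cfg.germline_vaf_threshold

    def normal_vaf(self, position: int, allele: str) -> float:
        return self._normal_vaf.get((position, allele), 0.0)

    def is_adjacent(self, call: MtVariantCall) -> bool:
        """True when a germline variant lies within the adjacency window."""
        w = self.config.adjacency_window
        for pos in self._germline_positions:
            if abs(pos - call.position) <= w and (pos, call.alt_allele) != (
                    call.position, call.alt_allele):
                return True
            if pos > call.position + w:
                break
        return False


def check_germline(call: MtVariantCall, index: GermlineIndex) -> Optional[Reason]:
    if index.is_germline(call.position, call.alt_allele):
        return Reason.GERMLINE
    return None


def remove_germline(calls: Sequence[MtVariantCall],
                    resource: Iterable[GermlineResourceEntry],
                    normal_calls: Sequence[MtVariantCall],
                    config: Optional[FilterConfig] = None) -> list:
    """Batch germline check; returns one Verdict per call (GERMLINE or clean)."""
    index = GermlineIndex(resource, normal_calls, config)
    verdicts = []
    for call in calls:
        reason = check_germline(call, index)
        verdicts.append(Verdict(call, [reason] if reason else []))
    return verdicts


# ---------------------------------------------------------------------------
# panel-of-normals noise model
# ---------------------------------------------------------------------------

def estimate_noise(normal_calls_by_sample: Mapping[str, Sequence[MtVariantCall]],
                   normal_depths: Optional[Mapping[str, float]] = None,
                   floor: float = 0.005) -> NoiseModel:
    """Per-position VAF noise level from a panel of normal samples.

    At each position with any non-reference signal the level is
    mean + 3*SD of the non-reference allele fraction across the whole panel
    (samples without signal contribute 0; SD is the n-1 sample SD, taken as
    0 for a single-normal panel), clamped below by ``floor``. Positions with
    no signal anywhere sit at the floor. ``normal_depths``, when given, is
    used only to validate that each panel sample was actually covered.
    """
    samples = list(normal_calls_by_sample)
    if not samples:
        raise ValueError("empty normal panel: use a floor-only NoiseModel instead")
    if normal_depths is not None:
        shallow = [s for s in samples if normal_depths.get(s, 1.0) <= 0]
        if shallow:
            raise ValueError(f"normal samples without coverage: {shallow}")
    n = len(samples)
    signal: dict = {}
    for sample in samples:
        per_position: dict = {}
        for call in normal_calls_by_sample[sample]:
            if call.vaf is not None:
                per_position[call.position] = per_position.get(call.position, 0.0) + call.vaf
        for position, vaf in per_position.items():
            signal.setdefault(position, []).append(min(vaf, 1.0))
    per_position_noise = {}
    for position, vafs in signal.items():
        values = vafs + [0.0] * (n - len(vafs))
        mean = sum(values) / n
        if n > 1:
            var = sum((v - mean) ** 2 for v in values) / (n - 1)
            sd = math.sqrt(var)
        else:
            sd = 0.0
        per_position_noise[position] = max(mean + 3.0 * sd, floor)
    return NoiseModel(per_position=per_position_noise, floor=floor)


def apply_noise_filter(call: MtVariantCall, model: NoiseModel) -> Optional[Reason]:
    """BELOW_NOISE when the VAF is strictly below the position's noise level."""
    vaf = call.vaf
    if vaf is None:
        return Reason.MISSING_ANNOTATION
    if vaf < model.level(call.position):
        return Reason.BELOW_NOISE
    return None


# ---------------------------------------------------------------------------
# composition and classification
# ---------------------------------------------------------------------------

def filter_variant(call: MtVariantCall,
                   config: FilterConfig,
                   regions: Sequence[BlacklistRegion],
                   germline_index: Optional[GermlineIndex] = None,
                   noise_model: Optional[NoiseModel] = None) -> Verdict:
    """Full filter chain for one call; every violated criterion is reported.

    The germline-adjacency waiver for the normal-context criterion is
    resolved here: a call is treated as adjacent when either the caller
    flagged it or a germline variant lies within the configured window.
    """
    reasons = []
    blacklisted = check_position_blacklist(call, regions)
    if blacklisted:
        reasons.append(blacklisted)
    effective = call
    if germline_index is not None and not call.adjacent_to_germline:
        if germline_index.is_adjacent(call):
            effective = replace(call, adjacent_to_germline=True)
    reasons.extend(check_read_evidence(effective, config))
    if germline_index is not None:
        germline = check_germline(call, germline_index)
        if germline:
            reasons.append(germline)
    if noise_model is not None:
        noisy = apply_noise_filter(call, noise_model)
        if noisy:
            reasons.append(noisy)
    return Verdict(effective, _order(reasons))


def classify_somatic_status(tumour_call: MtVariantCall,
                            normal_vaf: float,
                            config: Optional[ClassifyConfig] = None,
                            verdict: Optional[Verdict] = None) -> Optional[ClassifiedVariant]:
    """Label a passing tumour call as somatic or tumour-specific dysplastic.

    Somatic: essentially no signal in the paired normal (VAF < 1%).
    Dysplastic: present at low level in the normal (1%..95%) but expanded in
    the tumour by at least the configured VAF difference. Anything else
    (e.g. near-fixed in the normal, or no real expansion) is dropped from
    classified output with a log line.
    """
    if not 0.0 <= normal_vaf <= 1.0:
        raise ValueError(f"normal VAF {normal_vaf} outside [0,1]")
    config = config or ClassifyConfig()
    tumour_vaf = tumour_call.vaf
    if tumour_vaf is None:
        raise ValueError("tumour call has no VAF; cannot classify")
    if verdict is None:
        verdict = Verdict(tumour_call, [])
    if not verdict.passed:
        raise ValueError("only passing verdicts are classified")
    if normal_vaf < config.somatic_max_normal_vaf:
        label = LABEL_SOMATIC
    elif (normal_vaf <= config.dysplastic_max_normal_vaf
          and tumour_vaf - normal_vaf >= config.min_vaf_difference):
        label = LABEL_DYSPLASTIC
    else:
        logger.info(
            "%s:%d %s>%s dropped from classification (tumour VAF %.3f, normal VAF %.3f)",
            tumour_call.sample_id, tumour_call.position,
            tumour_call.ref_allele, tumour_call.alt_allele, tumour_vaf, normal_vaf)
        return None
    return ClassifiedVariant(verdict=verdict, label=label,
                             tumour_vaf=tumour_vaf, normal_vaf=normal_vaf)
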