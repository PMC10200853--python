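"""Readers and writers for every external file the pipeline touches.

All mitochondrial coordinates are 1-based inclusive on the 16,569 bp
reference (rCRS numbering). Contig names are normalized to a single
canonical name (``chrM``) on input; BED-style inputs declared as
0-based half-open are converted at the boundary so that nothing past
this module ever sees another convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Iterable, Mapping, Optional

import pysam

logger = logging.getLogger(__name__)

CANONICAL_CONTIG = "chrM"
MT_LENGTH = 16569
#: contig spellings accepted on input and mapped to CANONICAL_CONTIG
MITO_ALIASES = {"chrM", "MT", "chrMT", "M"}

CALLER_A = "caller_a"
CALLER_B = "caller_b"
CALLERS = (CALLER_A, CALLER_B)

#: INFO keys carrying per-read summaries, mapped to MtVariantCall attributes.
#: (vcf_key) -> (attribute, VCF Type)
ANNOTATION_FIELDS = {
    "DP": ("total_depth", "Integer"),
    "VR": ("variant_reads", "Integer"),
    "VRF": ("forward_variant_reads", "Integer"),
    "VBQ": ("variant_base_quality", "Float"),
    "MRP": ("mean_read_position", "Float"),
    "RRL": ("ref_read_length", "Float"),
    "VRL": ("var_read_length", "Float"),
    "RMQ": ("ref_mapq", "Float"),
    "VMQ": ("var_mapq", "Float"),
    "NCF": ("normal_context_fraction", "Float"),
    "RNM": ("ref_nm", "Float"),
    "VNM": ("var_nm", "Float"),
}
ADJACENT_FLAG = "ADJGL"

VALID_BASES = set("ACGTN")


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------

@dataclass
class RawVariantRecord:
    """One candidate chrM variant as read from a caller's VCF."""

    contig: str
    position: int  # 1-based, inclusive
    ref_allele: str
    alt_allele: str
    caller_id: str
    annotations: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.contig = normalize_contig(self.contig)
        self.ref_allele = self.ref_allele.upper()
        self.alt_allele = self.alt_allele.upper()
        if not (1 <= self.position <= MT_LENGTH):
            raise ValueError(
                f"position {self.position} outside mitochondrial reference [1, {MT_LENGTH}]"
            )
        if not self.ref_allele or not self.alt_allele:
            raise ValueError("empty allele")
        if self.ref_allele == self.alt_allele:
            raise ValueError(f"ref == alt ({self.ref_allele}) at {self.position}")
        if self.caller_id not in CALLERS:
            raise ValueError(f"unknown caller_id {self.caller_id!r}")

    @property
    def key(self) -> tuple:
        return (self.position, self.ref_allele, self.alt_allele)

    @property
    def missing_annotations(self) -> list:
        """Required per-read summaries absent from this record."""
        return [k for k in ANNOTATION_FIELDS if self.annotations.get(k) is None]


@dataclass
class DepthTableRow:
    """Mean depths at autosomal / chrM germline-variant sites for one sample."""

    sample_id: str
    mean_dp_auto: float
    mean_dp_chrm: float

    def __post_init__(self) -> None:
        if self.mean_dp_auto <= 0 or self.mean_dp_chrm <= 0:
            raise ValueError(
                f"sample {self.sample_id}: depths must be positive "
                f"(got auto={self.mean_dp_auto}, chrm={self.mean_dp_chrm})"
            )


BLACKLIST_ALL = "all_variants"
BLACKLIST_INDEL = "indel_only"


@dataclass(frozen=True)
class BlacklistRegion:
    start: int  # 1-based inclusive
    end: int    # 1-based inclusive
    applies_to: str = BLACKLIST_ALL

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end <= MT_LENGTH):
            raise ValueError(f"blacklist region {self.start}-{self.end} out of range")
        if self.applies_to not in (BLACKLIST_ALL, BLACKLIST_INDEL):
            raise ValueError(f"unknown blacklist scope {self.applies_to!r}")

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


SOURCE_COHORT = "cohort_normals"
SOURCE_PANEL = "external_panel"
SOURCE_POPDB = "population_db"
GERMLINE_SOURCES = (SOURCE_COHORT, SOURCE_PANEL, SOURCE_POPDB)


@dataclass(frozen=True)
class GermlineResourceEntry:
    position: int
    allele: str
    source: str
    frequency_or_vaf: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.frequency_or_vaf <= 1.0:
            raise ValueError(f"frequency_or_vaf {self.frequency_or_vaf} outside [0,1]")
        if self.source not in GERMLINE_SOURCES:
            raise ValueError(f"unknown germline source {self.source!r}")


# ---------------------------------------------------------------------------
# contig / coordinate normalization
# ---------------------------------------------------------------------------

def normalize_contig(name: str) -> str:
    """Map any accepted mitochondrial contig alias to the canonical name.

    Idempotent; non-mitochondrial names are returned unchanged.
    """
    return CANONICAL_CONTIG if name in MITO_ALIASES else name


def convert_interval(start: int, end: int, dialect: str) -> tuple:
    """Convert an on-disk interval to 1-based inclusive coordinates.

    ``dialect`` is ``"1-based-inclusive"`` (identity) or
    ``"0-based-halfopen"`` (BED convention: start+1, end unchanged).
    """
    if dialect == "1-based-inclusive":
        return start, end
    if dialect == "0-based-halfopen":
        return start + 1, end
    raise ValueError(f"unknown coordinate dialect {dialect!r}")


# ---------------------------------------------------------------------------
# VCF
# ---------------------------------------------------------------------------

def _variant_header(sample_id: Optional[str] = None) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.contigs.add(CANONICAL_CONTIG, length=MT_LENGTH)
    for key, (attr, vtype) in ANNOTATION_FIELDS.items():
        header.info.add(key, 1, vtype, f"Per-read summary: {attr}")
    header.info.add(ADJACENT_FLAG, 0, "Flag", "Variant lies within 2 bp of a germline variant")
    header.info.add("REASONS", ".", "String", "Filter reason codes (empty when passing)")
    header.filters.add("FAIL", None, None, "Failed one or more filter criteria")
    if sample_id is not None:
        header.add_line(f"##mtsomatic_sample={sample_id}")
    return header


def read_vcf_sample_id(path) -> Optional[str]:
    """Sample id recorded in the ``##mtsomatic_sample=`` header line, if any."""
    with pysam.VariantFile(str(path)) as vf:
        for line in str(vf.header).splitlines():
            if line.startswith("##mtsomatic_sample="):
                return line.split("=", 1)[1].strip()
    return None


def read_variant_vcf(path, caller_id: str) -> list:
    """Read mitochondrial records from a caller's VCF.

    Multi-allelic sites are split into one record per alt allele (per-site
    INFO values are replicated onto each split record). Records on other
    contigs are skipped with a logged count. Records missing a required
    per-read summary are returned with the gap visible in
    ``missing_annotations``, never dropped silently.
    """
    records = []
    skipped = 0
    try:
        vf = pysam.VariantFile(str(path))
    except (OSError, ValueError) as exc:
        raise ValueError(f"malformed or unreadable VCF {path}: {exc}") from exc
    with vf:
        for rec in vf:
            if normalize_contig(rec.contig) != CANONICAL_CONTIG:
                skipped += 1
                continue
            alts = rec.alts or ()
            for i, alt in enumerate(alts):
                if alt is None or set(alt.upper()) - VALID_BASES:
                    continue  # symbolic alleles are not mtDNA small variants
                ann = {}
                for key in ANNOTATION_FIELDS:
                    if key not in rec.info:
                        continue
                    value = rec.info[key]
                    if isinstance(value, tuple):
                        value = value[i] if i < len(value) else value[0]
                    ann[key] = value
                ann[ADJACENT_FLAG] = ADJACENT_FLAG in rec.info
                records.append(
                    RawVariantRecord(
                        contig=rec.contig,
                        position=rec.pos,
                        ref_allele=rec.ref,
                        alt_allele=alt,
                        caller_id=caller_id,
                        annotations=ann,
                    )
                )
    if skipped:
        logger.info("%s: ignored %d records on non-mitochondrial contigs", path, skipped)
    return records


def write_variant_vcf(calls: Iterable, path, sample_id: Optional[str] = None,
                      reasons_by_key: Optional[Mapping] = None) -> None:
    """Write calls (RawVariantRecord or MtVariantCall) to an uncompressed VCF.

    ``reasons_by_key`` optionally maps (position, ref, alt) to a list of
    filter reason codes written to INFO/REASONS and the FILTER column.
    """
    header = _variant_header(sample_id)
    calls = sorted(calls, key=lambda c: _call_key(c))
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for call in calls:
            pos, ref, alt = _call_key(call)
            rec = out.new_record(
                contig=CANONICAL_CONTIG,
                start=pos - 1,
                stop=pos - 1 + len(ref),
                alleles=(ref, alt),
            )
            for key, (attr, vtype) in ANNOTATION_FIELDS.items():
                value = _get_annotation(call, key, attr)
                if value is None:
                    continue
                rec.info[key] = int(value) if vtype == "Integer" else float(value)
            if _get_adjacent(call):
                rec.info[ADJACENT_FLAG] = True
            if reasons_by_key is not None:
                reasons = list(reasons_by_key.get((pos, ref, alt), []))
                if reasons:
                    rec.info["REASONS"] = ",".join(str(r) for r in reasons)
                    rec.filter.add("FAIL")
                else:
                    rec.filter.add("PASS")
            out.write(rec)


def _call_key(call) -> tuple:
    if hasattr(call, "key"):
        return call.key
    return (call.position, call.ref_allele, call.alt_allele)


def _get_annotation(call, vcf_key: str, attr: str):
    if hasattr(call, "annotations"):  # RawVariantRecord
        return call.annotations.get(vcf_key)
    return getattr(call, attr, None)


def _get_adjacent(call) -> bool:
    if hasattr(call, "annotations"):
        return bool(call.annotations.get(ADJACENT_FLAG, False))
    return bool(getattr(call, "adjacent_to_germline", False))


# ---------------------------------------------------------------------------
# TSV tables
# ---------------------------------------------------------------------------

def _read_tsv_rows(path) -> tuple:
    """(header fields, data rows) of a TSV, skipping '#' comment lines."""
    header = None
    rows = []
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
            else:
                rows.append(dict(zip(header, fields)))
    return header or [], rows


def read_depth_table(path) -> list:
    """Read the per-sample depth summary TSV (sample_id, mean_dp_auto, mean_dp_chrm)."""
    header, rows = _read_tsv_rows(path)
    required = {"sample_id", "mean_dp_auto", "mean_dp_chrm"}
    if not required <= set(header):
        raise ValueError(f"{path}: depth table must have columns {sorted(required)}")
    out, seen = [], set()
    for row in rows:
        sid = row["sample_id"]
        if sid in seen:
            raise ValueError(f"{path}: duplicate sample_id {sid!r}")
        seen.add(sid)
        out.append(DepthTableRow(sid, float(row["mean_dp_auto"]), float(row["mean_dp_chrm"])))
    return out


def write_depth_table(rows: Iterable, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tmean_dp_auto\tmean_dp_chrm\n")
        for r in rows:
            fh.write(f"{r.sample_id}\t{r.mean_dp_auto:.6g}\t{r.mean_dp_chrm:.6g}\n")


def read_purity_table(path) -> list:
    """Read the purity/ploidy TSV (sample_id, f, ploidy) into PurityPloidy rows."""
    from .copy_number import PurityPloidy

    header, rows = _read_tsv_rows(path)
    required = {"sample_id", "f", "ploidy"}
    if not required <= set(header):
        raise ValueError(f"{path}: purity table must have columns {sorted(required)}")
    out, seen = [], set()
    for row in rows:
        sid = row["sample_id"]
        if sid in seen:
            raise ValueError(f"{path}: duplicate sample_id {sid!r}")
        seen.add(sid)
        out.append(PurityPloidy(sid, float(row["f"]), float(row["ploidy"])))
    return out


def write_purity_table(rows: Iterable, path) -> None:
    with open(path, "w") as fh:
        fh.write("sample_id\tf\tploidy\n")
        for r in rows:
            fh.write(f"{r.sample_id}\t{r.f:.6g}\t{r.ploidy:.6g}\n")


def read_blacklist(path, dialect: Optional[str] = None) -> list:
    """Read a BED-like blacklist into 1-based inclusive regions.

    The coordinate dialect may be declared in a ``#coords=`` header line or
    passed explicitly; the explicit argument wins. A third/‌fourth column
    value of ``indel`` marks indel-only regions. Overlapping regions of the
    same scope are merged with a warning.
    """
    declared = "1-based-inclusive"
    regions = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            if line.startswith("#"):
                if line.lower().startswith("#coords="):
                    declared = line.split("=", 1)[1].strip()
                continue
            fields = line.split("\t")
            if len(fields) < 2:
                raise ValueError(f"{path}: blacklist line needs >=2 columns: {line!r}")
            start, end = convert_interval(int(fields[0]), int(fields[1]),
                                          dialect or declared)
            scope = BLACKLIST_ALL
            if len(fields) > 2 and fields[2].strip().lower().startswith("indel"):
                scope = BLACKLIST_INDEL
            regions.append(BlacklistRegion(start, end, scope))
    return merge_blacklist(regions)


def merge_blacklist(regions: list) -> list:
    """Merge overlapping regions of equal scope, warning when any merge occurs."""
    merged = []
    for scope in (BLACKLIST_ALL, BLACKLIST_INDEL):
        group = sorted((r for r in regions if r.applies_to == scope),
                       key=lambda r: (r.start, r.end))
        for region in group:
            if merged and merged[-1].applies_to == scope and region.start <= merged[-1].end:
                logger.warning("merging overlapping blacklist regions %s and %s",
                               merged[-1], region)
                merged[-1] = BlacklistRegion(merged[-1].start,
                                             max(merged[-1].end, region.end), scope)
            else:
                merged.append(region)
    return sorted(merged, key=lambda r: (r.start, r.end))


def load_default_blacklist() -> list:
    """The packaged default NUMT/homopolymer blacklist (8 regions)."""
    with resources.as_file(resources.files("mtsomatic.data") / "blacklist.tsv") as p:
        return read_blacklist(p)


def read_germline_resource(path) -> list:
    """Read the germline-polymorphism resource TSV (position, allele, source, frequency_or_vaf)."""
    header, rows = _read_tsv_rows(path)
    required = {"position", "allele", "source", "frequency_or_vaf"}
    if not required <= set(header):
        raise ValueError(f"{path}: germline resource must have columns {sorted(required)}")
    return [
        GermlineResourceEntry(int(r["position"]), r["allele"].upper(),
                              r["source"], float(r["frequency_or_vaf"]))
        for r in rows
    ]


def write_germline_resource(entries: Iterable, path) -> None:
    with open(path, "w") as fh:
        fh.write("position\tallele\tsource\tfrequency_or_vaf\n")
        for e in entries:
            fh.write(f"{e.position}\t{e.allele}\t{e.source}\t{e.frequency_or_vaf:.6g}\n")


def read_sidecar_annotations(path) -> dict:
    """Read a sidecar annotation TSV keyed on (sample_id, position, ref, alt).

    Columns beyond the key are VCF annotation keys (DP, VR, ...); used to
    supply per-read summaries a caller's VCF lacks.
    """
    header, rows = _read_tsv_rows(path)
    key_cols = {"sample_id", "position", "ref", "alt"}
    if not key_cols <= set(header):
        raise ValueError(f"{path}: sidecar must have columns {sorted(key_cols)}")
    sidecar = {}
    for row in rows:
        key = (row["sample_id"], int(row["position"]), row["ref"].upper(), row["alt"].upper())
        values = {}
        for col, raw in row.items():
            if col in key_cols or raw in ("", "NA", "."):
                continue
            values[col] = raw == "True" if col == ADJACENT_FLAG else float(raw)
        sidecar[key] = values
    return sidecar


def apply_sidecar(records: list, sidecar: Mapping, sample_id: str) -> list:
    """Fill annotation gaps in ``records`` from a sidecar table (in place)."""
    for rec in records:
        extra = sidecar.get((sample_id,) + rec.key)
        if not extra:
            continue
        for key, value in extra.items():
            if rec.annotations.get(key) is None:
                rec.annotations[key] = value
    return records


def read_sample_sheet(path) -> list:
    """Read the sample sheet TSV (sample_id, patient_id, role, group, paired_normal)."""
    header, rows = _read_tsv_rows(path)
    required = {"sample_id", "patient_id", "role", "group"}
    if not required <= set(header):
        raise ValueError(f"{path}: sample sheet must have columns {sorted(required)}")
    for row in rows:
        if row["role"] not in ("tumour", "normal"):
            raise ValueError(f"{path}: role must be tumour/normal, got {row['role']!r}")
    return rows


def write_sample_sheet(rows: Iterable[Mapping], path) -> None:
    cols = ["sample_id", "patient_id", "role", "group", "paired_normal"]
    with open(path, "w") as fh:
        fh.write("\t".join(cols) + "\n")
        for row in rows:
            fh.write("\t".join(str(row.get(c, "")) for c in cols) + "\n")
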