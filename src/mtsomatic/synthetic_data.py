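"""Synthetic paired tumour/normal chrM cohorts with known ground truth.

The generator emulates the statistical structure of the pipeline's inputs so
that every stage is testable without restricted-access sequencing data:

* per-sample mean depths at autosomal and chrM sites, negative-binomially
  overdispersed around expectations chosen so that the copy-number estimator
  recovers the simulated true mtDNA copy number in expectation,
* near-fixed germline haplogroup variants shared by a patient's tumour and
  normal, plus population polymorphisms shared across patients,
* true somatic heteroplasmies injected only into tumours, with binomial
  read sampling at the simulated depth,
* sequencing artifacts each designed to violate exactly one named filter
  criterion (strand bias, read-end clustering, blacklist position, low
  support, low base quality, read-length/MAPQ/NM imbalance, broken context),
* low-level position noise present across the normal panel, with tumour
  noise calls placed strictly below the panel's resulting noise level,
* two emulated callers emitting overlapping but non-identical subsets.

One master seed fixes the whole cohort; per-sample substreams are derived by
counter so cohorts are extensible without perturbing earlier samples. The
generated 16,569 bp reference is synthetic (random bases in rCRS
coordinates), not the real rCRS sequence.
"""

from __future__ import annotations

import dataclasses
import json
import shutil
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path
from typing import Optional

import numpy as np

from . import io_formats
from .copy_number import PurityPloidy, correction_factor
from .io_formats import (
    CALLER_A,
    CALLER_B,
    MT_LENGTH,
    SOURCE_COHORT,
    SOURCE_POPDB,
    DepthTableRow,
    GermlineResourceEntry,
    load_default_blacklist,
)
from .variant_filter import MtVariantCall, Reason, estimate_noise, union_calls

BASES = np.array(list("ACGT"))

LABEL_TRUE_SOMATIC = "true_somatic"
LABEL_GERMLINE = "germline"
LABEL_NOISE = "noise"
ARTIFACT_PREFIX = "artifact:"

#: artifact classes the generator can inject, keyed by the criterion each violates
ARTIFACT_REASONS = (
    Reason.STRAND, Reason.READ_POSITION, Reason.BLACKLIST, Reason.SUPPORT,
    Reason.BASE_QUALITY, Reason.LENGTH_DIFF, Reason.MAPQ_DIFF,
    Reason.NORMAL_CONTEXT, Reason.NM_DIFF,
)


@dataclass(frozen=True)
class GroupSpec:
    """One tumour group: its size, copy-number range and somatic burden."""

    name: str
    n: int
    mtcn_range: tuple = (100.0, 2000.0)
    somatic_rate: float = 2.0  # Poisson mean per tumour


def _default_groups() -> tuple:
    # cohort composition mirroring the study groups at desk scale:
    # BHD tumours carry higher mtCN and fewer somatic variants than
    # sporadic ChRCC
    return (
        GroupSpec("BHD-ChRCC", 10, (500.0, 2000.0), 1.0),
        GroupSpec("BHD-HOCT", 4, (500.0, 2000.0), 1.0),
        GroupSpec("sporadic-ChRCC", 10, (100.0, 800.0), 3.0),
    )


@dataclass
class SimulationSpec:
    """Everything that determines a simulated cohort. One seed fixes it all."""

    seed: int = 0
    groups: tuple = field(default_factory=_default_groups)
    normal_mtcn_range: tuple = (500.0, 1500.0)
    purity_range: tuple = (0.3, 0.9)
    ploidy_choices: tuple = (1.7, 2.0, 2.3)
    n_true_somatic_per_tumour: Optional[int] = None  # fixed count; None -> Poisson per group
    somatic_vaf_range: tuple = (0.1, 0.9)
    somatic_indel_fraction: float = 0.1
    pathogenic_fraction: float = 0.25
    n_germline_haplogroup: int = 30
    n_population_polymorphisms: int = 10
    artifact_rates: dict = field(default_factory=lambda: {
        Reason.STRAND: 0.5, Reason.READ_POSITION: 0.5, Reason.BLACKLIST: 0.5,
        Reason.SUPPORT: 0.5, Reason.BASE_QUALITY: 0.5, Reason.LENGTH_DIFF: 0.25,
        Reason.MAPQ_DIFF: 0.25, Reason.NORMAL_CONTEXT: 0.25, Reason.NM_DIFF: 0.25,
    })
    sequencing_error_vaf: float = 0.002
    n_noise_positions: int = 15
    noise_floor: float = 0.005
    mean_depth_auto: float = 30.0
    depth_overdispersion: float = 30.0  # negative-binomial shape r
    n_auto_sites: int = 2000
    n_chrm_sites: int = 30
    caller_concordance: float = 0.9

    def __post_init__(self) -> None:
        if not 0 <= self.caller_concordance <= 1:
            raise ValueError("caller_concordance outside [0,1]")
        lo, hi = self.purity_range
        if not (0 <= lo <= hi <= 1):
            raise ValueError("purity_range outside [0,1]")
        if any(r < 0 for r in self.artifact_rates.values()):
            raise ValueError("artifact rates must be >= 0")
        lo, hi = self.somatic_vaf_range
        if not (0 < lo <= hi < 1):
            raise ValueError("somatic_vaf_range must sit strictly inside (0,1)")
        if self.sequencing_error_vaf >= lo:
            raise ValueError(
                "sequencing_error_vaf must be below the somatic VAF range; "
                "the spec is contradictory otherwise")

    @property
    def n_tumours(self) -> int:
        return sum(g.n for g in self.groups)

    @property
    def n_normals(self) -> int:
        return self.n_tumours  # one paired normal per tumour

    @classmethod
    def single_group(cls, n: int, **kwargs) -> "SimulationSpec":
        """Convenience spec with one uniform tumour group (used by tests)."""
        group_kwargs = {}
        for key in ("mtcn_range", "somatic_rate"):
            if key in kwargs:
                group_kwargs[key] = kwargs.pop(key)
        return cls(groups=(GroupSpec("group", n, **group_kwargs),), **kwargs)


@dataclass
class GroundTruthVariant:
    sample_id: str
    position: int
    ref_allele: str
    alt_allele: str
    label: str  # true_somatic / germline / noise / artifact:<REASON>
    true_vaf: float
    pathogenic: bool = False


@dataclass
class GroundTruth:
    samples: dict   # sample_id -> {true_mtCN, f, ploidy, role, group, patient}
    variants: list  # of GroundTruthVariant

    def by_label(self, prefix: str) -> list:
        return [v for v in self.variants if v.label.startswith(prefix)]


@dataclass
class SimulatedCohort:
    spec: SimulationSpec
    reference: str
    calls: dict          # caller -> sample_id -> [MtVariantCall]
    depth_rows: list
    purity_rows: list
    sample_sheet: list   # dicts: sample_id, patient_id, role, group, paired_normal
    germline_resource: list
    pathogenic: set      # (position, alt)
    ground_truth: GroundTruth


# ---------------------------------------------------------------------------
# helpers
# ---------------------------------------------------------------------------

def _nb(rng, mu: float, r: float, size=None):
    """Negative binomial with mean mu and shape r (variance mu + mu^2/r)."""
    return rng.negative_binomial(r, r / (r + mu), size=size)


def _alt_base(rng, ref: str) -> str:
    choices = [b for b in "ACGT" if b != ref]
    return choices[rng.integers(0, len(choices))]


def _blacklist_positions(regions) -> tuple:
    """(all-variant positions, every blacklisted position)."""
    all_var, every = [], []
    for r in regions:
        span = range(r.start, r.end + 1)
        every.extend(span)
        if r.applies_to == io_formats.BLACKLIST_ALL:
            all_var.extend(span)
    return np.array(all_var), set(every)


def _passing_evidence(rng, total_depth: int, true_vaf: float) -> dict:
    """Per-read summaries drawn from truncated normals at non-violating centres."""
    vr = int(rng.binomial(total_depth, true_vaf))
    vr = max(vr, 1)
    ref_len = float(np.clip(rng.normal(150.0, 3.0), 130.0, 170.0))
    ref_mapq = float(np.clip(rng.normal(60.0, 1.0), 55.0, 62.0))
    ref_nm = float(np.clip(rng.normal(1.0, 0.3), 0.2, 2.0))
    return dict(
        total_depth=int(total_depth),
        variant_reads=vr,
        forward_variant_reads=int(np.clip(rng.binomial(vr, 0.5), 0, vr)),
        variant_base_quality=float(np.clip(rng.normal(32.0, 3.0), 25.0, 42.0)),
        mean_read_position=float(np.clip(rng.normal(0.5, 0.07), 0.25, 0.75)),
        ref_read_length=ref_len,
        var_read_length=ref_len - float(np.clip(rng.normal(0.0, 3.0), -10.0, 10.0)),
        ref_mapq=ref_mapq,
        var_mapq=ref_mapq - float(np.clip(rng.normal(0.0, 2.0), -5.0, 5.0)),
        normal_context_fraction=float(rng.uniform(0.9, 1.0)),
        ref_nm=ref_nm,
        var_nm=ref_nm + float(np.clip(rng.normal(0.5, 0.5), -0.5, 2.0)),
    )


def _apply_artifact(rng, fields: dict, reason: Reason) -> dict:
    """Overwrite exactly the summaries that make ``reason`` fire."""
    fields = dict(fields)
    vr = fields["variant_reads"]
    if reason == Reason.STRAND:
        forward = int(np.ceil(0.95 * vr)) if rng.random() < 0.5 else int(0.05 * vr)
        fields["forward_variant_reads"] = int(np.clip(forward, 0, vr))
    elif reason == Reason.READ_POSITION:
        fields["mean_read_position"] = float(rng.choice([0.05, 0.92]))
    elif reason == Reason.SUPPORT:
        new_vr = int(rng.integers(1, 10))
        fields["variant_reads"] = new_vr
        fields["forward_variant_reads"] = new_vr // 2
    elif reason == Reason.BASE_QUALITY:
        fields["variant_base_quality"] = float(rng.uniform(5.0, 15.0))
    elif reason == Reason.LENGTH_DIFF:
        fields["var_read_length"] = fields["ref_read_length"] - float(rng.uniform(30.0, 60.0))
    elif reason == Reason.MAPQ_DIFF:
        fields["var_mapq"] = fields["ref_mapq"] - float(rng.uniform(15.0, 30.0))
    elif reason == Reason.NORMAL_CONTEXT:
        fields["normal_context_fraction"] = float(rng.uniform(0.3, 0.6))
    elif reason == Reason.NM_DIFF:
        fields["var_nm"] = fields["ref_nm"] + float(rng.uniform(4.0, 8.0))
    # BLACKLIST is positional: handled by placing the variant in a region
    return fields


def _pick_positions(rng, n: int, excluded: set, lo: int = 100, hi: int = MT_LENGTH - 100) -> list:
    out = []
    guard = 0
    while len(out) < n:
        pos = int(rng.integers(lo, hi + 1))
        if pos not in excluded:
            out.append(pos)
            excluded.add(pos)
        guard += 1
        if guard > 100 * max(n, 1) + 1000:
            raise RuntimeError("could not place variants: position space exhausted")
    return out


# ---------------------------------------------------------------------------
# cohort simulation
# ---------------------------------------------------------------------------

def simulate_cohort(spec: SimulationSpec) -> SimulatedCohort:
    """Generate a full paired cohort; deterministic given ``spec`` (incl. seed)."""
    seed = int(spec.seed) % (2**31)
    rng_ref = np.random.default_rng([seed, 0])
    reference = "".join(rng_ref.choice(BASES, size=MT_LENGTH))

    blacklist = load_default_blacklist()
    bl_all_positions, bl_every = _blacklist_positions(blacklist)

    rng_global = np.random.default_rng([seed, 1])
    reserved = set(bl_every)
    # population polymorphisms shared across patients
    poly_positions = _pick_positions(rng_global, spec.n_population_polymorphisms, reserved)
    polys = []
    for pos in poly_positions:
        ref = reference[pos - 1]
        polys.append((pos, ref, _alt_base(rng_global, ref),
                      float(rng_global.uniform(0.02, 0.5))))
    # panel-wide noisy positions
    noise_positions = _pick_positions(rng_global, spec.n_noise_positions, reserved)

    patients = []
    idx = 0
    for group in spec.groups:
        for _ in range(group.n):
            idx += 1
            patients.append((idx, group))

    calls = {CALLER_A: {}, CALLER_B: {}}
    depth_rows, purity_rows, sheet, truth_variants = [], [], [], []
    samples_truth = {}
    pathogenic = set()
    normal_calls_by_sample = {}

    def emit(rng, sample_id: str, position: int, ref: str, alt: str,
             fields: dict, label: str, true_vaf: float,
             is_pathogenic: bool = False, adjacent: bool = False) -> None:
        call_kwargs = dict(fields)
        u = rng.random()
        both = u < spec.caller_concordance
        caller_a_only = not both and u < spec.caller_concordance + (1 - spec.caller_concordance) / 2
        targets = [CALLER_A, CALLER_B] if both else ([CALLER_A] if caller_a_only else [CALLER_B])
        for caller in targets:
            kw = dict(call_kwargs)
            if caller == CALLER_B:  # slight annotation disagreement between callers
                kw["variant_base_quality"] = float(
                    max(kw["variant_base_quality"] + rng.normal(0.0, 0.3), 1.0))
            calls[caller].setdefault(sample_id, []).append(
                MtVariantCall(sample_id=sample_id, position=position,
                              ref_allele=ref, alt_allele=alt,
                              adjacent_to_germline=adjacent,
                              callers=frozenset({caller}), **kw))
        truth_variants.append(GroundTruthVariant(
            sample_id=sample_id, position=position, ref_allele=ref,
            alt_allele=alt, label=label, true_vaf=true_vaf,
            pathogenic=is_pathogenic))

    # ---- pass 1: patient germline + normal samples (defines the noise panel)
    patient_germline = {}
    normal_mu_chrm = {}
    for i, group in patients:
        rng_n = np.random.default_rng([seed, 2, i])
        patient = f"P{i:02d}"
        normal_id = f"{patient}-N"
        used = set(reserved)
        germline = []
        for pos in _pick_positions(rng_n, spec.n_germline_haplogroup, used):
            ref = reference[pos - 1]
            germline.append((pos, ref, _alt_base(rng_n, ref)))
        for pos, ref, alt, freq in polys:
            if rng_n.random() < freq:
                germline.append((pos, ref, alt))
        patient_germline[i] = germline

        true_mtcn = float(rng_n.uniform(*spec.normal_mtcn_range))
        mu_chrm = spec.mean_depth_auto * true_mtcn / correction_factor(1.0, 2.0)
        normal_mu_chrm[normal_id] = mu_chrm
        depth_rows.append(DepthTableRow(
            normal_id,
            float(np.mean(_nb(rng_n, spec.mean_depth_auto, spec.depth_overdispersion,
                              spec.n_auto_sites))),
            float(np.mean(_nb(rng_n, mu_chrm, spec.depth_overdispersion,
                              spec.n_chrm_sites))),
        ))
        purity_rows.append(PurityPloidy(normal_id, 1.0, 2.0))
        samples_truth[normal_id] = dict(true_mtCN=true_mtcn, f=1.0, ploidy=2.0,
                                        role="normal", group="paired-normal",
                                        patient=patient)
        sheet.append(dict(sample_id=normal_id, patient_id=patient, role="normal",
                          group="paired-normal", paired_normal=""))

        for pos, ref, alt in germline:
            depth = max(int(_nb(rng_n, mu_chrm, spec.depth_overdispersion)), 20)
            fields = _passing_evidence(rng_n, depth, 0.985)
            emit(rng_n, normal_id, pos, ref, alt, fields, LABEL_GERMLINE, 0.985)
        for pos in noise_positions:
            if rng_n.random() >= 0.8:
                continue
            depth = max(int(_nb(rng_n, mu_chrm, spec.depth_overdispersion)), 20)
            vaf = float(rng_n.uniform(0.25 * spec.sequencing_error_vaf,
                                      2.0 * spec.sequencing_error_vaf))
            vr = max(int(round(vaf * depth)), 1)
            ref = reference[pos - 1]
            fields = _passing_evidence(rng_n, depth, vr / depth)
            fields["variant_reads"] = vr
            fields["forward_variant_reads"] = min(vr // 2, vr)
            emit(rng_n, normal_id, pos, ref, _alt_base(rng_n, ref), fields,
                 LABEL_NOISE, vaf)
        normal_calls_by_sample[normal_id] = union_calls(
            calls[CALLER_A].get(normal_id, []), calls[CALLER_B].get(normal_id, []))

    # the noise levels the tumour noise calls must stay below
    noise_model = estimate_noise(normal_calls_by_sample, floor=spec.noise_floor)

    # keep injected somatics/artifacts clear of every germline allele in the
    # cohort resource: a coinciding position would be removed as germline (or
    # waive the normal-context criterion) by construction, not by chance
    germline_zone = set()
    for germline in patient_germline.values():
        for pos, _ref, _alt in germline:
            germline_zone.update(range(pos - 3, pos + 4))
    for pos, _ref, _alt, _freq in polys:
        germline_zone.update(range(pos - 3, pos + 4))

    # ---- pass 2: tumours
    for i, group in patients:
        rng_t = np.random.default_rng([seed, 3, i])
        patient = f"P{i:02d}"
        tumour_id = f"{patient}-T"
        normal_id = f"{patient}-N"
        germline = patient_germline[i]
        germline_positions = {pos for pos, _r, _a in germline}
        used = set(reserved) | germline_positions

        true_mtcn = float(rng_t.uniform(*group.mtcn_range))
        f = float(rng_t.uniform(*spec.purity_range))
        ploidy = float(rng_t.choice(np.array(spec.ploidy_choices)))
        corr = correction_factor(f, ploidy)
        mu_chrm = spec.mean_depth_auto * true_mtcn / corr
        depth_rows.append(DepthTableRow(
            tumour_id,
            float(np.mean(_nb(rng_t, spec.mean_depth_auto, spec.depth_overdispersion,
                              spec.n_auto_sites))),
            float(np.mean(_nb(rng_t, mu_chrm, spec.depth_overdispersion,
                              spec.n_chrm_sites))),
        ))
        purity_rows.append(PurityPloidy(tumour_id, f, ploidy))
        samples_truth[tumour_id] = dict(true_mtCN=true_mtcn, f=f, ploidy=ploidy,
                                        role="tumour", group=group.name,
                                        patient=patient)
        sheet.append(dict(sample_id=tumour_id, patient_id=patient, role="tumour",
                          group=group.name, paired_normal=normal_id))

        # germline haplogroup, shared with the paired normal
        for pos, ref, alt in germline:
            depth = max(int(_nb(rng_t, mu_chrm, spec.depth_overdispersion)), 20)
            fields = _passing_evidence(rng_t, depth, 0.985)
            emit(rng_t, tumour_id, pos, ref, alt, fields, LABEL_GERMLINE, 0.985)

        # true somatic heteroplasmies
        if spec.n_true_somatic_per_tumour is not None:
            n_somatic = spec.n_true_somatic_per_tumour
        else:
            n_somatic = int(rng_t.poisson(group.somatic_rate))
        somatic_excluded = used | germline_zone
        for pos in _pick_positions(rng_t, n_somatic, somatic_excluded):
            used.add(pos)
            ref = reference[pos - 1]
            if rng_t.random() < spec.somatic_indel_fraction:
                alt = ref + _alt_base(rng_t, "N")  # 1-bp insertion
            else:
                alt = _alt_base(rng_t, ref)
            vaf = float(rng_t.uniform(*spec.somatic_vaf_range))
            depth = max(int(_nb(rng_t, mu_chrm, spec.depth_overdispersion)), 20)
            fields = _passing_evidence(rng_t, depth, vaf)
            is_path = bool(rng_t.random() < spec.pathogenic_fraction)
            if is_path:
                pathogenic.add((pos, alt))
            emit(rng_t, tumour_id, pos, ref, alt, fields, LABEL_TRUE_SOMATIC,
                 vaf, is_pathogenic=is_path)

        # artifacts, one designed criterion violation each
        bl_used: set = set()  # blacklist positions sit inside `reserved`
        for reason in ARTIFACT_REASONS:
            rate = spec.artifact_rates.get(reason, 0.0)
            n_art = int(rng_t.poisson(rate)) if rate > 0 else 0
            for _ in range(n_art):
                if reason == Reason.BLACKLIST:
                    candidates = [int(p) for p in bl_all_positions if p not in bl_used]
                    if not candidates:
                        continue
                    pos = candidates[rng_t.integers(0, len(candidates))]
                    bl_used.add(pos)
                else:
                    pos = _pick_positions(rng_t, 1, used | germline_zone)[0]
                    used.add(pos)
                ref = reference[pos - 1]
                alt = _alt_base(rng_t, ref)
                vaf = float(rng_t.uniform(0.15, 0.45))
                depth = max(int(_nb(rng_t, mu_chrm, spec.depth_overdispersion)), 20)
                fields = _apply_artifact(rng_t, _passing_evidence(rng_t, depth, vaf),
                                         reason)
                emit(rng_t, tumour_id, pos, ref, alt, fields,
                     f"{ARTIFACT_PREFIX}{reason.value}",
                     fields["variant_reads"] / fields["total_depth"])

        # sub-noise tumour calls at the panel's noisy positions
        for pos in noise_positions:
            if rng_t.random() >= 0.5 or pos in used:
                continue
            used.add(pos)
            level = noise_model.level(pos)
            vaf = 0.4 * level
            depth = max(int(_nb(rng_t, mu_chrm, spec.depth_overdispersion)), 20)
            vr = max(int(round(vaf * depth)), 1)
            if vr / depth >= level:  # shallow sample: cannot sit below the level
                continue
            ref = reference[pos - 1]
            fields = _passing_evidence(rng_t, depth, vr / depth)
            fields["variant_reads"] = vr
            fields["forward_variant_reads"] = min(vr // 2, vr)
            emit(rng_t, tumour_id, pos, ref, _alt_base(rng_t, ref), fields,
                 LABEL_NOISE, vaf)

    for caller in calls:
        for sample in calls[caller]:
            calls[caller][sample].sort(key=lambda c: c.key)

    resource = [GermlineResourceEntry(pos, alt, SOURCE_POPDB, freq)
                for pos, _ref, alt, freq in polys]
    cohort_seen = {}
    for sample_id, sample_calls in normal_calls_by_sample.items():
        for call in sample_calls:
            if call.vaf is not None and call.vaf > 0.95:
                key = (call.position, call.alt_allele)
                cohort_seen[key] = max(cohort_seen.get(key, 0.0), call.vaf)
    resource.extend(GermlineResourceEntry(pos, alt, SOURCE_COHORT, min(vaf, 1.0))
                    for (pos, alt), vaf in sorted(cohort_seen.items()))

    return SimulatedCohort(
        spec=spec,
        reference=reference,
        calls=calls,
        depth_rows=depth_rows,
        purity_rows=purity_rows,
        sample_sheet=sheet,
        germline_resource=resource,
        pathogenic=pathogenic,
        ground_truth=GroundTruth(samples=samples_truth, variants=truth_variants),
    )


# ---------------------------------------------------------------------------
# fixture bundle
# ---------------------------------------------------------------------------

def _spec_to_jsonable(spec: SimulationSpec) -> dict:
    out = dataclasses.asdict(spec)
    out["groups"] = [dataclasses.asdict(g) for g in spec.groups]
    out["artifact_rates"] = {str(k): v for k, v in spec.artifact_rates.items()}
    return out


def write_fixture_bundle(cohort: SimulatedCohort, directory) -> dict:
    """Write the cohort in the exact on-disk formats the pipeline consumes.

    Returns the manifest (also written as ``manifest.json``).
    """
    directory = Path(directory)
    (directory / "vcf").mkdir(parents=True, exist_ok=True)

    ref_path = directory / "synthetic_chrM.fa"
    with open(ref_path, "w") as fh:
        fh.write(">chrM synthetic mitochondrial reference (rCRS coordinates, random bases)\n")
        for i in range(0, MT_LENGTH, 70):
            fh.write(cohort.reference[i:i + 70] + "\n")

    io_formats.write_depth_table(cohort.depth_rows, directory / "depth.tsv")
    io_formats.write_purity_table(cohort.purity_rows, directory / "purity.tsv")
    io_formats.write_sample_sheet(cohort.sample_sheet, directory / "sample_sheet.tsv")
    io_formats.write_germline_resource(cohort.germline_resource,
                                       directory / "germline_resource.tsv")
    from .annotation import write_pathogenic_list
    write_pathogenic_list(cohort.pathogenic, directory / "pathogenic.tsv")
    with resources.as_file(resources.files("mtsomatic.data") / "blacklist.tsv") as p:
        shutil.copy(p, directory / "blacklist.tsv")

    vcf_files = []
    sample_ids = sorted({row["sample_id"] for row in cohort.sample_sheet})
    for sample_id in sample_ids:
        for caller in (CALLER_A, CALLER_B):
            path = directory / "vcf" / f"{sample_id}.{caller}.vcf"
            io_formats.write_variant_vcf(cohort.calls[caller].get(sample_id, []),
                                         path, sample_id=sample_id)
            vcf_files.append(str(path.relative_to(directory)))

    truth = {
        "samples": cohort.ground_truth.samples,
        "variants": [dataclasses.asdict(v) for v in cohort.ground_truth.variants],
    }
    with open(directory / "ground_truth.json", "w") as fh:
        json.dump(truth, fh, indent=1, sort_keys=True)

    manifest = {
        "seed": cohort.spec.seed,
        "spec": _spec_to_jsonable(cohort.spec),
        "files": sorted(vcf_files + [
            "synthetic_chrM.fa", "depth.tsv", "purity.tsv", "sample_sheet.tsv",
            "germline_resource.tsv", "pathogenic.tsv", "blacklist.tsv",
            "ground_truth.json",
        ]),
    }
    with open(directory / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=1, sort_keys=True)
    return manifest


def load_ground_truth(path) -> GroundTruth:
    with open(path) as fh:
        raw = json.load(fh)
    return GroundTruth(
        samples=raw["samples"],
        variants=[GroundTruthVariant(**v) for v in raw["variants"]],
    )
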