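"""End-to-end orchestration of the mtDNA analysis.

Stage order is fixed: copy number -> caller union -> blacklist/read-evidence
filters -> germline removal -> noise estimation from the normal panel ->
noise filter -> somatic/dysplastic classification -> consequence annotation
-> per-sample summaries and Welch group comparisons. Every stage logs and
reports its in/out record counts, and per sample the pass count plus the
rejected count always reconciles with the union size.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd

from . import annotation, copy_number, group_stats, io_formats, variant_filter
from .io_formats import CALLER_A, CALLER_B
from .variant_filter import (
    ClassifyConfig,
    FilterConfig,
    GermlineIndex,
    MtVariantCall,
    union_calls,
)

logger = logging.getLogger(__name__)

STAGES = ("copy_number", "filter", "classify", "annotate", "summarize")


class PipelineError(RuntimeError):
    """A stage-validation failure; carries the stage name for the exit message."""

    def __init__(self, stage: str, message: str) -> None:
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Resolved inputs and thresholds of one run; echoed verbatim in the report."""

    depth_path: str
    sample_sheet_path: str
    vcf_dir: str
    out_dir: str
    purity_path: Optional[str] = None
    germline_resource_path: Optional[str] = None
    blacklist_path: Optional[str] = None      # None -> packaged default
    pathogenic_path: Optional[str] = None
    reference_path: Optional[str] = None
    sidecar_path: Optional[str] = None
    filter_config: FilterConfig = field(default_factory=FilterConfig)
    classify_config: ClassifyConfig = field(default_factory=ClassifyConfig)
    rna_is_nonsilent: bool = True

    @classmethod
    def from_bundle(cls, input_dir, out_dir, **overrides) -> "RunConfig":
        """Conventional layout written by the synthetic fixture bundle."""
        input_dir = Path(input_dir)

        def maybe(name: str) -> Optional[str]:
            path = input_dir / name
            return str(path) if path.exists() else None

        return cls(
            depth_path=str(input_dir / "depth.tsv"),
            sample_sheet_path=str(input_dir / "sample_sheet.tsv"),
            vcf_dir=str(input_dir / "vcf"),
            out_dir=str(out_dir),
            purity_path=maybe("purity.tsv"),
            germline_resource_path=maybe("germline_resource.tsv"),
            blacklist_path=maybe("blacklist.tsv"),
            pathogenic_path=maybe("pathogenic.tsv"),
            reference_path=maybe("synthetic_chrM.fa"),
            sidecar_path=maybe("sidecar.tsv"),
            **overrides,
        )

    def to_jsonable(self) -> dict:
        out = dataclasses.asdict(self)
        for key in ("filter_config", "classify_config"):
            out[key] = {k: (list(v) if isinstance(v, tuple) else v)
                        for k, v in out[key].items()}
        return out


def _read_reference(path) -> str:
    from Bio import SeqIO

    record = next(SeqIO.parse(str(path), "fasta"))
    return str(record.seq).upper()


def _load_sample_calls(config: RunConfig, sample_id: str) -> list:
    """Union of both callers' calls for one sample (with sidecar fill-in)."""
    vcf_dir = Path(config.vcf_dir)
    sidecar = (io_formats.read_sidecar_annotations(config.sidecar_path)
               if config.sidecar_path else {})
    per_caller = []
    for caller in (CALLER_A, CALLER_B):
        path = vcf_dir / f"{sample_id}.{caller}.vcf"
        if not path.exists():
            per_caller.append([])
            continue
        raw = io_formats.read_variant_vcf(path, caller)
        if sidecar:
            io_formats.apply_sidecar(raw, sidecar, sample_id)
        per_caller.append([MtVariantCall.from_raw(r, sample_id) for r in raw])
    return union_calls(per_caller[0], per_caller[1])


def run_pipeline(config: RunConfig, until: str = "summarize") -> dict:
    """Run the pipeline and return the (JSON-serializable) run report.

    ``until`` truncates execution after the named stage, for the staged CLI
    subcommands; outputs of completed stages are always written.
    """
    if until not in STAGES:
        raise ValueError(f"unknown stage {until!r}; expected one of {STAGES}")
    until_index = STAGES.index(until)
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    report: dict = {"config": config.to_jsonable(), "stages": {}, "samples": {}}

    # ---- inputs -----------------------------------------------------------
    try:
        sheet = io_formats.read_sample_sheet(config.sample_sheet_path)
    except (OSError, ValueError) as exc:
        raise PipelineError("inputs", f"sample sheet: {exc}") from exc
    tumours = [row for row in sheet if row["role"] == "tumour"]
    normals = [row for row in sheet if row["role"] == "normal"]
    group_of = {row["sample_id"]: row["group"] for row in sheet}
    paired_normal = {row["sample_id"]: row.get("paired_normal") or None
                     for row in tumours}
    report["stages"]["inputs"] = {"n_tumours": len(tumours), "n_normals": len(normals)}

    # ---- stage: copy number ----------------------------------------------
    try:
        depths = io_formats.read_depth_table(config.depth_path)
        purities = (io_formats.read_purity_table(config.purity_path)
                    if config.purity_path else [])
    except (OSError, ValueError) as exc:
        raise PipelineError("copy_number", str(exc)) from exc
    if not config.purity_path:
        logger.warning("no purity table given; assuming f=1, ploidy=2 for all samples")
    known = {pp.sample_id for pp in purities}
    defaulted = [d.sample_id for d in depths if d.sample_id not in known]
    if defaulted:
        logger.warning("purity/ploidy defaulted to f=1, ploidy=2 for: %s", defaulted)
    cn_results = copy_number.estimate_cohort(depths, purities)
    cn_by_sample = {r.sample_id: r for r in cn_results}
    copy_number.write_copy_number_table(cn_results, out_dir / "mtcn.tsv")
    try:
        cn_groups = copy_number.summarize_copy_number_by_group(cn_results, group_of)
    except KeyError as exc:
        raise PipelineError("copy_number", str(exc)) from exc
    cn_groups.to_csv(out_dir / "mtcn_groups.tsv", sep="\t")
    report["stages"]["copy_number"] = {
        "n_samples": len(cn_results),
        "defaulted_purity": sorted(defaulted),
    }
    logger.info("copy_number: %d samples in, %d estimates out", len(depths), len(cn_results))
    if until_index < 1:
        _write_report(report, out_dir)
        return report

    # ---- stage: filter (union + blacklist + evidence + germline + noise) --
    blacklist = (io_formats.read_blacklist(config.blacklist_path)
                 if config.blacklist_path else io_formats.load_default_blacklist())
    resource = (io_formats.read_germline_resource(config.germline_resource_path)
                if config.germline_resource_path else [])
    fcfg = config.filter_config

    try:
        normal_calls = {row["sample_id"]: _load_sample_calls(config, row["sample_id"])
                        for row in normals}
    except ValueError as exc:
        raise PipelineError("filter", str(exc)) from exc
    if normal_calls:
        normal_depths = {d.sample_id: d.mean_dp_chrm for d in depths
                         if d.sample_id in normal_calls}
        noise_model = variant_filter.estimate_noise(normal_calls, normal_depths,
                                                    floor=fcfg.noise_floor)
    else:
        logger.warning("no normal samples: noise filter uses the floor only")
        noise_model = variant_filter.NoiseModel({}, floor=fcfg.noise_floor)
    report["stages"]["noise"] = {
        "n_normals": len(normal_calls),
        "n_positions_with_signal": len(noise_model.per_position),
        "floor": noise_model.floor,
    }

    verdicts_by_sample: dict = {}
    audit_rows = []
    (out_dir / "vcf").mkdir(exist_ok=True)
    for row in tumours:
        sample_id = row["sample_id"]
        try:
            union = _load_sample_calls(config, sample_id)
        except ValueError as exc:
            raise PipelineError("filter", f"{sample_id}: {exc}") from exc
        pair = paired_normal.get(sample_id)
        index = GermlineIndex(resource, normal_calls.get(pair, []), fcfg)
        verdicts = [variant_filter.filter_variant(c, fcfg, blacklist, index, noise_model)
                    for c in union]
        verdicts_by_sample[sample_id] = (verdicts, index)
        n_pass = sum(v.passed for v in verdicts)
        reason_counts: dict = {}
        for v in verdicts:
            for reason in v.failed_reasons:
                reason_counts[str(reason)] = reason_counts.get(str(reason), 0) + 1
                audit_rows.append((sample_id, v.call.position, v.call.ref_allele,
                                   v.call.alt_allele, str(reason)))
        report["samples"][sample_id] = {
            "union": len(union),
            "pass": n_pass,
            "fail": len(union) - n_pass,
            "reasons": dict(sorted(reason_counts.items())),
        }
        logger.info("filter %s: %d in union, %d pass, %d fail",
                    sample_id, len(union), n_pass, len(union) - n_pass)
        io_formats.write_variant_vcf(
            [v.call for v in verdicts], out_dir / "vcf" / f"{sample_id}.filtered.vcf",
            sample_id=sample_id,
            reasons_by_key={v.call.key: v.failed_reasons for v in verdicts})
    with open(out_dir / "audit_reasons.tsv", "w") as fh:
        fh.write("sample_id\tposition\tref\talt\treason\n")
        for entry in audit_rows:
            fh.write("\t".join(str(x) for x in entry) + "\n")
    report["stages"]["filter"] = {
        "n_union_total": sum(r["union"] for r in report["samples"].values()),
        "n_pass_total": sum(r["pass"] for r in report["samples"].values()),
    }
    if until_index < 2:
        _write_report(report, out_dir)
        return report

    # ---- stage: classify ---------------------------------------------------
    classified_by_sample: dict = {}
    for sample_id, (verdicts, index) in verdicts_by_sample.items():
        classified = []
        dropped = 0
        for verdict in verdicts:
            if not verdict.passed:
                continue
            call = verdict.call
            normal_vaf = index.normal_vaf(call.position, call.alt_allele)
            result = variant_filter.classify_somatic_status(
                call, normal_vaf, config.classify_config, verdict)
            if result is None:
                dropped += 1
            else:
                classified.append(result)
        classified_by_sample[sample_id] = classified
        report["samples"][sample_id]["classified"] = len(classified)
        report["samples"][sample_id]["dropped_unclassifiable"] = dropped
    with open(out_dir / "classified.tsv", "w") as fh:
        fh.write("sample_id\tposition\tref\talt\tlabel\ttumour_vaf\tnormal_vaf\tcallers\n")
        for sample_id in sorted(classified_by_sample):
            for v in classified_by_sample[sample_id]:
                fh.write(f"{sample_id}\t{v.call.position}\t{v.call.ref_allele}\t"
                         f"{v.call.alt_allele}\t{v.label}\t{v.tumour_vaf:.6g}\t"
                         f"{v.normal_vaf:.6g}\t{','.join(sorted(v.call.callers))}\n")
    report["stages"]["classify"] = {
        "n_classified_total": sum(len(v) for v in classified_by_sample.values()),
    }
    if until_index < 3:
        _write_report(report, out_dir)
        return report

    # ---- stage: annotate ---------------------------------------------------
    model = annotation.load_default_gene_model()
    pathogenic = (annotation.read_pathogenic_list(config.pathogenic_path)
                  if config.pathogenic_path else set())
    reference = _read_reference(config.reference_path) if config.reference_path else None
    if reference is None:
        logger.warning("no reference sequence: protein-gene SNVs reported as "
                       "potentially protein-altering without codon resolution")
    consequences_by_sample: dict = {}
    with open(out_dir / "consequences.tsv", "w") as fh:
        fh.write("sample_id\tposition\tref\talt\tgene\tcategory\tis_nonsilent\tpathogenic\n")
        for sample_id in sorted(classified_by_sample):
            csqs = {}
            for v in classified_by_sample[sample_id]:
                csq = annotation.annotate_consequence(
                    v.call, model, pathogenic, reference,
                    rna_is_nonsilent=config.rna_is_nonsilent)
                csqs[v.call.key] = csq
                fh.write(f"{sample_id}\t{csq.position}\t{csq.ref_allele}\t"
                         f"{csq.alt_allele}\t{csq.gene or 'NA'}\t{csq.category}\t"
                         f"{csq.is_nonsilent}\t{csq.pathogenic_flag}\n")
            consequences_by_sample[sample_id] = csqs
    report["stages"]["annotate"] = {
        "n_annotated": sum(len(c) for c in consequences_by_sample.values()),
        "n_nonsilent": sum(csq.is_nonsilent for c in consequences_by_sample.values()
                           for csq in c.values()),
    }
    if until_index < 4:
        _write_report(report, out_dir)
        return report

    # ---- stage: summarize --------------------------------------------------
    summaries = []
    for row in tumours:
        sample_id = row["sample_id"]
        cn = cn_by_sample.get(sample_id)
        if cn is None:
            raise PipelineError("summarize", f"no copy-number estimate for {sample_id}")
        summaries.append(group_stats.summarize_sample(
            classified_by_sample.get(sample_id, []), cn, group_of[sample_id],
            consequences_by_sample.get(sample_id)))
    group_stats.write_summaries(summaries, out_dir / "summaries.tsv")
    comparisons = group_stats.compare_groups(summaries)
    # mtCN is also compared across ALL samples (tumour groups + paired normals)
    cn_quantity = group_stats.compare_groups(
        [group_stats.SampleSummary(r.sample_id, group_of[r.sample_id], 0, 0, 0, 0, 0,
                                   None, None, r.mtCN)
         for r in cn_results if r.sample_id in group_of],
        quantities=("mtCN",))
    cn_quantity = cn_quantity.assign(quantity="mtCN_all_samples")
    comparisons = pd.concat([comparisons, cn_quantity], ignore_index=True)
    comparisons.to_csv(out_dir / "comparisons.tsv", sep="\t", index=False)
    report["stages"]["summarize"] = {
        "n_summaries": len(summaries),
        "comparisons": json.loads(comparisons.to_json(orient="records")),
    }
    _write_report(report, out_dir)
    return report


def _write_report(report: dict, out_dir: Path) -> None:
    with open(out_dir / "report.json", "w") as fh:
        json.dump(report, fh, indent=1, sort_keys=True, default=str)
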