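"""Consequence annotation of mtDNA variants on the mitochondrial gene model.

The packaged gene model lists the 37 mitochondrial genes plus the control
region in rCRS coordinates (NC_012920.1, 1-based inclusive). Protein genes
are translated with the vertebrate mitochondrial genetic code (NCBI table 2:
AGA/AGG stop, ATA Met, TGA Trp); light-strand genes (ND6 and several tRNAs)
are reverse-complemented before codon lookup. Several gene pairs overlap
(ATP8/ATP6, ND4L/ND4): a variant inside an overlap is annotated against both
genes and the worst consequence is reported.

Codon-level calls need the reference sequence; pass the rCRS (or, for
simulated cohorts, the generator's synthetic reference) as a plain string.
Incomplete stop codons at protein-gene 3' ends are padded with A, mirroring
the polyadenylation that completes them in vivo.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from importlib import resources
from typing import Iterable, Optional, Sequence

from Bio.Data import CodonTable
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

MITO_TABLE = CodonTable.unambiguous_dna_by_id[2]

STRAND_HEAVY = "H"
STRAND_LIGHT = "L"

GENE_PROTEIN = "protein"
GENE_TRNA = "tRNA"
GENE_RRNA = "rRNA"
GENE_CONTROL = "control"

CAT_SYNONYMOUS = "synonymous"
CAT_MISSENSE = "missense"
CAT_NONSENSE = "nonsense"
CAT_FRAMESHIFT = "frameshift"
CAT_TRNA = "tRNA"
CAT_RRNA = "rRNA"
CAT_NONCODING = "noncoding"

#: ranking used to pick the worst consequence across overlapping genes
_SEVERITY = {
    CAT_FRAMESHIFT: 6,
    CAT_NONSENSE: 5,
    CAT_MISSENSE: 4,
    CAT_TRNA: 3,
    CAT_RRNA: 3,
    CAT_SYNONYMOUS: 2,
    CAT_NONCODING: 1,
}


@dataclass(frozen=True)
class MtGene:
    name: str
    start: int  # 1-based inclusive
    end: int
    strand: str
    type: str

    def __post_init__(self) -> None:
        if not (1 <= self.start <= self.end <= 16569):
            raise ValueError(f"gene {self.name}: interval out of range")

    @property
    def length(self) -> int:
        return self.end - self.start + 1

    @property
    def incomplete_stop_bases(self) -> int:
        """0, 1 or 2 trailing bases short of a full stop codon (protein genes)."""
        return (-self.length) % 3 if self.type == GENE_PROTEIN else 0

    def contains(self, position: int) -> bool:
        return self.start <= position <= self.end


class MtGeneModel:
    """The mitochondrial gene model as an ordered list of intervals."""

    def __init__(self, genes: Sequence[MtGene]) -> None:
        self.genes = sorted(genes, key=lambda g: (g.start, g.end))

    def genes_at(self, position: int) -> list:
        return [g for g in self.genes if g.contains(position)]


def load_default_gene_model() -> MtGeneModel:
    """Packaged rCRS-coordinate gene model."""
    genes = []
    with resources.as_file(resources.files("mtsomatic.data") / "gene_model.tsv") as path:
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith("#"):
                    continue
                name, start, end, strand, gtype = line.split("\t")
                genes.append(MtGene(name, int(start), int(end), strand, gtype))
    return MtGeneModel(genes)


@dataclass
class Consequence:
    position: int
    ref_allele: str
    alt_allele: str
    gene: Optional[str]
    category: str
    is_nonsilent: bool
    pathogenic_flag: bool = False


def _codon_change(gene: MtGene, position: int, ref: str, alt: str,
                  reference: str) -> str:
    """Consequence category of an SNV in a protein gene."""
    if reference[position - 1].upper() != ref:
        logger.warning("reference mismatch at %d: sequence %s, call ref %s",
                       position, reference[position - 1], ref)
    gene_seq = reference[gene.start - 1:gene.end].upper()
    if gene.strand == STRAND_LIGHT:
        coding = str(Seq(gene_seq).reverse_complement())
        offset = gene.end - position
        base = str(Seq(alt).reverse_complement())
    else:
        coding = gene_seq
        offset = position - gene.start
        base = alt
    coding = coding + "A" * gene.incomplete_stop_bases  # polyadenylation pad
    codon_start = (offset // 3) * 3
    codon = list(coding[codon_start:codon_start + 3])
    within = offset % 3
    ref_codon = "".join(codon)
    codon[within] = base
    alt_codon = "".join(codon)
    ref_stop = ref_codon in MITO_TABLE.stop_codons
    alt_stop = alt_codon in MITO_TABLE.stop_codons
    if ref_stop and alt_stop:
        return CAT_SYNONYMOUS
    if alt_stop:
        return CAT_NONSENSE
    if ref_stop:
        return CAT_MISSENSE  # stop-loss: protein-altering
    ref_aa = MITO_TABLE.forward_table[ref_codon]
    alt_aa = MITO_TABLE.forward_table[alt_codon]
    return CAT_SYNONYMOUS if ref_aa == alt_aa else CAT_MISSENSE


def _gene_category(gene: MtGene, position: int, ref: str, alt: str,
                   is_indel: bool, reference: Optional[str]) -> str:
    if gene.type == GENE_CONTROL:
        return CAT_NONCODING
    if gene.type == GENE_TRNA:
        return CAT_TRNA
    if gene.type == GENE_RRNA:
        return CAT_RRNA
    # protein gene
    if is_indel:
        if abs(len(ref) - len(alt)) % 3 != 0:
            return CAT_FRAMESHIFT
        return CAT_MISSENSE  # in-frame indel: protein-altering
    if reference is None:
        # without a sequence the codon cannot be resolved; report the
        # protein-altering possibility conservatively
        return CAT_MISSENSE
    if len(ref) == 1:
        return _codon_change(gene, position, ref, alt, reference)
    # multi-nucleotide substitution: translate each position, keep the worst
    categories = [
        _codon_change(gene, position + i, ref[i], alt[i], reference)
        for i in range(len(ref)) if gene.contains(position + i)
    ]
    return max(categories, key=_SEVERITY.__getitem__) if categories else CAT_NONCODING


def annotate_consequence(call, model: MtGeneModel,
                         pathogenic_list: Iterable[tuple] = (),
                         reference: Optional[str] = None,
                         rna_is_nonsilent: bool = True) -> Consequence:
    """Classify one variant as silent / non-silent / non-coding.

    ``call`` needs position / ref_allele / alt_allele / is_indel attributes.
    Variants spanning a gene boundary are annotated against the gene
    containing their start, with a warning. ``pathogenic_list`` is a set of
    (position, alt_allele) pairs from a curated pathogenic-allele table.
    """
    position, ref, alt = call.position, call.ref_allele, call.alt_allele
    genes = model.genes_at(position)
    end_position = position + max(len(ref) - 1, 0)
    if genes and any(not g.contains(end_position) for g in genes):
        logger.warning("variant at %d spans a gene boundary; annotated against "
                       "the gene containing its start", position)
    real_genes = [g for g in genes if g.type != GENE_CONTROL]
    if not real_genes:
        category, gene_name = CAT_NONCODING, (genes[0].name if genes else None)
    else:
        per_gene = [
            (g, _gene_category(g, position, ref, alt, call.is_indel, reference))
            for g in real_genes
        ]
        gene, category = max(per_gene, key=lambda gc: _SEVERITY[gc[1]])
        gene_name = gene.name
    if category in (CAT_TRNA, CAT_RRNA):
        nonsilent = rna_is_nonsilent
    else:
        nonsilent = category not in (CAT_SYNONYMOUS, CAT_NONCODING)
    return Consequence(
        position=position,
        ref_allele=ref,
        alt_allele=alt,
        gene=gene_name,
        category=category,
        is_nonsilent=nonsilent,
        pathogenic_flag=(position, alt) in set(pathogenic_list),
    )


def read_pathogenic_list(path) -> set:
    """Read a pathogenic-allele TSV (position, alt) into a set of keys."""
    out = set()
    with open(path) as fh:
        header = None
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if header is None:
                header = fields
                if header[:2] != ["position", "alt"]:
                    raise ValueError(f"{path}: expected columns position, alt")
                continue
            out.add((int(fields[0]), fields[1].upper()))
    return out


def write_pathogenic_list(entries: Iterable[tuple], path) -> None:
    with open(path, "w") as fh:
        fh.write("position\talt\n")
        for position, alt in sorted(entries):
            fh.write(f"{position}\t{alt}\n")
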