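"""Somatic variant ingestion, mutation burden, and gene mutation flags."""

from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import pysam

logger = logging.getLogger(__name__)

#: Consequence terms counted as non-synonymous (protein-altering). Terms are
#: matched as substrings so both bare terms ("missense") and Sequence
#: Ontology style ("missense_variant") qualify.
NONSYNONYMOUS_TERMS = (
    "missense",
    "nonsense",
    "stop_gained",
    "stop_lost",
    "start_lost",
    "frameshift",
    "inframe",
    "splice_acceptor",
    "splice_donor",
    "splice_site",
)


@dataclass(frozen=True)
class SomaticVariant:
    sample: str
    chromosome: str
    position: int  # 1-based, VCF convention
    ref: str
    alt: str
    consequence: str | None = None
    gene: str | None = None

    @property
    def variant_class(self) -> str:
        if len(self.ref) == 1 and len(self.alt) == 1:
            return "SNV"
        if len(self.alt) > len(self.ref):
            return "insertion"
        if len(self.alt) < len(self.ref):
            return "deletion"
        return "MNV"

    @property
    def is_snv(self) -> bool:
        return self.variant_class == "SNV"


@dataclass(frozen=True)
class SampleVariantSummary:
    sample: str
    n_variants: int
    n_snv: int
    tmb: float
    gene_flags: Mapping[str, bool]


def read_vcf(
    path: str,
    sample: str | None = None,
    gene_field: str = "GENE",
    consequence_field: str = "CONSEQ",
    keep_filtered: bool = False,
) -> list[SomaticVariant]:
    """Read somatic variants from a VCF 4.x file.

    Emits one variant per ALT allele (multi-allelic records are split).
    Records whose FILTER is neither PASS nor missing are dropped unless
    ``keep_filtered``. Gene symbol and consequence are taken from the
    configurable INFO keys when present.
    """
    variants: list[SomaticVariant] = []
    with pysam.VariantFile(path) as vcf:
        sid = sample if sample is not None else _infer_sample_id(vcf, path)
        for rec in vcf:
            filters = list(rec.filter.keys())
            if not keep_filtered and filters and filters != ["PASS"]:
                continue
            gene = _info_str(rec, gene_field)
            conseq = _info_str(rec, consequence_field)
            for alt in rec.alts or ():
                variants.append(
                    SomaticVariant(
                        sample=sid,
                        chromosome=rec.chrom,
                        position=rec.pos,
                        ref=rec.ref,
                        alt=alt,
                        consequence=conseq,
                        gene=gene,
                    )
                )
    return variants


def _infer_sample_id(vcf: pysam.VariantFile, path: str) -> str:
    if list(vcf.header.samples):
        return list(vcf.header.samples)[0]
    import os

    return os.path.basename(path).split(".")[0]


def _info_str(rec, key: str) -> str | None:
    if key not in rec.info:
        return None
    val = rec.info[key]
    if isinstance(val, tuple):
        val = val[0]
    return str(val) if val is not None else None


def compute_tmb(variants: Sequence[SomaticVariant] | int, size_mb: float) -> float:
    """Tumor mutation burden: variants per megabase of assessed genome.

    Counts all somatic variants (SNVs and indels alike) by default, matching
    whole-catalog totals. ``variants`` may be a collection or a plain count.
    """
    if size_mb <= 0:
        raise ValueError("effective size must be positive")
    n = variants if isinstance(variants, int) else len(variants)
    return n / size_mb


def nonsynonymous_flags(
    variants: Sequence[SomaticVariant],
    gene_panel: Iterable[str],
    terms: Sequence[str] = NONSYNONYMOUS_TERMS,
) -> dict[str, bool]:
    """Per-gene flag: does the sample carry >=1 non-synonymous variant?

    A variant lacking gene or consequence annotation never sets a flag
    (it is logged and counted as non-flagging).
    """
    flags = {g: False for g in gene_panel}
    n_unannotated = 0
    for v in variants:
        if v.gene is None or v.consequence is None:
            n_unannotated += 1
            continue
        if v.gene in flags and _is_nonsynonymous(v.consequence, terms):
            flags[v.gene] = True
    if n_unannotated:
        logger.info("%d variants lacked gene/consequence annotation", n_unannotated)
    return flags


def _is_nonsynonymous(consequence: str, terms: Sequence[str]) -> bool:
    c = consequence.lower()
    return any(t in c for t in terms)


def summarize_sample(
    variants: Sequence[SomaticVariant],
    size_mb: float,
    gene_panel: Iterable[str] = (),
) -> SampleVariantSummary:
    sample = variants[0].sample if variants else ""
    n_snv = sum(1 for v in variants if v.is_snv)
    return SampleVariantSummary(
        sample=sample,
        n_variants=len(variants),
        n_snv=n_snv,
        tmb=compute_tmb(len(variants), size_mb),
        gene_flags=nonsynonymous_flags(variants, gene_panel),
    )


def write_vcf(variants: Sequence[SomaticVariant], path: str,
              build_lengths: Mapping[str, int], sample: str) -> None:
    """Write a minimal somatic VCF (uncompressed, PASS-only records)."""
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        for chrom, length in build_lengths.items():
            fh.write(f"##contig=<ID={chrom},length={length}>\n")
        fh.write('##INFO=<ID=GENE,Number=1,Type=String,Description="Gene symbol">\n')
        fh.write('##INFO=<ID=CONSEQ,Number=1,Type=String,Description="Consequence">\n')
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t%s\n" % sample)
        for v in sorted(variants, key=lambda v: (v.chromosome, v.position)):
            info = []
            if v.gene:
                info.append(f"GENE={v.gene}")
            if v.consequence:
                info.append(f"CONSEQ={v.consequence}")
            fh.write(
                f"{v.chromosome}\t{v.position}\t.\t{v.ref}\t{v.alt}\t.\tPASS\t"
                f"{';'.join(info) or '.'}\tGT\t0/1\n"
            )
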