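"""Synthetic two-group tumor cohort generator.

Emulates the structure of a whole-genome study contrasting younger (<50 y)
and older (>=50 y) oral-cancer patients: allele-specific copy-number
segments with whole-arm and focal events at group-specific frequencies,
somatic SNV catalogs with trinucleotide-signature structure, per-sample
metadata (sex, smoking), and right-censored survival — all on a scaled
"toy" genome so a full cohort simulates in seconds.

Defaults encode the study conditions: group sizes 26/11; arm/focal event
frequencies such as 8q gain 92%/55%, whole-chr20 gain 62%/9%, 7p11 focal
amplification 27%/0%, 11q13 focal amplification 23%/82%; TMB log-normal
with medians 3.20/8.45 variants/Mb; clock-like (SBS1/5) versus APOBEC
(SBS2/13) dominated signature mixtures.

The generator is deterministic given its seed: the same config yields a
byte-identical fixture.
"""

from __future__ import annotations

import json
import logging
import math
import os
from dataclasses import dataclass, field, asdict
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .cnv import CopyNumberSegment, SamplePloidyProfile, write_segments
from .genome import ChromosomeArm, GeneLocus, GenomeBuild
from .signatures import (BASES, CHANNELS, COMPLEMENT, SignatureCatalog,
                         toy_catalog)
from .stats import SurvivalRecord
from .variants import SomaticVariant, write_vcf

logger = logging.getLogger(__name__)

# hg38 primary-assembly chromosome lengths (bp), used only as relative
# proportions when scaling the toy genome.
_HG38_LENGTHS = {
    "chr1": 248956422, "chr2": 242193529, "chr3": 198295559,
    "chr4": 190214555, "chr5": 181538259, "chr6": 170805979,
    "chr7": 159345973, "chr8": 145138636, "chr9": 138394717,
    "chr10": 133797422, "chr11": 135086622, "chr12": 133275309,
    "chr13": 114364328, "chr14": 107043718, "chr15": 101991189,
    "chr16": 90338345, "chr17": 83257441, "chr18": 80373285,
    "chr19": 58617616, "chr20": 64444167, "chr21": 46709983,
    "chr22": 50818468, "chrX": 156040895, "chrY": 57227415,
}

# Approximate centromere position as a fraction of chromosome length;
# defines the toy p/q split.
_CENTROMERE_FRACTION = {
    "chr1": 0.50, "chr2": 0.39, "chr3": 0.46, "chr4": 0.26, "chr5": 0.27,
    "chr6": 0.33, "chr7": 0.38, "chr8": 0.31, "chr9": 0.31, "chr10": 0.30,
    "chr11": 0.40, "chr12": 0.26, "chr13": 0.15, "chr14": 0.16,
    "chr15": 0.19, "chr16": 0.41, "chr17": 0.30, "chr18": 0.23,
    "chr19": 0.44, "chr20": 0.44, "chr21": 0.28, "chr22": 0.29,
    "chrX": 0.39, "chrY": 0.18,
}

# Gene placements as fractions of chromosome length, chosen to land on the
# cytogenetically correct arm of the toy genome.
_GENE_FRACTIONS = {
    "EGFR": ("chr7", 0.30),    # 7p11
    "CCND1": ("chr11", 0.60),  # 11q13
    "TP53": ("chr17", 0.08),   # 17p13
    "LRP1B": ("chr2", 0.60),   # 2q22
    "NOTCH1": ("chr9", 0.95),  # 9q34
    "CDKN2A": ("chr9", 0.15),  # 9p21
}
_GENE_LENGTH_FRACTION = 0.005

#: Features whose carriers receive a whole-arm copy-number event.
ARM_FEATURES = ("8q_gain", "chr20_gain", "3p_loss")
FOCAL_FEATURES = {"7p11_amp": "EGFR", "11q13_amp": "CCND1"}
MUTATION_PANEL = ("TP53", "LRP1B", "NOTCH1", "CDKN2A")


def _default_event_probs() -> dict[str, tuple[float, float]]:
    # (young, old) carrier probabilities
    return {
        "8q_gain": (0.92, 0.55),
        "chr20_gain": (0.62, 0.09),
        "3p_loss": (0.82, 0.62),
        "7p11_amp": (0.27, 0.0),
        "11q13_amp": (0.23, 0.82),
    }


def _default_mutation_probs() -> dict[str, tuple[float, float]]:
    return {
        "TP53": (0.85, 0.82),
        "LRP1B": (0.12, 0.45),
        "NOTCH1": (0.24, 0.27),
        "CDKN2A": (0.23, 0.36),
    }


def _default_mixtures() -> tuple[dict[str, float], dict[str, float]]:
    young = {"SBS1": 0.45, "SBS5": 0.35, "SBS2": 0.10, "SBS13": 0.10}
    old = {"SBS1": 0.10, "SBS5": 0.10, "SBS2": 0.45, "SBS13": 0.35}
    return young, old


@dataclass
class CohortSimConfig:
    """Knobs of the synthetic cohort; defaults are the study conditions."""

    seed: int = 0
    n_young: int = 26
    n_old: int = 11
    event_probs: dict[str, tuple[float, float]] = field(
        default_factory=_default_event_probs)
    mutation_probs: dict[str, tuple[float, float]] = field(
        default_factory=_default_mutation_probs)
    wgd_prob: tuple[float, float] = (0.3, 0.3)
    tmb_median: tuple[float, float] = (3.20, 8.45)
    tmb_sigma: float = 0.5
    signature_mixture: tuple[dict[str, float], dict[str, float]] = field(
        default_factory=_default_mixtures)
    focal_copy_number: float = 20.0
    male_prob: tuple[float, float] = (0.65, 0.64)
    # (ever, never, unknown) per group
    smoking_probs: tuple[tuple[float, float, float],
                         tuple[float, float, float]] = (
        (0.42, 0.39, 0.19), (0.91, 0.09, 0.0))
    pfs24: dict[str, float] = field(
        default_factory=lambda: {"male": 0.56, "female": 0.86})
    censor_range: tuple[float, float] = (6.0, 60.0)
    #: Length of the largest toy chromosome, in Mb; other chromosomes scale
    #: with their hg38 proportions.
    genome_scale_mb: float = 5.0
    cn_jitter: float = 0.0

    def __post_init__(self):
        for name, (py, po) in {**self.event_probs, **self.mutation_probs}.items():
            if not (0 <= py <= 1 and 0 <= po <= 1):
                raise ValueError(f"probability out of range for {name}")
        if self.n_young <= 0 or self.n_old <= 0:
            raise ValueError("group sizes must be positive")
        if min(self.tmb_median) <= 0:
            raise ValueError("TMB medians must be positive")
        for mix in self.signature_mixture:
            if abs(sum(mix.values()) - 1.0) > 1e-6:
                raise ValueError("signature mixtures must sum to 1")
        for f in self.event_probs:
            if f not in ARM_FEATURES and f not in FOCAL_FEATURES:
                raise ValueError(f"unknown event feature {f!r}")


def toy_genome(scale_mb: float = 5.0) -> tuple[GenomeBuild, list[ChromosomeArm],
                                               list[GeneLocus]]:
    """A 24-chromosome toy genome scaled down from hg38 proportions.

    Chromosome lengths are hg38 lengths rescaled so the largest chromosome
    is ``scale_mb`` megabases; arms split at the approximate centromere
    fraction; a six-gene panel is placed on the biologically correct arms.
    Acrocentric short arms are non-callable, as in the real genome.
    """
    factor = scale_mb * 1e6 / max(_HG38_LENGTHS.values())
    lengths = {c: max(int(l * factor), 10_000) for c, l in _HG38_LENGTHS.items()}
    build = GenomeBuild(name=f"toy-{scale_mb}Mb", lengths=lengths)
    arms = []
    acro = {"13p", "14p", "15p", "21p", "22p"}
    for chrom, length in lengths.items():
        split = int(length * _CENTROMERE_FRACTION[chrom])
        short = chrom.removeprefix("chr")
        arms.append(ChromosomeArm(chrom, "p", 0, split,
                                  callable=f"{short}p" not in acro))
        arms.append(ChromosomeArm(chrom, "q", split, length))
    genes = []
    for symbol, (chrom, frac) in _GENE_FRACTIONS.items():
        length = lengths[chrom]
        start = int(length * frac)
        end = start + max(int(length * _GENE_LENGTH_FRACTION), 200)
        genes.append(GeneLocus(symbol, chrom, start, end))
    return build, arms, genes


@dataclass
class SyntheticSample:
    sample: str
    group: str  # "<50" or ">=50"
    sex: str
    smoking: str
    profile: SamplePloidyProfile
    events: dict[str, bool]
    mutated_genes: dict[str, bool]
    tmb_true: float
    segments: list[CopyNumberSegment]
    variants: list[SomaticVariant]
    survival: SurvivalRecord


@dataclass
class SyntheticCohort:
    config: CohortSimConfig
    build: GenomeBuild
    arms: list[ChromosomeArm]
    genes: list[GeneLocus]
    catalog: SignatureCatalog
    sequences: dict[str, np.ndarray]  # base codes 0..3 per chromosome
    samples: list[SyntheticSample]

    @property
    def truth(self) -> pd.DataFrame:
        rows = []
        for s in self.samples:
            row = {
                "sample": s.sample, "age_group": s.group, "sex": s.sex,
                "smoking": s.smoking, "wgd": s.profile.wgd,
                "ploidy": s.profile.ploidy, "tmb_true": s.tmb_true,
                "time_months": s.survival.time, "event": s.survival.event,
            }
            row.update(s.events)
            row.update({f"{g}_mut": v for g, v in s.mutated_genes.items()})
            rows.append(row)
        return pd.DataFrame(rows)

    def sequence_str(self, chrom: str) -> str:
        codes = self.sequences[chrom]
        return codes_to_str(codes)

    def reference(self) -> dict[str, str]:
        """In-memory reference usable wherever a FASTA is accepted."""
        return {c: self.sequence_str(c) for c in self.sequences}


_BASE_ARR = np.frombuffer(b"ACGT", dtype=np.uint8)


def codes_to_str(codes: np.ndarray) -> str:
    return _BASE_ARR[codes].tobytes().decode()


# canonical (pyrimidine-centered) context handling ---------------------------

_CONTEXTS_32 = tuple(
    f"{five}{center}{three}"
    for center in "CT" for five in BASES for three in BASES
)
_CONTEXT_INDEX = {c: i for i, c in enumerate(_CONTEXTS_32)}


def _revcomp(s: str) -> str:
    return "".join(COMPLEMENT[b] for b in reversed(s))


def _canonical_context(tri: str) -> str:
    return tri if tri[1] in "CT" else _revcomp(tri)


# 64-entry lookup: raw trinucleotide code -> canonical context index
_CANON_TABLE = np.empty(64, dtype=np.int8)
for _i5 in range(4):
    for _ic in range(4):
        for _i3 in range(4):
            _tri = BASES[_i5] + BASES[_ic] + BASES[_i3]
            _CANON_TABLE[16 * _i5 + 4 * _ic + _i3] = _CONTEXT_INDEX[
                _canonical_context(_tri)]

#: channel index -> (canonical context index, pyrimidine-frame alt base)
_CHANNEL_CONTEXT = []
for _ch in CHANNELS:
    _five, _ref, _alt, _three = _ch[0], _ch[2], _ch[4], _ch[6]
    _CHANNEL_CONTEXT.append((_CONTEXT_INDEX[f"{_five}{_ref}{_three}"], _alt))


def simulate_cohort(config: CohortSimConfig | None = None) -> SyntheticCohort:
    """Generate a complete synthetic two-group cohort.

    Per sample: a baseline diploid (or tetraploid, if WGD is drawn) segment
    profile; whole-arm gains/losses and focal amplicons drawn at the
    group's event frequencies; an SNV catalog whose size follows the
    group's TMB distribution and whose trinucleotide channels follow the
    group's signature mixture, placed by rejection-sampling reference
    positions with the matching context; planted missense variants for the
    mutated-gene panel; and exponential survival with uniform censoring.
    """
    config = config or CohortSimConfig()
    rng = np.random.default_rng(config.seed)
    build, arms, genes = toy_genome(config.genome_scale_mb)
    catalog = toy_catalog()
    sequences = {
        chrom: rng.integers(0, 4, size=length, dtype=np.uint8)
        for chrom, length in build.lengths.items()
    }
    gene_map = {g.symbol: g for g in genes}
    arm_map = {a.name: a for a in arms}
    genome_mb = build.genome_mb

    samples = []
    for gi, (group, n) in enumerate((("<50", config.n_young),
                                     (">=50", config.n_old))):
        for k in range(n):
            sid = f"{'Y' if gi == 0 else 'O'}{k + 1:03d}"
            samples.append(_simulate_sample(
                sid, group, gi, config, rng, build, arms, arm_map, gene_map,
                catalog, sequences, genome_mb))
    return SyntheticCohort(config, build, arms, genes, catalog, sequences,
                           samples)


def _simulate_sample(sid, group, gi, config, rng, build, arms, arm_map,
                     gene_map, catalog, sequences, genome_mb) -> SyntheticSample:
    sex = "male" if rng.random() < config.male_prob[gi] else "female"
    smoking = str(rng.choice(["ever", "never", "unknown"],
                             p=np.asarray(config.smoking_probs[gi]) /
                             sum(config.smoking_probs[gi])))
    wgd = bool(rng.random() < config.wgd_prob[gi])
    base_total, base_major = (4, 2) if wgd else (2, 1)

    events = {
        feature: bool(rng.random() < (py if gi == 0 else po))
        for feature, (py, po) in config.event_probs.items()
    }
    # Y-chromosome loss in males: near-universal in the older group.
    y_loss = sex == "male" and bool(rng.random() < (0.17 if gi == 0 else 1.0))

    segments = _build_segments(
        sid, config, rng, build, arm_map, gene_map, events, y_loss, sex,
        base_total, base_major, wgd)

    ploidy = _average_ploidy(segments)
    profile = SamplePloidyProfile(sid, purity=round(float(rng.uniform(0.3, 0.95)), 3),
                                  ploidy=ploidy, wgd=wgd)

    mutated = {
        g: bool(rng.random() < (py if gi == 0 else po))
        for g, (py, po) in config.mutation_probs.items()
    }

    tmb = float(rng.lognormal(math.log(config.tmb_median[gi]), config.tmb_sigma))
    n_snv = max(int(round(tmb * genome_mb)), 1)
    variants = _draw_snvs(sid, n_snv, config.signature_mixture[gi], catalog,
                          sequences, build, rng)
    variants += _plant_gene_mutations(sid, mutated, gene_map, sequences, rng)

    rate = -math.log(config.pfs24[sex]) / 24.0
    t_event = float(rng.exponential(1.0 / rate))
    t_cens = float(rng.uniform(*config.censor_range))
    survival = SurvivalRecord(sid, time=round(min(t_event, t_cens), 3),
                              event=t_event <= t_cens, group=group)

    return SyntheticSample(sid, group, sex, smoking, profile, events, mutated,
                           tmb, segments, variants, survival)


def _build_segments(sid, config, rng, build, arm_map, gene_map, events,
                    y_loss, sex, base_total, base_major, wgd):
    """Assemble non-overlapping per-chromosome segments with planted events."""
    minor = base_total - base_major

    def gain(total, major):
        return total + 1, major + 1

    def loss(total, major):
        if total - major > 0:
            return total - 1, major
        return max(total - 1, 0), max(major - 1, 0)

    # arm name -> (total, major) override
    arm_cn: dict[str, tuple[int, int]] = {}
    if events.get("8q_gain"):
        arm_cn["8q"] = gain(base_total, base_major)
    if events.get("chr20_gain"):
        arm_cn["20p"] = gain(base_total, base_major)
        arm_cn["20q"] = gain(base_total, base_major)
    if events.get("3p_loss"):
        arm_cn["3p"] = loss(base_total, base_major)

    focal: dict[str, tuple[int, int, float]] = {}  # chrom -> (start, end, CN)
    for feature, gene_symbol in FOCAL_FEATURES.items():
        if events.get(feature):
            g = gene_map[gene_symbol]
            margin = g.end - g.start
            start = max(g.start - margin, 0)
            end = min(g.end + margin, build.lengths[g.chromosome])
            focal[g.chromosome] = (start, end, config.focal_copy_number)

    segments = []
    for chrom, length in build.lengths.items():
        if chrom == "chrY" and sex == "female":
            continue
        if chrom in ("chrX", "chrY") and sex == "male":
            cn = (base_total // 2, base_total // 2)
            if chrom == "chrY" and y_loss:
                cn = (0, 0)
            pieces = [(0, length, cn)]
        else:
            pieces = []
            for arm in ("p", "q"):
                a = arm_map[f"{chrom.removeprefix('chr')}{arm}"]
                cn = arm_cn.get(a.name, (base_total, base_major))
                pieces.append((a.start, a.end, cn))
        if chrom in focal:
            fstart, fend, fcn = focal[chrom]
            fcn_int = int(round(fcn))
            new_pieces = []
            for (s, e, cn) in pieces:
                if fend <= s or fstart >= e:
                    new_pieces.append((s, e, cn))
                    continue
                if s < fstart:
                    new_pieces.append((s, fstart, cn))
                ov_s, ov_e = max(s, fstart), min(e, fend)
                new_pieces.append((ov_s, ov_e, (fcn_int, fcn_int - minor)))
                if e > fend:
                    new_pieces.append((fend, e, cn))
            pieces = new_pieces
        for s, e, (total, major) in pieces:
            jitter = rng.normal(0, config.cn_jitter) if config.cn_jitter else 0.0
            total_f = max(total + jitter, 0.0)
            segments.append(CopyNumberSegment(
                sid, chrom, s, e, round(total_f, 4),
                round(min(major + jitter / 2 if config.cn_jitter else major,
                          total_f), 4)))
    return segments


def _average_ploidy(segments: Sequence[CopyNumberSegment]) -> float:
    total_bp = sum(s.length for s in segments)
    weighted = sum(s.length * s.copy_number for s in segments)
    return round(weighted / total_bp, 4)


def _draw_snvs(sid, n_snv, mixture, catalog, sequences, build, rng):
    """Draw SNVs channel-first, then rejection-sample matching positions."""
    sig_names = list(mixture)
    sig_idx = [catalog.names.index(s) for s in sig_names]
    probs = np.array([mixture[s] for s in sig_names])
    chosen_sigs = rng.choice(len(sig_names), size=n_snv, p=probs)
    channels = np.empty(n_snv, dtype=np.int64)
    for j, cat_col in enumerate(sig_idx):
        mask = chosen_sigs == j
        if mask.any():
            channels[mask] = rng.choice(
                96, size=int(mask.sum()), p=catalog.matrix[:, cat_col])

    # pending[context] = list of SNV slots needing that canonical context
    pending: dict[int, list[int]] = {}
    for i, ch in enumerate(channels):
        ctx, _ = _CHANNEL_CONTEXT[ch]
        pending.setdefault(ctx, []).append(i)

    chroms = list(build.lengths)
    lengths = np.array([build.lengths[c] for c in chroms], dtype=float)
    chrom_p = lengths / lengths.sum()

    placements: dict[int, tuple[str, int]] = {}
    used: set[tuple[str, int]] = set()
    remaining = n_snv
    batch = max(4 * n_snv, 1024)
    guard = 0
    while remaining > 0:
        guard += 1
        if guard > 200:
            raise RuntimeError("context rejection sampling failed to converge")
        ci = rng.choice(len(chroms), size=batch, p=chrom_p)
        for c in np.unique(ci):
            chrom = chroms[int(c)]
            seq = sequences[chrom]
            L = len(seq)
            n_here = int((ci == c).sum())
            pos = rng.integers(1, L - 1, size=n_here)
            codes = (seq[pos - 1].astype(np.int16) * 16
                     + seq[pos] * 4 + seq[pos + 1])
            canon = _CANON_TABLE[codes]
            for p, ct in zip(pos, canon):
                slots = pending.get(int(ct))
                if not slots:
                    continue
                key = (chrom, int(p))
                if key in used:
                    continue
                used.add(key)
                placements[slots.pop()] = key
                remaining -= 1
                if not slots:
                    del pending[int(ct)]
            if remaining == 0:
                break

    variants = []
    for i in range(n_snv):
        chrom, p = placements[i]
        seq = sequences[chrom]
        ref = BASES[seq[p]]
        _, alt_pyr = _CHANNEL_CONTEXT[channels[i]]
        alt = alt_pyr if ref in "CT" else COMPLEMENT[alt_pyr]
        variants.append(SomaticVariant(sid, chrom, int(p) + 1, ref, alt))
    return variants


def _plant_gene_mutations(sid, mutated, gene_map, sequences, rng):
    variants = []
    for gene, flag in mutated.items():
        if not flag:
            continue
        g = gene_map[gene]
        pos0 = int(rng.integers(g.start, g.end))
        seq = sequences[g.chromosome]
        ref = BASES[seq[pos0]]
        alt = rng.choice([b for b in BASES if b != ref])
        variants.append(SomaticVariant(
            sid, g.chromosome, pos0 + 1, ref, str(alt),
            consequence="missense_variant", gene=gene))
    return variants


# ---------------------------------------------------------------------------
# fixture writing

def write_fixture(cohort: SyntheticCohort, directory: str,
                  overwrite: bool = False) -> dict[str, str]:
    """Write the cohort to disk in the pipeline's own input formats.

    Emits a segments TSV, one VCF per sample, the toy FASTA with its
    index, cytoband-style arm definitions, a gene BED, the signature
    catalog TSV, a metadata TSV, and the ground-truth JSON. Re-reading
    these files through the pipeline's readers reproduces the in-memory
    objects.
    """
    os.makedirs(directory, exist_ok=True)
    if os.listdir(directory) and not overwrite:
        raise FileExistsError(
            f"directory {directory!r} is not empty (pass overwrite=True)")

    paths = {}
    seed_note = f"# seed={cohort.config.seed}\n"

    seg_path = os.path.join(directory, "segments.tsv")
    write_segments([s for smp in cohort.samples for s in smp.segments], seg_path)
    paths["segments"] = seg_path

    vcf_dir = os.path.join(directory, "vcf")
    os.makedirs(vcf_dir, exist_ok=True)
    for smp in cohort.samples:
        vp = os.path.join(vcf_dir, f"{smp.sample}.vcf")
        write_vcf(smp.variants, vp, cohort.build.lengths, smp.sample)
    paths["vcf_dir"] = vcf_dir

    fasta_path = os.path.join(directory, "genome.fa")
    with open(fasta_path, "w") as fh:
        for chrom in cohort.build.chromosomes:
            fh.write(f">{chrom}\n")
            seq = cohort.sequence_str(chrom)
            for i in range(0, len(seq), 80):
                fh.write(seq[i:i + 80] + "\n")
    import pyfaidx

    pyfaidx.Faidx(fasta_path)  # writes genome.fa.fai
    paths["fasta"] = fasta_path

    arm_path = os.path.join(directory, "cytobands.tsv")
    with open(arm_path, "w") as fh:
        for arm in cohort.arms:
            band = f"{arm.arm}11"
            fh.write(f"{arm.chromosome}\t{arm.start}\t{arm.end}\t{band}\tgneg\n")
    paths["arms"] = arm_path

    bed_path = os.path.join(directory, "genes.bed")
    with open(bed_path, "w") as fh:
        for g in cohort.genes:
            fh.write(f"{g.chromosome}\t{g.start}\t{g.end}\t{g.symbol}\t0\t{g.strand}\n")
    paths["genes"] = bed_path

    cat_path = os.path.join(directory, "catalog.tsv")
    cohort.catalog.to_tsv(cat_path)
    paths["catalog"] = cat_path

    meta_path = os.path.join(directory, "metadata.tsv")
    meta = cohort.truth[["sample", "age_group", "sex", "smoking",
                         "time_months", "event"]]
    with open(meta_path, "w") as fh:
        fh.write(seed_note)
        meta.to_csv(fh, sep="\t", index=False)
    paths["metadata"] = meta_path

    truth_path = os.path.join(directory, "ground_truth.json")
    truth = cohort.truth.copy()
    truth_records = json.loads(truth.to_json(orient="records"))
    with open(truth_path, "w") as fh:
        json.dump({"seed": cohort.config.seed, "samples": truth_records},
                  fh, indent=1)
    paths["truth"] = truth_path

    build_path = os.path.join(directory, "build.yaml")
    with open(build_path, "w") as fh:
        fh.write(f"name: {cohort.build.name}\nlengths:\n")
        for c, l in cohort.build.lengths.items():
            fh.write(f"  {c}: {l}\n")
    paths["build"] = build_path
    return paths
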