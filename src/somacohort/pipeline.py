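"""End-to-end study driver.

Chains simulation or file ingestion through copy-number classification,
spectrum building and signature refitting, the per-sample feature table,
the contrast grid, and a JSON/markdown report. Every number in the report
is taken from a stage output that is also written to disk.
"""

from __future__ import annotations

import glob
import json
import logging
import os
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import yaml

from . import cnv, signatures, stats, variants as vr
from .genome import GenomeBuild, load_arm_definitions, load_genes_bed
from .simulate import (CohortSimConfig, SyntheticCohort, simulate_cohort,
                       write_fixture, FOCAL_FEATURES, MUTATION_PANEL)

logger = logging.getLogger(__name__)

#: The contrast grid mirroring the study's feature-by-demographic table.
DEFAULT_CONTRASTS: tuple[dict, ...] = (
    {"feature": "tmb", "grouping": "age"},
    {"feature": "tmb", "grouping": "sex"},
    {"feature": "tmb", "grouping": "smoking"},
    {"feature": "8q_gain", "grouping": "age"},
    {"feature": "chr20_gain", "grouping": "age"},
    {"feature": "7p11_amp", "grouping": "age"},
    {"feature": "11q13_amp", "grouping": "age"},
    {"feature": "TP53_mut", "grouping": "age"},
    {"feature": "CDKN2A_mut", "grouping": "age"},
    {"feature": "LRP1B_mut", "grouping": "age"},
    {"feature": "3p_loss", "grouping": "sex"},
    {"feature": "7p11_amp", "grouping": "sex"},
    {"feature": "11q13_amp", "grouping": "sex"},
    {"feature": "TP53_mut", "grouping": "sex"},
    {"feature": "NOTCH1_mut", "grouping": "sex"},
    {"feature": "7p11_amp", "grouping": "smoking"},
    {"feature": "11q13_amp", "grouping": "smoking"},
    {"feature": "TP53_mut", "grouping": "smoking"},
    {"feature": "NOTCH1_mut", "grouping": "smoking"},
)


@dataclass
class StudyConfig:
    """Study-level configuration: simulate OR ingest, never both."""

    simulate: CohortSimConfig | None = None
    inputs: dict | None = None  # paths: segments, vcf_dir, fasta, arms,
    #                             genes, catalog, metadata, build
    rule_family: str = "tcga_conditional"
    tmb_denominator_mb: float | None = None  # default: build genome size
    contrasts: Sequence[Mapping[str, str]] = DEFAULT_CONTRASTS
    outdir: str = "study_out"
    seed: int | None = None

    def __post_init__(self):
        if (self.simulate is None) == (self.inputs is None):
            raise ValueError("exactly one of simulate/inputs must be given")

    @classmethod
    def from_yaml(cls, path: str) -> "StudyConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        sim = raw.get("simulate")
        if sim is not None:
            sim = CohortSimConfig(**sim)
        return cls(
            simulate=sim,
            inputs=raw.get("inputs"),
            rule_family=raw.get("rule_family", "tcga_conditional"),
            tmb_denominator_mb=raw.get("tmb_denominator_mb"),
            contrasts=raw.get("contrasts", DEFAULT_CONTRASTS),
            outdir=raw.get("outdir", "study_out"),
            seed=raw.get("seed"),
        )


def characterize_sample(
    sample: str,
    segments,
    sample_variants,
    build: GenomeBuild,
    arms,
    genes,
    catalog,
    reference,
    rule_family: str = "tcga_conditional",
    genome_mb: float | None = None,
) -> dict:
    """All per-sample genomic features from segments + variants.

    Recomputes WGD and average ploidy from the segments (the PURPLE-style
    inputs carry raw estimates, not calls), classifies every callable arm
    and panel gene, scores aneuploidy, summarizes mutation burden and the
    non-synonymous panel, and refits the mutational spectrum.
    """
    genome_mb = genome_mb or build.genome_mb
    wgd = cnv.infer_wgd(segments, build)
    total_bp = sum(s.length for s in segments)
    ploidy = sum(s.length * s.copy_number for s in segments) / total_bp
    profile = cnv.SamplePloidyProfile(sample, purity=1.0, ploidy=ploidy, wgd=wgd)

    arm_calls = [
        cnv.classify_arm(arm, segments, profile)
        for arm in arms if arm.callable
    ]
    autosomal_calls = [c for c in arm_calls
                       if not c.arm.startswith(("X", "Y"))]
    score = cnv.aneuploidy_score(autosomal_calls, sample=sample)

    row: dict = {
        "sample": sample,
        "wgd": wgd,
        "ploidy": round(ploidy, 4),
        "aneuploidy_score": score.score,
    }
    call_map = {c.arm: c.status for c in arm_calls}
    row["8q_gain"] = call_map.get("8q") == "amplified"
    row["chr20_gain"] = (call_map.get("20p") == "amplified"
                         and call_map.get("20q") == "amplified")
    row["3p_loss"] = call_map.get("3p") == "deleted"

    gene_map = {g.symbol: g for g in genes}
    for feature, symbol in FOCAL_FEATURES.items():
        g = gene_map[symbol]
        cn = cnv.gene_copy_number(g, segments)
        row[feature] = cnv.classify_gene(cn, profile, rule_family) == "amplified"
        row[f"{symbol}_cn"] = cn

    summary = vr.summarize_sample(sample_variants, genome_mb, MUTATION_PANEL)
    row["tmb"] = summary.tmb
    row["n_variants"] = summary.n_variants
    row["n_snv"] = summary.n_snv
    for g, flag in summary.gene_flags.items():
        row[f"{g}_mut"] = flag

    spectrum = signatures.build_spectrum(sample_variants, reference, sample)
    if spectrum.total > 0:
        profile_sig = signatures.refit_exposures(spectrum, catalog)
        row["dominant_signature_group"] = profile_sig.dominant
        row["reconstruction_cosine"] = round(profile_sig.cosine_similarity, 6)
        row["_exposures"] = profile_sig.contributions
    else:
        row["dominant_signature_group"] = "none"
        row["reconstruction_cosine"] = float("nan")
        row["_exposures"] = {}
    row["_spectrum"] = spectrum
    row["_arm_calls"] = arm_calls
    return row


def run_study(config: StudyConfig) -> dict:
    """Run the full pipeline and write the report bundle to config.outdir."""
    os.makedirs(config.outdir, exist_ok=True)
    stage = "setup"
    try:
        stage = "ingest"
        if config.simulate is not None:
            if config.seed is not None:
                config.simulate.seed = config.seed
            cohort = simulate_cohort(config.simulate)
            build, arms, genes = cohort.build, cohort.arms, cohort.genes
            catalog = cohort.catalog
            reference = cohort.reference()
            per_sample = {
                s.sample: (s.segments, s.variants) for s in cohort.samples
            }
            metadata = cohort.truth[["sample", "age_group", "sex", "smoking",
                                     "time_months", "event"]]
        else:
            build, arms, genes, catalog, reference, per_sample, metadata = (
                _load_inputs(config.inputs))

        genome_mb = config.tmb_denominator_mb or build.genome_mb

        stage = "characterize"
        rows = [
            characterize_sample(sid, segs, vars_, build, arms, genes, catalog,
                                reference, config.rule_family, genome_mb)
            for sid, (segs, vars_) in per_sample.items()
        ]
        spectra = [r.pop("_spectrum") for r in rows]
        exposures = [r.pop("_exposures") for r in rows]
        arm_calls = [r.pop("_arm_calls") for r in rows]

        features = pd.DataFrame(rows).merge(metadata, on="sample")

        stage = "write-calls"
        _write_calls(arm_calls, features, config.outdir)
        signatures.write_spectra(spectra, os.path.join(config.outdir,
                                                       "spectra.tsv"))
        _write_exposures(features["sample"], exposures,
                         os.path.join(config.outdir, "exposures.tsv"))
        feat_out = features.drop(
            columns=[c for c in features.columns if c.startswith("_")])
        feat_out.to_csv(os.path.join(config.outdir, "feature_table.tsv"),
                        sep="\t", index=False)

        stage = "contrasts"
        results = stats.run_contrast_grid(features, config.contrasts)
        res_df = stats.results_to_frame(results)
        res_df.to_csv(os.path.join(config.outdir, "contrasts.tsv"),
                      sep="\t", index=False)

        stage = "survival"
        survival = _survival_summary(features)

        stage = "report"
        report = _build_report(features, res_df, survival, config)
        with open(os.path.join(config.outdir, "report.json"), "w") as fh:
            json.dump(report, fh, indent=1, default=_jsonify)
        _write_markdown(report, os.path.join(config.outdir, "report.md"))
        return report
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {exc}") from exc


def _load_inputs(inputs: dict):
    import pyfaidx

    for key in ("segments", "vcf_dir", "fasta", "arms", "genes", "catalog",
                "metadata", "build"):
        if key not in inputs:
            raise ValueError(f"inputs block missing {key!r}")
        if key != "vcf_dir" and not os.path.exists(inputs[key]):
            raise FileNotFoundError(f"input file not found: {inputs[key]}")
    with open(inputs["build"]) as fh:
        build = GenomeBuild.from_yaml(fh)
    arms = load_arm_definitions(inputs["arms"], build)
    genes = load_genes_bed(inputs["genes"], build)
    catalog = signatures.SignatureCatalog.from_tsv(inputs["catalog"])
    reference = pyfaidx.Fasta(inputs["fasta"])
    seg_by_sample = cnv.read_segments(inputs["segments"])
    per_sample = {}
    for path in sorted(glob.glob(os.path.join(inputs["vcf_dir"], "*.vcf"))):
        sid = os.path.basename(path).removesuffix(".vcf")
        per_sample[sid] = (seg_by_sample.get(sid, []), vr.read_vcf(path, sid))
    metadata = pd.read_csv(inputs["metadata"], sep="\t", comment="#")
    return build, arms, genes, catalog, reference, per_sample, metadata


def _write_calls(arm_calls, features, outdir):
    rows = []
    for calls in arm_calls:
        for c in calls:
            rows.append((c.sample, f"arm:{c.arm}", c.status,
                         f"{c.deleted_fraction:.4f}/{c.amplified_fraction:.4f}"))
    for _, r in features.iterrows():
        for feat in ("8q_gain", "chr20_gain", "3p_loss", "7p11_amp",
                     "11q13_amp"):
            rows.append((r["sample"], feat, "present" if r[feat] else "absent",
                         ""))
    pd.DataFrame(rows, columns=["sample", "feature", "status", "value"]).to_csv(
        os.path.join(outdir, "calls.tsv"), sep="\t", index=False)


def _write_exposures(sample_ids, exposures, path):
    rows = []
    for sid, exp in zip(sample_ids, exposures):
        row = {"sample": sid}
        row.update({k: round(v, 6) for k, v in exp.items()})
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def _survival_summary(features) -> dict:
    out = {}
    if "time_months" not in features.columns:
        return out
    recs = {
        sex: [stats.SurvivalRecord(r["sample"], r["time_months"],
                                   bool(r["event"]), sex)
              for _, r in features[features["sex"] == sex].iterrows()
              if r["time_months"] > 0]
        for sex in ("male", "female")
    }
    if recs["male"] and recs["female"]:
        out["pfs24_male"] = round(stats.km_survival_at(recs["male"], 24.0), 4)
        out["pfs24_female"] = round(stats.km_survival_at(recs["female"], 24.0), 4)
        out["logrank_sex_p"] = round(stats.log_rank(recs["male"],
                                                    recs["female"]), 4)
    return out


def _build_report(features, res_df, survival, config) -> dict:
    groups = {"young": features[features["age_group"] == "<50"],
              "old": features[features["age_group"] == ">=50"]}
    tmb = {}
    freq = {}
    for name, g in groups.items():
        if len(g):
            med, mad = stats.median_mad(g["tmb"])
            tmb[name] = {"median": round(med, 4), "mad": round(mad, 4),
                         "n": len(g)}
            freq[name] = {
                feat: round(float(g[feat].mean()), 4)
                for feat in ("8q_gain", "chr20_gain", "3p_loss", "7p11_amp",
                             "11q13_amp", "TP53_mut", "LRP1B_mut",
                             "NOTCH1_mut", "CDKN2A_mut")
                if feat in g.columns
            }
    dom = features.groupby("age_group")["dominant_signature_group"] \
                  .agg(lambda s: s.value_counts().to_dict()).to_dict()
    aneu = {name: stats.median_mad(g["aneuploidy_score"])[0]
            for name, g in groups.items() if len(g)}
    return {
        "n_samples": len(features),
        "tmb": tmb,
        "event_frequencies": freq,
        "dominant_signature_groups": dom,
        "aneuploidy_median": aneu,
        "wgd_fraction": round(float(features["wgd"].mean()), 4),
        "contrasts": res_df.to_dict(orient="records"),
        "survival": survival,
        "rule_family": config.rule_family,
        "note": "p-values are raw (no multiple-testing correction)",
    }


def _jsonify(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.bool_):
        return bool(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")


def _write_markdown(report: dict, path: str) -> None:
    lines = ["# Study report", ""]
    for name, t in report["tmb"].items():
        lines.append(f"- TMB {name}: median {t['median']} "
                     f"(MAD = {t['mad']}), n = {t['n']}")
    lines.append("")
    lines.append("| feature | grouping | test | p | printed |")
    lines.append("|---|---|---|---|---|")
    for r in report["contrasts"]:
        lines.append(f"| {r['feature']} | {r['grouping']} | {r['test']} | "
                     f"{r['p']:.4g} | {r['p_printed']} |")
    if report["survival"]:
        lines.append("")
        for k, v in report["survival"].items():
            lines.append(f"- {k}: {v}")
    lines.append("")
    lines.append(f"_{report['note']}_")
    with open(path, "w") as fh:
        fh.write("\n".join(lines) + "\n")
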