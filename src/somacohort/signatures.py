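"""Trinucleotide mutation spectra and reference-signature refitting.

Spectra use the standard 96-channel pyrimidine-centered scheme: six
substitution classes (C>A, C>G, C>T, T>A, T>C, T>G), each in 16 flanking
contexts, ordered class-major then 5' then 3' flank (A[C>A]A ... T[T>G]T).
Purine-centered substitutions are reverse-complemented onto this frame.

Refitting solves a non-negative least-squares problem on the
frequency-normalized spectrum against a catalog of known signatures
(COSMIC v2/v3 TSVs are accepted as input) and reports relative
contributions plus the cosine similarity of the reconstruction.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from scipy.spatial.distance import cosine as _cosine_distance

from .variants import SomaticVariant

logger = logging.getLogger(__name__)

BASES = "ACGT"
COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A"}
SUBSTITUTIONS = ("C>A", "C>G", "C>T", "T>A", "T>C", "T>G")

#: Channel labels in canonical order, e.g. "A[C>A]A".
CHANNELS: tuple[str, ...] = tuple(
    f"{five}[{sub}]{three}"
    for sub in SUBSTITUTIONS
    for five in BASES
    for three in BASES
)
_CHANNEL_INDEX = {c: i for i, c in enumerate(CHANNELS)}

#: Default signature -> biological group mapping used for dominance calls.
DEFAULT_GROUPS: dict[str, str] = {
    "SBS1": "clock-like (SBS1/5)",
    "SBS5": "clock-like (SBS1/5)",
    "SBS2": "APOBEC (SBS2/13)",
    "SBS13": "APOBEC (SBS2/13)",
    "SBS4": "tobacco (SBS4/92)",
    "SBS92": "tobacco (SBS4/92)",
}
#: Fixed precedence for tie-breaking between groups.
GROUP_ORDER = ("clock-like (SBS1/5)", "APOBEC (SBS2/13)", "tobacco (SBS4/92)", "other")


def classify_context(ref: str, alt: str, five: str, three: str) -> int:
    """Channel index of a single-base substitution in its trinucleotide context.

    Purine reference bases are reverse-complemented (substitution and both
    flanks) so the central base is a pyrimidine.
    """
    for b in (ref, alt, five, three):
        if b not in BASES:
            raise ValueError(f"unscorable context: ambiguous base {b!r}")
    if ref == alt:
        raise ValueError("ref and alt must differ")
    if ref in "AG":  # purine: flip strand
        ref, alt = COMPLEMENT[ref], COMPLEMENT[alt]
        five, three = COMPLEMENT[three], COMPLEMENT[five]
    return _CHANNEL_INDEX[f"{five}[{ref}>{alt}]{three}"]


@dataclass(frozen=True)
class TrinucleotideSpectrum:
    sample: str
    counts: np.ndarray  # shape (96,), non-negative integers

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.shape != (96,):
            raise ValueError("spectrum must have 96 channels")
        if (counts < 0).any():
            raise ValueError("spectrum counts must be non-negative")
        object.__setattr__(self, "counts", counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"channel": CHANNELS, self.sample: self.counts})


class _SequenceAccessor:
    """Uniform flank lookup over a pyfaidx.Fasta or a dict of strings."""

    def __init__(self, reference):
        self._ref = reference

    def fetch(self, chrom: str, start: int, end: int) -> str:
        """Zero-based half-open slice of the reference."""
        try:
            seq = self._ref[chrom][start:end]
        except KeyError as exc:
            raise ValueError(f"chromosome {chrom!r} not in reference") from exc
        return str(getattr(seq, "seq", seq)).upper()


def build_spectrum(
    variants: Sequence[SomaticVariant],
    reference,
    sample: str | None = None,
) -> TrinucleotideSpectrum:
    """96-channel spectrum of a sample's SNVs.

    ``reference`` is a pyfaidx.Fasta (or any mapping of chromosome to
    sequence) providing the two flanking bases. Non-SNVs are ignored;
    SNVs with unscorable (ambiguous) contexts are logged and skipped.
    """
    acc = _SequenceAccessor(reference)
    counts = np.zeros(96, dtype=np.int64)
    if sample is None:
        sample = variants[0].sample if variants else ""
    skipped = 0
    for v in variants:
        if not v.is_snv:
            continue
        pos0 = v.position - 1  # to zero-based
        if pos0 < 1:
            raise ValueError(f"SNV at {v.chromosome}:{v.position} lacks a 5' flank")
        tri = acc.fetch(v.chromosome, pos0 - 1, pos0 + 2)
        if len(tri) < 3:
            raise ValueError(
                f"SNV at {v.chromosome}:{v.position} outside reference bounds"
            )
        if tri[1] != v.ref.upper():
            raise ValueError(
                f"reference mismatch at {v.chromosome}:{v.position}: "
                f"VCF says {v.ref}, FASTA says {tri[1]}"
            )
        try:
            counts[classify_context(tri[1], v.alt.upper(), tri[0], tri[2])] += 1
        except ValueError:
            skipped += 1
    if skipped:
        logger.info("%d SNVs had unscorable contexts and were skipped", skipped)
    return TrinucleotideSpectrum(sample, counts)


@dataclass(frozen=True)
class SignatureCatalog:
    names: tuple[str, ...]
    matrix: np.ndarray  # shape (96, n_signatures); columns sum to 1

    def __post_init__(self):
        matrix = np.asarray(self.matrix, dtype=float)
        if matrix.shape != (96, len(self.names)):
            raise ValueError("catalog matrix must be 96 x n_signatures")
        if (matrix < 0).any():
            raise ValueError("signature probabilities must be non-negative")
        sums = matrix.sum(axis=0)
        if not np.allclose(sums, 1.0, atol=1e-6):
            raise ValueError("each signature must sum to 1 within 1e-6")
        object.__setattr__(self, "matrix", matrix)

    def subset(self, names: Sequence[str]) -> "SignatureCatalog":
        idx = [self.names.index(n) for n in names]
        return SignatureCatalog(tuple(names), self.matrix[:, idx])

    @classmethod
    def from_tsv(cls, source) -> "SignatureCatalog":
        """Read a COSMIC-layout catalog: first column channel labels,
        one column per signature."""
        df = pd.read_csv(source, sep="\t")
        df = df.set_index(df.columns[0])
        try:
            df = df.loc[list(CHANNELS)]
        except KeyError as exc:
            raise ValueError("catalog rows do not cover the 96 channels") from exc
        mat = df.to_numpy(dtype=float)
        mat = mat / mat.sum(axis=0, keepdims=True)
        return cls(tuple(df.columns), mat)

    def to_tsv(self, path) -> None:
        df = pd.DataFrame(self.matrix, columns=list(self.names))
        df.insert(0, "Type", CHANNELS)
        df.to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class ExposureProfile:
    sample: str
    contributions: Mapping[str, float]  # relative, sum to 1
    cosine_similarity: float
    dominant: str = ""


def refit_exposures(
    spectrum: TrinucleotideSpectrum,
    catalog: SignatureCatalog,
    grouping: Mapping[str, str] | None = None,
) -> ExposureProfile:
    """Non-negative least-squares refit of a spectrum against known signatures.

    Minimizes ||m - S e||_2 with e >= 0 where m is the spectrum normalized
    to frequencies. Contributions are e renormalized to sum 1; the cosine
    similarity between m and the reconstruction S e is reported.
    """
    if spectrum.total == 0:
        raise ValueError("empty spectrum: no scorable SNVs to refit")
    m = spectrum.counts.astype(float) / spectrum.total
    e, _ = nnls(catalog.matrix, m)
    total = e.sum()
    if total == 0:
        warnings.warn("refit produced all-zero exposures")
        contributions = {n: 0.0 for n in catalog.names}
        cos = 0.0
    else:
        contributions = dict(zip(catalog.names, e / total))
        recon = catalog.matrix @ e
        cos = float(1.0 - _cosine_distance(m, recon))
    profile = ExposureProfile(spectrum.sample, contributions, cos)
    dom = dominant_group(profile, grouping or DEFAULT_GROUPS)
    return ExposureProfile(spectrum.sample, contributions, cos, dom)


def dominant_group(
    profile: ExposureProfile, grouping: Mapping[str, str] | None = None
) -> str:
    """Biological signature group with the largest summed contribution.

    Unmapped signatures fall into "other" with a warning; exact ties are
    broken by the fixed group order (and logged).
    """
    grouping = grouping or DEFAULT_GROUPS
    sums: dict[str, float] = {}
    for sig, contrib in profile.contributions.items():
        group = grouping.get(sig)
        if group is None:
            warnings.warn(f"signature {sig} has no group mapping; assigning 'other'")
            group = "other"
        sums[group] = sums.get(group, 0.0) + contrib
    order = {g: i for i, g in enumerate(GROUP_ORDER)}
    best = max(sums, key=lambda g: (sums[g], -order.get(g, len(order))))
    ties = [g for g, s in sums.items() if s == sums[best] and g != best]
    if ties:
        warnings.warn(
            f"dominant-group tie between {best} and {ties}; "
            "resolved by fixed group order"
        )
    return best


def toy_catalog() -> SignatureCatalog:
    """A small synthetic four-signature catalog for tests and simulation.

    The four signatures are synthetic stand-ins shaped after well-known
    biological processes (they are NOT the COSMIC reference vectors):

    - SBS1: C>T at NpCpG sites (spontaneous 5-methylcytosine deamination);
    - SBS2: C>T in a TpCpN context (APOBEC deamination);
    - SBS13: C>G in a TpCpN context (APOBEC with REV1 lesion bypass);
    - SBS5: a flat, featureless background (clock-like).

    Each concentrates 90% of its mass on its characteristic channels with a
    10% uniform floor, keeping the columns linearly well-separated so
    mixtures are identifiable.
    """
    mat = np.zeros((96, 4))
    names = ("SBS1", "SBS2", "SBS5", "SBS13")

    def channels_where(sub, five=None, three=None):
        idx = []
        for i, ch in enumerate(CHANNELS):
            if f"[{sub}]" not in ch:
                continue
            if five is not None and ch[0] not in five:
                continue
            if three is not None and ch[-1] not in three:
                continue
            idx.append(i)
        return idx

    peaked = {
        0: channels_where("C>T", three="G"),          # SBS1-like
        1: channels_where("C>T", five="T"),           # SBS2-like
        3: channels_where("C>G", five="T"),           # SBS13-like
    }
    for col, idx in peaked.items():
        mat[idx, col] = 0.9 / len(idx)
        mat[:, col] += 0.1 / 96
    mat[:, 2] = 1.0 / 96                              # SBS5-like: flat
    return SignatureCatalog(names, mat)


def write_spectra(spectra: Sequence[TrinucleotideSpectrum], path) -> None:
    """Write spectra as a 96-row TSV, one column per sample.

    The header comment records the channel ordering convention.
    """
    df = pd.DataFrame({"channel": CHANNELS})
    for s in spectra:
        df[s.sample] = s.counts
    with open(path, "w") as fh:
        fh.write("# 96 channels, pyrimidine-centered, class-major order "
                 "(A[C>A]A ... T[T>G]T)\n")
        df.to_csv(fh, sep="\t", index=False)
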