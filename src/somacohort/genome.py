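"""Reference coordinate system: chromosomes, arms, and gene loci.

All coordinates are zero-based half-open internally; 1-based positions
(VCF convention) are converted at the read boundary.
"""

from __future__ import annotations

import io
import logging
import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import yaml

logger = logging.getLogger(__name__)

#: Short arms of the acrocentric human chromosomes carry only repetitive
#: rDNA/heterochromatin and are excluded from arm-level calling by convention.
ACROCENTRIC_SHORT_ARMS = frozenset({"13p", "14p", "15p", "21p", "22p"})


@dataclass(frozen=True)
class GenomeBuild:
    """An ordered set of chromosomes with lengths.

    The autosome subset (22 chromosomes for a human build) drives
    whole-genome-duplication inference and the aneuploidy denominator;
    sex chromosomes stay callable for arm events but are excluded there.
    """

    name: str
    lengths: Mapping[str, int]
    chromosomes: tuple[str, ...] = field(init=False)

    def __post_init__(self):
        names = tuple(self.lengths)
        if len(set(names)) != len(names):
            raise ValueError("duplicate chromosome names")
        for c, l in self.lengths.items():
            if l <= 0:
                raise ValueError(f"non-positive length for {c}")
        object.__setattr__(self, "chromosomes", names)

    @property
    def autosomes(self) -> tuple[str, ...]:
        return tuple(c for c in self.chromosomes if _is_autosome(c))

    @property
    def genome_mb(self) -> float:
        """Total genome size in megabases (the default TMB denominator)."""
        return sum(self.lengths.values()) / 1e6

    @classmethod
    def from_fai(cls, path: str, name: str = "custom") -> "GenomeBuild":
        lengths = {}
        with open(path) as fh:
            for line in fh:
                parts = line.rstrip("\n").split("\t")
                lengths[parts[0]] = int(parts[1])
        return cls(name=name, lengths=lengths)

    @classmethod
    def from_yaml(cls, stream) -> "GenomeBuild":
        cfg = yaml.safe_load(stream)
        return cls(name=cfg.get("name", "custom"),
                   lengths={str(k): int(v) for k, v in cfg["lengths"].items()})


def _is_autosome(chrom: str) -> bool:
    c = chrom.removeprefix("chr")
    return c.isdigit() and 1 <= int(c) <= 22


@dataclass(frozen=True)
class ChromosomeArm:
    chromosome: str
    arm: str  # "p" or "q"
    start: int
    end: int
    callable: bool = True

    def __post_init__(self):
        if self.arm not in ("p", "q"):
            raise ValueError(f"arm must be p or q, got {self.arm!r}")
        if self.end <= self.start:
            raise ValueError(f"empty arm interval {self.name}")

    @property
    def name(self) -> str:
        return f"{self.chromosome.removeprefix('chr')}{self.arm}"

    @property
    def length(self) -> int:
        return self.end - self.start


@dataclass(frozen=True)
class GeneLocus:
    symbol: str
    chromosome: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"empty interval for gene {self.symbol}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"bad strand {self.strand!r}")


def overlap_length(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Length in bp of the intersection of two half-open intervals.

    Symmetric; disjoint or merely adjacent intervals return 0.
    """
    return max(0, min(a[1], b[1]) - max(a[0], b[0]))


def load_arm_definitions(source, build: GenomeBuild) -> list[ChromosomeArm]:
    """Build one p and one q arm per chromosome from a cytoband table.

    ``source`` is a path or text stream in UCSC cytoBand layout
    (chrom, start, end, band, stain). Each arm is the union of its bands;
    "acen" bands are split at the centromere midpoint so every base belongs
    to exactly one arm. Acrocentric short arms are marked non-callable.

    Rows naming unknown chromosomes are dropped with a warning; a
    chromosome present in the table but missing one arm is an error.
    """
    if isinstance(source, str):
        fh = open(source)
    else:
        fh = source
    # arm -> [min_start, max_end]
    extents: dict[tuple[str, str], list[int]] = {}
    acen: dict[str, list[tuple[str, int, int]]] = {}
    with fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"malformed cytoband row at line {i}: {line!r}")
            chrom, start, end, band = parts[0], int(parts[1]), int(parts[2]), parts[3]
            stain = parts[4] if len(parts) > 4 else ""
            if chrom not in build.lengths:
                warnings.warn(f"cytoband row for unknown chromosome {chrom!r} dropped")
                continue
            if end > build.lengths[chrom]:
                raise ValueError(f"band {chrom}{band} extends past chromosome end")
            arm = band[:1]
            if arm not in ("p", "q"):
                raise ValueError(f"band name {band!r} does not encode an arm")
            if stain == "acen":
                acen.setdefault(chrom, []).append((arm, start, end))
                continue
            key = (chrom, arm)
            ext = extents.setdefault(key, [start, end])
            ext[0] = min(ext[0], start)
            ext[1] = max(ext[1], end)

    # acen bands: split the centromere at its midpoint between p and q
    for chrom, bands in acen.items():
        lo = min(s for _, s, _ in bands)
        hi = max(e for _, _, e in bands)
        mid = (lo + hi) // 2
        for arm, bound in (("p", mid), ("q", mid)):
            key = (chrom, arm)
            if key in extents:
                if arm == "p":
                    extents[key][1] = max(extents[key][1], bound)
                else:
                    extents[key][0] = min(extents[key][0], bound)

    if not extents:
        raise ValueError("no arms defined")

    by_chrom: dict[str, set[str]] = {}
    for chrom, arm in extents:
        by_chrom.setdefault(chrom, set()).add(arm)
    for chrom, arms in by_chrom.items():
        if arms != {"p", "q"}:
            missing = ({"p", "q"} - arms).pop()
            raise ValueError(f"chromosome {chrom} is missing its {missing} arm")

    out = []
    for chrom in build.chromosomes:
        for arm in ("p", "q"):
            key = (chrom, arm)
            if key not in extents:
                continue
            start, end = extents[key]
            name = f"{chrom.removeprefix('chr')}{arm}"
            out.append(ChromosomeArm(chrom, arm, start, end,
                                     callable=name not in ACROCENTRIC_SHORT_ARMS))
    return out


def load_genes_bed(source, build: GenomeBuild | None = None) -> list[GeneLocus]:
    """Read gene loci from a BED file (chrom, start, end, name[, score, strand])."""
    if isinstance(source, str):
        fh = open(source)
    else:
        fh = source
    genes = []
    seen = set()
    with fh:
        for i, line in enumerate(fh, 1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            parts = line.split("\t")
            if len(parts) < 4:
                raise ValueError(f"BED row at line {i} lacks a name field")
            chrom, start, end, symbol = parts[0], int(parts[1]), int(parts[2]), parts[3]
            strand = parts[5] if len(parts) > 5 else "+"
            if build is not None and chrom not in build.lengths:
                warnings.warn(f"gene {symbol} on unknown chromosome {chrom!r} dropped")
                continue
            if build is not None and end > build.lengths[chrom]:
                raise ValueError(f"gene {symbol} extends past chromosome end")
            if symbol in seen:
                raise ValueError(f"duplicate gene symbol {symbol!r}")
            seen.add(symbol)
            genes.append(GeneLocus(symbol, chrom, start, end, strand))
    return genes
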