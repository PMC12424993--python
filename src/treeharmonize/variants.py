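"""Somatic variant domain types and readers/writers for standard formats.

Coordinates are 0-based half-open internally; conversion to/from VCF's
1-based convention happens only at the I/O boundary. Chromosome names are
taken verbatim from inputs.
"""

from __future__ import annotations

import enum
import logging
import warnings
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import pandas as pd
import pysam

logger = logging.getLogger(__name__)


class FormatError(ValueError):
    """Malformed input file."""


@dataclass(frozen=True, order=True)
class GenomicInterval:
    """0-based half-open genomic interval."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if not self.chrom:
            raise ValueError("empty chromosome name")
        if not self.start < self.end:
            raise ValueError(f"degenerate interval [{self.start}, {self.end})")

    def overlaps(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start < other.end
            and other.start < self.end
        )

    def contains_point(self, chrom: str, pos0: int) -> bool:
        return self.chrom == chrom and self.start <= pos0 < self.end

    def contains(self, other: "GenomicInterval") -> bool:
        return (
            self.chrom == other.chrom
            and self.start <= other.start
            and other.end <= self.end
        )

    def intersection(self, other: "GenomicInterval") -> Optional["GenomicInterval"]:
        if not self.overlaps(other):
            return None
        return GenomicInterval(
            self.chrom, max(self.start, other.start), min(self.end, other.end)
        )

    @property
    def length(self) -> int:
        return self.end - self.start


class VariantStatus(str, enum.Enum):
    PRESENT = "present"
    ABSENT = "absent"
    MISSING = "missing"
    LOST = "lost"  # assigned only by regenotyping


class SvType(str, enum.Enum):
    DEL = "DEL"
    INS = "INS"
    DUP = "DUP"
    INV = "INV"
    BND = "BND"


@dataclass
class SnvCall:
    """Per-subline status of one somatic SNV (1-based position)."""

    chrom: str
    pos: int
    ref_allele: str
    alt_allele: str
    subline: str
    status: VariantStatus
    depth: int = 0
    alt_depth: int = 0

    @property
    def vaf(self) -> float:
        return self.alt_depth / self.depth if self.depth > 0 else 0.0

    @property
    def key(self) -> Tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref_allele, self.alt_allele)


@dataclass
class SvCall:
    """One structural variant with its carrier subline set."""

    variant_id: str
    sv_type: SvType
    breakend_1: Tuple[str, int]
    breakend_2: Optional[Tuple[str, int]]
    length: Optional[int]
    sublines_present: Set[str]

    def __post_init__(self) -> None:
        if self.sv_type in (SvType.DEL, SvType.DUP, SvType.INV):
            if self.breakend_2 is None or self.breakend_1[0] != self.breakend_2[0]:
                raise ValueError(f"{self.sv_type.value} must have both breakends on one chromosome")
            if not self.breakend_1[1] < self.breakend_2[1]:
                raise ValueError("breakend positions must be increasing")

    @property
    def interval(self) -> Optional[GenomicInterval]:
        if self.breakend_2 is None or self.breakend_1[0] != self.breakend_2[0]:
            return None
        return GenomicInterval(self.breakend_1[0], self.breakend_1[1], self.breakend_2[1])


@dataclass
class CnaSegment:
    """Integer copy-number segment of one subline (diploid baseline = 2)."""

    interval: GenomicInterval
    copy_number: int
    subline: str

    def __post_init__(self) -> None:
        if self.copy_number < 0:
            raise ValueError("negative copy number")


class LossSource(str, enum.Enum):
    SV_DELETION = "sv_deletion"
    CN_LOSS = "cn_loss"


@dataclass
class LossRegion:
    """A genomic span where one subline lost sequence (deletion or CN<=1)."""

    interval: GenomicInterval
    subline: str
    source: LossSource


# ---------------------------------------------------------------------------
# Readers
# ---------------------------------------------------------------------------

def read_snv_vcf(path: str, subline: str) -> List[SnvCall]:
    """Read per-subline SNV calls from a (single-sample) VCF.

    Depth and alt depth come from FORMAT DP/AD when present, else INFO DP.
    Every record in the file is a "present" call for ``subline``.
    """
    calls: List[SnvCall] = []
    with pysam.VariantFile(path) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            if rec.alts is None:
                continue
            depth = 0
            alt_depth = 0
            if samples:
                fmt = rec.samples[samples[0]]
                if "DP" in fmt and fmt["DP"] is not None:
                    depth = int(fmt["DP"])
                ad = fmt.get("AD")
                if ad is not None and len(ad) >= 2 and ad[1] is not None:
                    alt_depth = int(ad[1])
            elif "DP" in rec.info:
                depth = int(rec.info["DP"])
            calls.append(
                SnvCall(
                    chrom=rec.chrom,
                    pos=rec.pos,
                    ref_allele=rec.ref,
                    alt_allele=rec.alts[0],
                    subline=subline,
                    status=VariantStatus.PRESENT,
                    depth=depth,
                    alt_depth=alt_depth,
                )
            )
    if not calls:
        logger.warning("no SNV records in %s", path)
    return calls


def read_sv_vcf(path: str) -> List[SvCall]:
    """Read multi-sample SV calls; carriers are samples with a non-ref GT."""
    out: List[SvCall] = []
    with pysam.VariantFile(path) as vcf:
        samples = list(vcf.header.samples)
        for rec in vcf:
            svtype = rec.info.get("SVTYPE")
            if svtype is None:
                continue
            svtype = SvType(str(svtype))
            carriers = set()
            for s in samples:
                gt = rec.samples[s].get("GT")
                if gt and any(a not in (0, None) for a in gt):
                    carriers.add(s)
            end = rec.info.get("END", rec.stop)
            length = rec.info.get("SVLEN")
            if isinstance(length, (tuple, list)):
                length = length[0]
            if length is not None:
                length = abs(int(length))
            be2: Optional[Tuple[str, int]]
            if svtype is SvType.INS:
                be2 = None
            elif svtype is SvType.BND:
                be2 = _parse_bnd_mate(rec.alts[0]) if rec.alts else None
            else:
                be2 = (rec.chrom, int(end))
            out.append(
                SvCall(
                    variant_id=rec.id or f"{rec.chrom}:{rec.pos}:{svtype.value}",
                    sv_type=svtype,
                    breakend_1=(rec.chrom, rec.pos),
                    breakend_2=be2,
                    length=length,
                    sublines_present=carriers,
                )
            )
    if not out:
        logger.warning("no SV records in %s", path)
    return out


def _parse_bnd_mate(alt: str) -> Optional[Tuple[str, int]]:
    for br in ("[", "]"):
        if br in alt:
            inner = alt.split(br)[1]
            chrom, pos = inner.split(":")
            return (chrom, int(pos))
    return None


CNA_COLUMNS = ["chrom", "start", "end", "copy_number", "subline"]


def read_cna_tsv(path: str) -> List[CnaSegment]:
    """Read integer copy-number segments from a headered TSV."""
    df = pd.read_csv(path, sep="\t")
    missing = set(CNA_COLUMNS) - set(df.columns)
    if missing:
        raise FormatError(f"CNA TSV missing columns: {sorted(missing)}")
    if df.empty:
        logger.warning("no CNA segments in %s", path)
    return [
        CnaSegment(
            interval=GenomicInterval(str(r.chrom), int(r.start), int(r.end)),
            copy_number=int(r.copy_number),
            subline=str(r.subline),
        )
        for r in df.itertuples()
    ]


def write_cna_tsv(segments: Sequence[CnaSegment], path: str) -> None:
    rows = [
        (s.interval.chrom, s.interval.start, s.interval.end, s.copy_number, s.subline)
        for s in segments
    ]
    pd.DataFrame(rows, columns=CNA_COLUMNS).to_csv(path, sep="\t", index=False)


def read_loss_bed(path: str) -> List[LossRegion]:
    """Read loss regions from BED3+ (cols 4/5 optionally subline, source)."""
    out: List[LossRegion] = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith(("#", "track")):
                continue
            parts = line.split("\t")
            if len(parts) < 3:
                raise FormatError(f"BED line with <3 columns: {line!r}")
            subline = parts[3] if len(parts) > 3 else ""
            source = (
                LossSource(parts[4]) if len(parts) > 4 else LossSource.SV_DELETION
            )
            out.append(
                LossRegion(
                    interval=GenomicInterval(parts[0], int(parts[1]), int(parts[2])),
                    subline=subline,
                    source=source,
                )
            )
    if not out:
        logger.warning("no loss regions in %s", path)
    return out


def write_loss_bed(losses: Sequence[LossRegion], path: str) -> None:
    with open(path, "w") as fh:
        for l in losses:
            fh.write(
                f"{l.interval.chrom}\t{l.interval.start}\t{l.interval.end}"
                f"\t{l.subline}\t{l.source.value}\n"
            )


# ---------------------------------------------------------------------------
# Germline subtraction
# ---------------------------------------------------------------------------

def subtract_germline(
    calls: Iterable[SnvCall],
    blacklist_variants: Iterable[Tuple[str, int, str, str]],
    blacklist_regions: Iterable[GenomicInterval],
) -> List[SnvCall]:
    """Drop calls matching a germline variant or inside a germline region.

    Variants are keyed (chrom, pos, ref, alt) with 1-based pos; regions are
    0-based half-open.
    """
    black = set(blacklist_variants)
    regions = list(blacklist_regions)
    kept = []
    for c in calls:
        if c.key in black:
            continue
        pos0 = c.pos - 1
        if any(r.contains_point(c.chrom, pos0) for r in regions):
            continue
        kept.append(c)
    return kept
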