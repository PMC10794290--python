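"""Reading per-site allele-count tables and VCFs; writing annotated call VCFs.

All coordinates on every interface in this module are 1-based and fully
closed, matching pileup, bam-readcount and VCF conventions.

The count-table dialect is the default bam-readcount output: tab-delimited
lines ``chrom  pos  ref  depth  base:count:meanMQ:meanBQ:...`` with one
colon-separated field block per base.  Only the first four colon fields of
each block (base, count, mean mapping quality, mean base quality) are
consumed; trailing fields are ignored, which keeps the parser robust to
version drift in the upstream extractor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import IO, Iterable, Iterator, Mapping, Sequence

import pysam

logger = logging.getLogger(__name__)

BASES = ("A", "C", "G", "T")


class CountTableParseError(ValueError):
    """A malformed line in a bam-readcount-dialect table."""


class VcfFormatError(ValueError):
    """An unreadable or malformed VCF input."""


@dataclass(frozen=True)
class RawBaseRecord:
    """Per-site raw counts and mean qualities for each of the four bases.

    ``counts``, ``mean_mq`` and ``mean_bq`` are keyed by base (A/C/G/T).
    ``depth`` is the depth reported by the extractor; the four base counts
    may sum to less than ``depth`` because reads showing N or indels are
    dropped upstream.
    """

    chrom: str
    pos: int  # 1-based
    ref_base: str
    depth: int
    counts: Mapping[str, int]
    mean_mq: Mapping[str, float]
    mean_bq: Mapping[str, float]


@dataclass(frozen=True)
class SiteCounts:
    """Read counts at one site split into reference / dominant-alternative /
    minor-alternative classes: K = R + M + X1 + X2 with M >= X1 >= X2."""

    chrom: str
    pos: int  # 1-based
    ref_base: str
    alt_base: str | None
    K: int
    R: int
    M: int
    X1: int
    X2: int

    def __post_init__(self) -> None:
        if self.K != self.R + self.M + self.X1 + self.X2:
            raise ValueError(f"K={self.K} != R+M+X1+X2 at {self.chrom}:{self.pos}")
        if min(self.R, self.M, self.X1, self.X2) < 0:
            raise ValueError(f"negative count at {self.chrom}:{self.pos}")
        # select_alleles guarantees M >= X1; re-scoring an external caller's
        # ALT may designate a non-dominant allele as M, so only the minor
        # classes are required to be ordered here.
        if not (self.X1 >= self.X2):
            raise ValueError(f"minor alternative counts not ordered at {self.chrom}:{self.pos}")
        if self.M > 0 and self.alt_base == self.ref_base:
            raise ValueError(f"alt == ref with M>0 at {self.chrom}:{self.pos}")

    @property
    def af(self) -> float:
        """Empirical alternative allele frequency M/K (0 for K=0)."""
        return self.M / self.K if self.K else 0.0


@dataclass(frozen=True)
class ExternalCall:
    """A single-nucleotide call taken from another caller's VCF."""

    chrom: str
    pos: int  # 1-based
    ref: str
    alt: str
    af: float | None = None
    source: str = ""

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError("pos must be >= 1")
        if self.ref == self.alt:
            raise ValueError("ref == alt")


@dataclass
class CallRecord:
    """One called/scored variant destined for VCF output."""

    chrom: str
    pos: int
    ref: str
    alt: str
    K: int
    R: int
    M: int
    psi: float
    log10_psi: float
    rank: int | None = None


def _parse_base_block(block: str, lineno: int) -> tuple[str, int, float, float] | None:
    parts = block.split(":")
    if len(parts) < 2:
        raise CountTableParseError(f"line {lineno}: malformed per-base field {block!r}")
    base = parts[0].upper()
    if base not in BASES:
        return None  # '=', 'N', indel blocks: not part of the four-allele model
    try:
        count = int(parts[1])
        mq = float(parts[2]) if len(parts) > 2 else 0.0
        bq = float(parts[3]) if len(parts) > 3 else 0.0
    except ValueError as exc:
        raise CountTableParseError(f"line {lineno}: non-numeric value in {block!r}") from exc
    return base, count, mq, bq


def parse_readcount_table(stream: IO[str] | Iterable[str]) -> list[RawBaseRecord]:
    """Parse a bam-readcount-dialect table into :class:`RawBaseRecord` rows.

    Input order is preserved.  Sites whose reference base is not one of
    A/C/G/T (e.g. N) are skipped with a warning.  Malformed lines raise
    :class:`CountTableParseError` naming the 1-based line number.
    """
    records: list[RawBaseRecord] = []
    n_skipped_ref = 0
    for lineno, line in enumerate(stream, start=1):
        line = line.rstrip("\n")
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) < 4:
            raise CountTableParseError(
                f"line {lineno}: expected >= 4 tab-separated fields, got {len(fields)}"
            )
        chrom = fields[0]
        try:
            pos = int(fields[1])
            depth = int(fields[3])
        except ValueError as exc:
            raise CountTableParseError(f"line {lineno}: non-numeric position/depth") from exc
        ref_base = fields[2].upper()
        if ref_base not in BASES:
            n_skipped_ref += 1
            logger.warning("line %d: reference base %r is not A/C/G/T; site skipped", lineno, ref_base)
            continue
        counts = {b: 0 for b in BASES}
        mq = {b: 0.0 for b in BASES}
        bq = {b: 0.0 for b in BASES}
        for block in fields[4:]:
            parsed = _parse_base_block(block, lineno)
            if parsed is None:
                continue
            base, c, m, q = parsed
            counts[base] = c
            mq[base] = m
            bq[base] = q
        records.append(
            RawBaseRecord(chrom=chrom, pos=pos, ref_base=ref_base, depth=depth,
                          counts=counts, mean_mq=mq, mean_bq=bq)
        )
    if n_skipped_ref:
        logger.info("skipped %d sites with non-ACGT reference base", n_skipped_ref)
    return records


def select_alleles(record: RawBaseRecord) -> SiteCounts:
    """Split a raw record into (K, R, M, X1, X2) and identify the dominant
    alternative allele.

    R is the reference-base count; M is the largest non-reference count; the
    remaining two non-reference counts become X1 >= X2.  Ties for the
    dominant allele are broken by higher mean quality (BQ+MQ)/2, then by
    alphabetical base order, so the outcome is deterministic.
    """
    ref = record.ref_base
    alts = [b for b in BASES if b != ref]
    # sort key: count desc, mean quality desc, base alphabetical
    def key(b: str) -> tuple:
        q = (record.mean_bq[b] + record.mean_mq[b]) / 2.0
        return (-record.counts[b], -q, b)

    alts_sorted = sorted(alts, key=key)
    alt_base = alts_sorted[0]
    m = record.counts[alt_base]
    x1, x2 = sorted((record.counts[alts_sorted[1]], record.counts[alts_sorted[2]]), reverse=True)
    r = record.counts[ref]
    return SiteCounts(
        chrom=record.chrom,
        pos=record.pos,
        ref_base=ref,
        alt_base=alt_base,
        K=r + m + x1 + x2,
        R=r,
        M=m,
        X1=x1,
        X2=x2,
    )


def read_external_calls(vcf_path: str, source: str = "") -> list[ExternalCall]:
    """Read biallelic SNV calls from a VCF 4.x file.

    Multiallelic records are split into one call per ALT; records whose REF
    or ALT is not a single A/C/G/T base (indels, MNVs, symbolic alleles) are
    skipped, with the skipped count reported through the module logger.
    """
    try:
        vf = pysam.VariantFile(vcf_path)
    except (OSError, ValueError) as exc:
        raise VcfFormatError(f"cannot read VCF {vcf_path!r}: {exc}") from exc
    calls: list[ExternalCall] = []
    n_skipped = 0
    with vf:
        for rec in vf:
            ref = (rec.ref or "").upper()
            alts = rec.alts or ()
            for j, alt in enumerate(alts):
                alt = (alt or "").upper()
                if len(ref) != 1 or len(alt) != 1 or ref not in BASES or alt not in BASES:
                    n_skipped += 1
                    continue
                af = None
                if "AF" in rec.info:
                    raw = rec.info["AF"]
                    try:
                        af = float(raw[j] if isinstance(raw, tuple) else raw)
                    except (TypeError, ValueError, IndexError):
                        af = None
                calls.append(ExternalCall(chrom=rec.chrom, pos=rec.pos, ref=ref, alt=alt,
                                          af=af, source=source))
    if n_skipped:
        logger.info("skipped %d non-SNV ALT alleles while reading %s", n_skipped, vcf_path)
    return calls


def _fmt(x: float) -> str:
    """Render a float with 6 significant digits, the fixed INFO format."""
    return f"{x:.6g}"


def write_calls_vcf(
    calls: Sequence[CallRecord],
    metadata: Mapping[str, object] | None = None,
    path: str | None = None,
) -> str:
    """Serialize scored calls as VCF 4.2 text, sorted by (chrom, pos).

    INFO carries DP (=K), AD (R,M), AF (=M/K), LFDR (psi) and L10LFDR
    (log10 psi).  L10LFDR is the authoritative score: psi values far below
    double-precision linear range round to an LFDR of 0 while L10LFDR keeps
    the full magnitude.  ``metadata`` entries become ``##lfdr_snv_*`` header
    lines (fit provenance such as pi0, g-mode and threshold).
    """
    lines = ["##fileformat=VCFv4.2", "##source=lfdr-snv"]
    for key, value in (metadata or {}).items():
        lines.append(f"##lfdr_snv_{key}={value}")
    for chrom in sorted({c.chrom for c in calls}):
        lines.append(f"##contig=<ID={chrom}>")
    lines.append('##INFO=<ID=DP,Number=1,Type=Integer,Description="Total read depth K">')
    lines.append('##INFO=<ID=AD,Number=R,Type=Integer,Description="Reference and dominant-alternative read counts (R,M)">')
    lines.append('##INFO=<ID=AF,Number=A,Type=Float,Description="Dominant-alternative allele frequency M/K">')
    lines.append('##INFO=<ID=LFDR,Number=1,Type=Float,Description="Local false discovery rate psi">')
    lines.append('##INFO=<ID=L10LFDR,Number=1,Type=Float,Description="log10 of the LFDR (authoritative score)">')
    lines.append('##INFO=<ID=RANK,Number=1,Type=Integer,Description="Priority rank, 1 = most probable variant">')
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for call in sorted(calls, key=lambda c: (c.chrom, c.pos, c.alt)):
        af = call.M / call.K if call.K else 0.0
        info = (
            f"DP={call.K};AD={call.R},{call.M};AF={_fmt(af)};"
            f"LFDR={_fmt(call.psi)};L10LFDR={_fmt(call.log10_psi)}"
        )
        if call.rank is not None:
            info += f";RANK={call.rank}"
        lines.append(
            f"{call.chrom}\t{call.pos}\t.\t{call.ref}\t{call.alt}\t.\tPASS\t{info}"
        )
    text = "\n".join(lines) + "\n"
    if path is not None:
        with open(path, "w") as fh:
            fh.write(text)
    return text
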