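"""Intake of direct-to-consumer raw genotype exports.

Consumer vendors each ship their own flat-file dialect: 23andMe-style
tab-separated files with ``#`` comment headers and a single genotype column,
AncestryDNA-style five-column files with the two alleles split, and
MyHeritage-style quoted CSV. This module detects the dialect, parses it into
a common :class:`GenomeProfile`, assigns the anonymous identity metadata
(9-character uniqueID, md5 source digest), and exports harmonized profiles
as single-sample VCFv4.2. Fixture writers for all three dialects are
included so the whole intake path is testable without any real upload.

Coordinates are GRCh37 throughout (the build of the 1000 Genomes phase 3
reference the pipeline is designed around); no liftover is attempted.
"""

from __future__ import annotations

import csv
import hashlib
import io
import random
import re
import warnings
from collections import Counter
from dataclasses import dataclass, field
from enum import Enum
from typing import IO, Iterable, Mapping, Optional, Sequence, Union

from .errors import EmptyProfile, MissingChromosomeWarning, UnrecognizedFormat

ALLELES = frozenset("ACGT")
AUTOSOMES = tuple(str(i) for i in range(1, 23))
CHROMOSOMES = AUTOSOMES + ("X", "Y", "MT")
_CHROM_ALIASES = {"23": "X", "24": "Y", "25": "MT", "26": "MT", "M": "MT"}

MISSING_MARKERS = {"--", "-", "00", "0", "", "NC"}

UNIQUE_ID_RE = re.compile(r"^id_[0-9a-z]{9}$")
_ID_ALPHABET = "0123456789abcdefghijklmnopqrstuvwxyz"


class VendorDialect(str, Enum):
    """Recognized raw-data dialects."""

    TWENTYTHREE_AND_ME = "TWENTYTHREE_AND_ME"
    ANCESTRY = "ANCESTRY"
    MYHERITAGE = "MYHERITAGE"
    GENERIC = "GENERIC"


@dataclass(frozen=True)
class VariantCall:
    """One biallelic genotype call on GRCh37.

    ``genotype`` is an unordered pair of allele symbols from {A,C,G,T},
    or ``None`` when the vendor reported a no-call.
    """

    rsid: str
    chromosome: str
    position: int
    genotype: Optional[tuple[str, str]]

    @property
    def is_missing(self) -> bool:
        return self.genotype is None

    @property
    def is_autosomal(self) -> bool:
        return self.chromosome in AUTOSOMES


@dataclass
class GenomeProfile:
    """A parsed, vendor-tagged genome with anonymous identity metadata."""

    unique_id: str
    source_digest: str
    vendor_dialect: VendorDialect
    calls: list[VariantCall]
    call_stats: dict = field(default_factory=dict)

    def by_rsid(self) -> dict[str, VariantCall]:
        return {c.rsid: c for c in self.calls}

    @property
    def n_calls(self) -> int:
        return len(self.calls)


def assign_unique_id(
    rng_seed: Optional[int] = None,
    existing: Optional[Iterable[str]] = None,
) -> str:
    """Draw a fresh anonymous identifier ``id_`` + 9 chars of [0-9a-z].

    Deterministic under a fixed seed; regenerates on collision with the
    supplied registry of existing identifiers.
    """
    rng = random.Random(rng_seed)
    taken = set(existing) if existing is not None else set()
    while True:
        token = "id_" + "".join(rng.choice(_ID_ALPHABET) for _ in range(9))
        if token not in taken:
            return token


def source_digest(raw_bytes: bytes) -> str:
    """md5 hex digest of the raw upload bytes; identical files → one user."""
    return hashlib.md5(raw_bytes).hexdigest()


# ---------------------------------------------------------------------------
# dialect detection
# ---------------------------------------------------------------------------

def _as_lines(raw_lines: Union[str, bytes, IO, Iterable[str]]) -> list[str]:
    if isinstance(raw_lines, bytes):
        raw_lines = raw_lines.decode("utf-8", errors="replace")
    if isinstance(raw_lines, str):
        return raw_lines.splitlines()
    if hasattr(raw_lines, "read"):
        return _as_lines(raw_lines.read())
    return [line.rstrip("\r\n") for line in raw_lines]


def detect_format(raw_lines: Union[str, bytes, IO, Iterable[str]]) -> VendorDialect:
    """Decide the vendor dialect from headers, delimiter and column count.

    Raises :class:`UnrecognizedFormat` when nothing matches — the <1%
    hard-failure path of real uploads.
    """
    lines = [ln for ln in _as_lines(raw_lines) if ln.strip()]
    if not lines:
        raise UnrecognizedFormat("empty input stream")

    comments = [ln for ln in lines if ln.lstrip().startswith("#")]
    data = [ln for ln in lines if not ln.lstrip().startswith("#")]

    for ln in comments:
        low = ln.lower()
        if "rsid" in low and "chromosome" in low and "genotype" in low:
            return VendorDialect.TWENTYTHREE_AND_ME

    if not data:
        raise UnrecognizedFormat("only comment lines found")
    head = data[0]

    if "," in head and "\t" not in head:
        try:
            row = next(csv.reader([head]))
        except csv.Error:
            row = []
        lowered = [f.strip().lower() for f in row]
        if len(row) == 4 and ('"' in head or "rsid" in lowered):
            return VendorDialect.MYHERITAGE
        raise UnrecognizedFormat("comma-separated input is not MyHeritage-shaped")

    fields = head.split("\t")
    if len(fields) == 5:
        return VendorDialect.ANCESTRY
    if len(fields) == 4:
        if comments:
            return VendorDialect.TWENTYTHREE_AND_ME
        return VendorDialect.GENERIC
    raise UnrecognizedFormat(
        f"unrecognized layout: {len(fields)} tab-separated columns"
    )


# ---------------------------------------------------------------------------
# parsing
# ---------------------------------------------------------------------------

def _norm_chrom(raw: str) -> Optional[str]:
    c = raw.strip().upper()
    if c.startswith("CHR"):
        c = c[3:]
    c = _CHROM_ALIASES.get(c, c)
    return c if c in CHROMOSOMES else None


def _parse_genotype(raw: str) -> tuple[Optional[tuple[str, str]], Optional[str]]:
    """Return (genotype, rejection_reason). A missing call is (None, None)."""
    g = raw.strip().upper()
    if g in MISSING_MARKERS:
        return None, None
    if any(ch in "ID" for ch in g):
        return None, "indel_code"
    if len(g) == 1 and g in ALLELES:
        # haploid call (X/Y/MT): stored as a homozygous pair, PLINK-style
        return (g, g), "haploid"
    if len(g) == 2 and g[0] in ALLELES and g[1] in ALLELES:
        return (g[0], g[1]), None
    return None, "bad_genotype"


def _parse_allele_pair(a1: str, a2: str) -> tuple[Optional[tuple[str, str]], Optional[str]]:
    a1, a2 = a1.strip().upper(), a2.strip().upper()
    if a1 in {"0", "-", ""} and a2 in {"0", "-", ""}:
        return None, None
    if any(a in "ID" for a in (a1, a2)):
        return None, "indel_code"
    if a1 in ALLELES and a2 in ALLELES:
        return (a1, a2), None
    return None, "bad_genotype"


_HEADER_WORDS = {"rsid", "chromosome", "position", "genotype", "allele1", "allele2",
                 "result", "chrom", "pos"}


def _looks_like_header(fields: Sequence[str]) -> bool:
    return any(f.strip().strip('"').lower() in _HEADER_WORDS for f in fields)


def read_profile(
    raw_lines: Union[str, bytes, IO, Iterable[str]],
    dialect: VendorDialect,
    *,
    unique_id: Optional[str] = None,
    digest: Optional[str] = None,
    rng_seed: Optional[int] = None,
) -> GenomeProfile:
    """Parse a raw stream of the given dialect into a :class:`GenomeProfile`.

    Well-formed data lines become one :class:`VariantCall` each; vendor
    no-call markers become missing genotypes; malformed lines are counted as
    rejected, never fatal. Duplicate rsids keep the first occurrence.
    """
    if isinstance(raw_lines, bytes) and digest is None:
        digest = source_digest(raw_lines)
    lines = _as_lines(raw_lines)

    calls: list[VariantCall] = []
    seen: set[str] = set()
    reasons: Counter = Counter()
    n_total = n_data = n_missing = n_rejected = 0

    for ln in lines:
        if not ln.strip():
            continue
        n_total += 1
        if ln.lstrip().startswith("#"):
            continue

        if dialect is VendorDialect.MYHERITAGE:
            try:
                fields = next(csv.reader([ln]))
            except csv.Error:
                fields = []
        else:
            fields = ln.split("\t")

        if dialect is VendorDialect.ANCESTRY:
            want = 5
        else:
            want = 4
        if len(fields) != want:
            n_rejected += 1
            reasons["bad_column_count"] += 1
            continue
        if _looks_like_header(fields):
            continue
        n_data += 1

        rsid = fields[0].strip().strip('"')
        chrom = _norm_chrom(fields[1].strip().strip('"'))
        pos_raw = fields[2].strip().strip('"')

        if dialect is VendorDialect.ANCESTRY:
            genotype, reason = _parse_allele_pair(fields[3], fields[4])
        else:
            genotype, reason = _parse_genotype(fields[3].strip().strip('"'))

        if not rsid:
            n_rejected += 1
            reasons["bad_rsid"] += 1
            continue
        if chrom is None:
            n_rejected += 1
            reasons["bad_chromosome"] += 1
            continue
        try:
            pos = int(pos_raw)
        except ValueError:
            pos = -1
        if pos < 1:
            n_rejected += 1
            reasons["bad_position"] += 1
            continue
        if reason in {"indel_code", "bad_genotype"}:
            n_rejected += 1
            reasons[reason] += 1
            continue
        if rsid in seen:
            n_rejected += 1
            reasons["duplicate_rsid"] += 1
            continue
        if reason == "haploid":
            reasons["haploid"] += 1

        seen.add(rsid)
        if genotype is None:
            n_missing += 1
        calls.append(VariantCall(rsid, chrom, pos, genotype))

    if not calls:
        raise EmptyProfile("no valid variant calls parsed")

    present = {c.chromosome for c in calls}
    absent = [a for a in AUTOSOMES if a not in present]
    if absent:
        warnings.warn(
            f"autosomes entirely absent from profile: {','.join(absent)}",
            MissingChromosomeWarning,
            stacklevel=2,
        )

    stats = {
        "total_lines": n_total,
        "data_lines": n_data,
        "parsed": len(calls),
        "missing": n_missing,
        "rejected": n_rejected,
        "rejected_reasons": dict(reasons),
        "non_autosomal": sum(1 for c in calls if not c.is_autosomal),
        "absent_autosomes": absent,
    }
    return GenomeProfile(
        unique_id=unique_id or assign_unique_id(rng_seed),
        source_digest=digest or "0" * 32,
        vendor_dialect=dialect,
        calls=calls,
        call_stats=stats,
    )


def read_profile_bytes(raw: bytes, **kwargs) -> GenomeProfile:
    """Detect the dialect and parse in one step (digest taken from the bytes)."""
    dialect = detect_format(raw)
    return read_profile(raw, dialect, digest=source_digest(raw), **kwargs)


# ---------------------------------------------------------------------------
# fixture writers — one per dialect, used by tests and `dtcprs simulate`
# ---------------------------------------------------------------------------

def _gt_string(call: VariantCall, missing: str = "--") -> str:
    if call.genotype is None:
        return missing
    return call.genotype[0] + call.genotype[1]


def write_23andme(calls: Iterable[VariantCall], out: Optional[IO[str]] = None) -> str:
    buf = out or io.StringIO()
    buf.write("# This data file generated by a consumer genotyping service.\n")
    buf.write("# rsid\tchromosome\tposition\tgenotype\n")
    for c in calls:
        buf.write(f"{c.rsid}\t{c.chromosome}\t{c.position}\t{_gt_string(c)}\n")
    return buf.getvalue() if out is None else ""


def write_ancestry(calls: Iterable[VariantCall], out: Optional[IO[str]] = None) -> str:
    buf = out or io.StringIO()
    buf.write("rsid\tchromosome\tposition\tallele1\tallele2\n")
    for c in calls:
        if c.genotype is None:
            a1 = a2 = "0"
        else:
            a1, a2 = c.genotype
        buf.write(f"{c.rsid}\t{c.chromosome}\t{c.position}\t{a1}\t{a2}\n")
    return buf.getvalue() if out is None else ""


def write_myheritage(calls: Iterable[VariantCall], out: Optional[IO[str]] = None) -> str:
    buf = out or io.StringIO()
    buf.write('RSID,CHROMOSOME,POSITION,RESULT\n')
    for c in calls:
        buf.write(f'"{c.rsid}","{c.chromosome}","{c.position}","{_gt_string(c)}"\n')
    return buf.getvalue() if out is None else ""


def write_generic(calls: Iterable[VariantCall], out: Optional[IO[str]] = None) -> str:
    buf = out or io.StringIO()
    for c in calls:
        buf.write(f"{c.rsid}\t{c.chromosome}\t{c.position}\t{_gt_string(c)}\n")
    return buf.getvalue() if out is None else ""


#: the three vendor dialects (what `dtcprs simulate` exports)
DIALECT_WRITERS = {
    VendorDialect.TWENTYTHREE_AND_ME: write_23andme,
    VendorDialect.ANCESTRY: write_ancestry,
    VendorDialect.MYHERITAGE: write_myheritage,
}

_ALL_WRITERS = {**DIALECT_WRITERS, VendorDialect.GENERIC: write_generic}


def write_fixture(calls: Iterable[VariantCall], dialect: VendorDialect) -> str:
    """Emit the call set in the given dialect (round-trip partner of read_profile)."""
    return _ALL_WRITERS[dialect](calls)


# ---------------------------------------------------------------------------
# VCF export
# ---------------------------------------------------------------------------

_CONTIG_ORDER = {c: i for i, c in enumerate(CHROMOSOMES)}


def write_vcf(aligned_profile, sites, out: Optional[IO[str]] = None) -> str:
    """Export an allele-aligned profile as single-sample VCFv4.2 text.

    ``aligned_profile`` must come from :func:`dtcprs.harmonize.align_profile`
    (GT is the aligned alt-allele dosage); passing a raw profile raises
    :class:`UnharmonizedProfile`. Sites absent from the reference panel are
    omitted; contigs are ordered 1..22, X, Y, MT.
    """
    from .errors import UnharmonizedProfile
    from .harmonize import AlignedProfile, ReferencePanelSite

    if isinstance(aligned_profile, GenomeProfile):
        raise UnharmonizedProfile(
            "write_vcf requires an AlignedProfile; run harmonize.align_profile first"
        )
    if not isinstance(aligned_profile, AlignedProfile):
        raise UnharmonizedProfile(f"unsupported profile type {type(aligned_profile)}")

    site_by_rsid: Mapping[str, ReferencePanelSite] = (
        sites if isinstance(sites, Mapping) else {s.rsid: s for s in sites}
    )

    records = []
    for rsid, dosage in aligned_profile.alt_dosage.items():
        site = site_by_rsid.get(rsid)
        if site is None:
            continue
        if dosage is None:
            gt = "./."
        else:
            gt = {0: "0/0", 1: "0/1", 2: "1/1"}[int(dosage)]
        records.append((_CONTIG_ORDER[site.chromosome], site.position, site, gt))
    records.sort(key=lambda r: (r[0], r[1]))

    buf = out or io.StringIO()
    buf.write("##fileformat=VCFv4.2\n")
    buf.write("##source=dtcprs\n")
    for c in CHROMOSOMES:
        buf.write(f"##contig=<ID={c}>\n")
    buf.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
    sample = aligned_profile.profile.unique_id
    buf.write(f"#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t{sample}\n")
    for _, _, site, gt in records:
        buf.write(
            f"{site.chromosome}\t{site.position}\t{site.rsid}\t{site.ref}\t"
            f"{site.alt}\t.\tPASS\t.\tGT\t{gt}\n"
        )
    return buf.getvalue() if out is None else ""
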