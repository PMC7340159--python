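"""Allele harmonization and quality control against a reference panel.

Consumer files report genotypes on arbitrary strands. Every call is aligned
to the reference panel's {ref, alt} pair, trying the reported alleles first
and their reverse complement second; strand-ambiguous site classes (A/T and
C/G, where the flip is undetectable) are dropped unconditionally. On top of
alignment this module carries the cohort-level QC gate — minor allele
frequency > 0.05, Hardy-Weinberg exact p > 1e-5, genotype yield > 0.95, and
an imputation INFO >= 0.9 when such a column exists — and turns an aligned
profile into an effect-allele dosage vector for a weight panel, with an
explicit policy for panel SNPs the vendor never typed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import DegenerateInput, IncompletePanel, UnknownPopulation
from .genotype_io import AUTOSOMES, GenomeProfile, VariantCall

POPULATIONS = ("AFR", "AMR", "EAS", "EUR", "SAS")

COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}


@dataclass(frozen=True)
class ReferencePanelSite:
    """A biallelic reference site with per-super-population alt frequencies."""

    rsid: str
    chromosome: str
    position: int
    ref: str
    alt: str
    alt_frequency: Mapping[str, float]

    def alt_freq(self, population: str) -> float:
        try:
            return self.alt_frequency[population]
        except KeyError:
            raise UnknownPopulation(population) from None


@dataclass(frozen=True)
class QCThresholds:
    """The pipeline's SNP QC gate; ``info_min`` applies only when an
    imputation-quality column is supplied."""

    maf_min: float = 0.05
    hwe_p_min: float = 1e-5
    yield_min: float = 0.95
    info_min: float = 0.9


class AlignmentStatus(str, Enum):
    OK = "OK"                      # alleles matched ref/alt (possibly flipped)
    MISSING = "MISSING"            # vendor no-call at an alignable site
    AMBIGUOUS = "AMBIGUOUS"        # A/T or C/G site class: strand undetectable
    UNMATCHED = "UNMATCHED"        # alleles match neither orientation
    POSITION_MISMATCH = "POSITION_MISMATCH"  # panel is the coordinate authority


@dataclass(frozen=True)
class AlleleAlignment:
    status: AlignmentStatus
    alt_dosage: Optional[int] = None
    flipped: bool = False

    @property
    def ok(self) -> bool:
        return self.status in (AlignmentStatus.OK, AlignmentStatus.MISSING)


def is_strand_ambiguous(ref: str, alt: str) -> bool:
    return COMPLEMENT.get(ref) == alt


def align_alleles(call: VariantCall, site: ReferencePanelSite) -> AlleleAlignment:
    """Match a call's alleles to a site's {ref, alt}, flipping strand if needed.

    Returns a categorized result rather than raising: rejections are carried
    as counts by :func:`align_profile`.
    """
    if is_strand_ambiguous(site.ref, site.alt):
        return AlleleAlignment(AlignmentStatus.AMBIGUOUS)
    if call.position != site.position or call.chromosome != site.chromosome:
        return AlleleAlignment(AlignmentStatus.POSITION_MISMATCH)
    if call.genotype is None:
        return AlleleAlignment(AlignmentStatus.MISSING)

    valid = {site.ref, site.alt}
    direct = set(call.genotype) <= valid
    if direct:
        dosage = sum(1 for a in call.genotype if a == site.alt)
        return AlleleAlignment(AlignmentStatus.OK, dosage, flipped=False)
    flipped = tuple(COMPLEMENT[a] for a in call.genotype)
    if set(flipped) <= valid:
        dosage = sum(1 for a in flipped if a == site.alt)
        return AlleleAlignment(AlignmentStatus.OK, dosage, flipped=True)
    return AlleleAlignment(AlignmentStatus.UNMATCHED)


@dataclass
class AlignedProfile:
    """A profile with per-rsid aligned alt dosages plus a rejection ledger."""

    profile: GenomeProfile
    alt_dosage: dict[str, Optional[int]]  # rsid -> 0/1/2, None = missing call
    rejections: dict[str, str] = field(default_factory=dict)  # rsid -> reason

    @property
    def n_aligned(self) -> int:
        return sum(1 for v in self.alt_dosage.values() if v is not None)


def align_profile(
    profile: GenomeProfile,
    sites: Union[Iterable[ReferencePanelSite], Mapping[str, ReferencePanelSite]],
) -> AlignedProfile:
    """Align every call that has a panel site; categorize the rest."""
    site_by_rsid = sites if isinstance(sites, Mapping) else {s.rsid: s for s in sites}
    dosage: dict[str, Optional[int]] = {}
    rejections: dict[str, str] = {}
    for call in profile.calls:
        site = site_by_rsid.get(call.rsid)
        if site is None:
            rejections[call.rsid] = "OFF_PANEL"
            continue
        res = align_alleles(call, site)
        if res.status is AlignmentStatus.OK:
            dosage[call.rsid] = res.alt_dosage
        elif res.status is AlignmentStatus.MISSING:
            dosage[call.rsid] = None
        else:
            rejections[call.rsid] = res.status.value
    return AlignedProfile(profile, dosage, rejections)


# ---------------------------------------------------------------------------
# Hardy-Weinberg exact test
# ---------------------------------------------------------------------------

def hwe_exact_p(n_AA: int, n_Aa: int, n_aa: int) -> float:
    """Two-sided exact Hardy-Weinberg p-value.

    Conditional on the observed allele counts, sums the probability of every
    heterozygote-count configuration whose probability does not exceed that
    of the observed table (the classic exact HWE test). Exact for any sample
    size; the enumeration is linear in n.
    """
    for k in (n_AA, n_Aa, n_aa):
        if k < 0 or k != int(k):
            raise DegenerateInput("genotype counts must be non-negative integers")
    n = n_AA + n_Aa + n_aa
    if n == 0:
        raise DegenerateInput("all three genotype counts are zero")

    nA = 2 * n_AA + n_Aa
    nB = 2 * n_aa + n_Aa
    rare = min(nA, nB)
    # heterozygote counts share the parity of the rare-allele count
    hets = range(rare % 2, rare + 1, 2)

    lg = math.lgamma
    const = lg(n + 1) + lg(nA + 1) + lg(nB + 1) - lg(2 * n + 1)

    def logp(h: int) -> float:
        a = (nA - h) // 2  # hom for the A allele
        b = (nB - h) // 2
        return const + h * math.log(2.0) - lg(a + 1) - lg(h + 1) - lg(b + 1)

    lp_obs = logp(n_Aa)
    total = 0.0
    for h in hets:
        lp = logp(h)
        if lp <= lp_obs + 1e-9:
            total += math.exp(lp)
    return min(total, 1.0)


# ---------------------------------------------------------------------------
# cohort QC gate
# ---------------------------------------------------------------------------

_QC_COLUMNS = ("rsid", "n_AA", "n_Aa", "n_aa")

#: called-sample floor below which cohort MAF estimates are not trusted
MAF_COHORT_MIN_N = 50


def apply_qc(
    site_counts: pd.DataFrame,
    thresholds: QCThresholds = QCThresholds(),
) -> tuple[list[str], pd.DataFrame]:
    """Apply the SNP QC gate to per-site genotype counts.

    ``site_counts`` needs columns rsid, n_AA, n_Aa, n_aa; optional columns
    n_missing (for yield), info (imputation quality) and panel_frequency
    (used for MAF when fewer than 50 samples are called). Returns the
    retained rsid list and an exclusion ledger recording the first failing
    criterion per excluded site, checked in the order MAF, HWE, YIELD, INFO.
    """
    missing_cols = [c for c in _QC_COLUMNS if c not in site_counts.columns]
    if missing_cols:
        raise ValueError(f"site_counts lacks columns {missing_cols}")
    if len(site_counts) == 0:
        raise DegenerateInput("apply_qc requires at least one site")

    retained: list[str] = []
    excluded: list[tuple[str, str]] = []
    has_info = "info" in site_counts.columns
    has_panel_f = "panel_frequency" in site_counts.columns

    for row in site_counts.itertuples(index=False):
        n_called = row.n_AA + row.n_Aa + row.n_aa
        n_missing = getattr(row, "n_missing", 0) or 0

        if n_called >= MAF_COHORT_MIN_N or not has_panel_f:
            f = (2 * row.n_aa + row.n_Aa) / (2 * n_called) if n_called else 0.0
        else:
            f = float(row.panel_frequency)
        maf = min(f, 1.0 - f)
        if not maf > thresholds.maf_min:
            excluded.append((row.rsid, "MAF"))
            continue

        if n_called == 0 or not hwe_exact_p(row.n_AA, row.n_Aa, row.n_aa) > thresholds.hwe_p_min:
            excluded.append((row.rsid, "HWE"))
            continue

        total = n_called + n_missing
        yld = n_called / total if total else 0.0
        if not yld > thresholds.yield_min:
            excluded.append((row.rsid, "YIELD"))
            continue

        if has_info:
            info = getattr(row, "info")
            if info is not None and not (isinstance(info, float) and math.isnan(info)):
                if not info >= thresholds.info_min:
                    excluded.append((row.rsid, "INFO"))
                    continue

        retained.append(row.rsid)

    ledger = pd.DataFrame(excluded, columns=["rsid", "reason"])
    return retained, ledger


# ---------------------------------------------------------------------------
# dosage extraction against a weight panel
# ---------------------------------------------------------------------------

class MissingPolicy(str, Enum):
    SKIP = "SKIP"                      # contribute nothing — naive raw scoring
    FREQUENCY_FILL = "FREQUENCY_FILL"  # dosage := 2f, stand-in for imputation
    FAIL = "FAIL"                      # any gap is an error


class Provenance:
    GENOTYPED = 0
    FREQUENCY_FILLED = 1
    MISSING = 2


@dataclass
class DosageVector:
    """Effect-allele counts aligned to a WeightPanel's SNP order.

    ``values`` holds 0/1/2 for genotyped SNPs, 2f for frequency-filled ones
    and NaN for missing ones; ``provenance`` tracks which is which.
    """

    values: np.ndarray
    provenance: np.ndarray
    rsids: tuple[str, ...]

    @property
    def n_genotyped(self) -> int:
        return int(np.sum(self.provenance == Provenance.GENOTYPED))

    @property
    def n_frequency_filled(self) -> int:
        return int(np.sum(self.provenance == Provenance.FREQUENCY_FILLED))

    @property
    def n_missing(self) -> int:
        return int(np.sum(self.provenance == Provenance.MISSING))


def dosage_against_panel(
    profile: Union[GenomeProfile, AlignedProfile],
    panel,
    sites: Union[Iterable[ReferencePanelSite], Mapping[str, ReferencePanelSite]],
    missing_policy: MissingPolicy = MissingPolicy.SKIP,
    population: str = "EUR",
) -> DosageVector:
    """Extract effect-allele dosages for every SNP of a weight panel.

    A panel SNP contributes a genotyped count when the profile carries an
    alignable autosomal call at a panel site whose {ref, alt} contains the
    weight's effect allele (directly or reverse-complemented); every other
    case is a gap handled per ``missing_policy``.
    """
    if isinstance(profile, GenomeProfile):
        profile = align_profile(profile, sites)
    site_by_rsid = sites if isinstance(sites, Mapping) else {s.rsid: s for s in sites}

    m = len(panel.weights)
    values = np.full(m, np.nan)
    prov = np.full(m, Provenance.MISSING, dtype=np.int8)

    for i, w in enumerate(panel.weights):
        dosage = _effect_dosage(profile, site_by_rsid.get(w.rsid), w)
        if dosage is not None:
            values[i] = dosage
            prov[i] = Provenance.GENOTYPED
            continue
        if missing_policy is MissingPolicy.FAIL:
            raise IncompletePanel(f"panel SNP {w.rsid} unavailable in profile")
        if missing_policy is MissingPolicy.FREQUENCY_FILL:
            f = w.effect_allele_frequency.get(population)
            if f is None:
                raise UnknownPopulation(population)
            values[i] = 2 * f
            prov[i] = Provenance.FREQUENCY_FILLED
        # SKIP: leave NaN / MISSING

    return DosageVector(values, prov, tuple(w.rsid for w in panel.weights))


def _effect_dosage(aligned: AlignedProfile, site: Optional[ReferencePanelSite], weight):
    if site is None or site.chromosome not in AUTOSOMES:
        return None
    alt_dosage = aligned.alt_dosage.get(weight.rsid)
    if alt_dosage is None:  # absent, rejected, or vendor no-call
        return None
    eff = weight.effect_allele
    for allele in (eff, COMPLEMENT.get(eff)):
        if allele == site.alt:
            return alt_dosage
        if allele == site.ref:
            return 2 - alt_dosage
    return None


# ---------------------------------------------------------------------------
# reference-site table I/O
# ---------------------------------------------------------------------------

def read_reference_sites(path_or_buf) -> list[ReferencePanelSite]:
    """Read a tab-delimited reference site table.

    Columns: rsid, chromosome, position, ref, alt, AFR, AMR, EAS, EUR, SAS
    (per-population alt-allele frequencies).
    """
    df = pd.read_csv(path_or_buf, sep="\t", dtype={"chromosome": str})
    return [
        ReferencePanelSite(
            rsid=row.rsid,
            chromosome=str(row.chromosome),
            position=int(row.position),
            ref=row.ref,
            alt=row.alt,
            alt_frequency={p: float(getattr(row, p)) for p in POPULATIONS},
        )
        for row in df.itertuples(index=False)
    ]


def write_reference_sites(sites: Sequence[ReferencePanelSite], path_or_buf) -> None:
    df = pd.DataFrame(
        [
            {
                "rsid": s.rsid,
                "chromosome": s.chromosome,
                "position": s.position,
                "ref": s.ref,
                "alt": s.alt,
                **{p: s.alt_frequency[p] for p in POPULATIONS},
            }
            for s in sites
        ]
    )
    df.to_csv(path_or_buf, sep="\t", index=False)
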