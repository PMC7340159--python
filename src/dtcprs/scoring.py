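"""Polygenic risk scores with frequency centering and population scaling.

The score for one trait is the weighted sum of effect-allele dosages. Three
related quantities are reported per profile:

* raw sum               ``S = Σ β_j · x_j``  over attained SNPs
* zero-centered score   ``Σ β_j · x_j − 2 f_j β_j``  (per-SNP expectation
  removed, so a population member averages 0)
* Z-score               zero-centered score divided by the population
  standard deviation of the score.

The analytic denominator ``sqrt(Σ β² · 2f(1−f))`` is the score SD under
Hardy-Weinberg and linkage equilibrium — exact for LD-clumped top-SNP
panels. Empirical scaling against an ancestry-matched reference cohort is
available as an alternative, the analog of normalizing against previous
users of matching ethnicity.

Frequencies come per 1000 Genomes super-population (AFR, AMR, EAS, EUR,
SAS), so a profile is always centered and scaled against its own ancestry
group. Panels come in two modes: TOP_SNP (genome-wide-significant,
LD-clumped variants, p < 5e-8) and ALL_SNP (externally shrunk genome-wide
weights, e.g. LDpred output, supplied as input).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from enum import Enum
from typing import Iterable, Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .errors import (
    EmptyOverlapWarning,
    InsufficientReference,
    UnknownPopulation,
    ZeroVariancePanel,
)
from .harmonize import (
    AlignedProfile,
    DosageVector,
    MissingPolicy,
    Provenance,
    dosage_against_panel,
)

POPULATIONS = ("AFR", "AMR", "EAS", "EUR", "SAS")

#: minimum ancestry-matched cohort size for empirical normalization
MIN_EMPIRICAL_REFERENCE = 30


class ScoreMode(str, Enum):
    TOP_SNP = "TOP_SNP"
    ALL_SNP = "ALL_SNP"


class ScalingMode(str, Enum):
    ANALYTIC_1KG = "ANALYTIC_1KG"
    EMPIRICAL = "EMPIRICAL"


@dataclass(frozen=True)
class ScoreWeight:
    """One SNP of a scoring model: effect allele, β, per-population frequency."""

    rsid: str
    effect_allele: str
    other_allele: str
    beta: float
    effect_allele_frequency: Mapping[str, float]


@dataclass
class WeightPanel:
    """A trait's scoring model: ordered weights plus mode and provenance."""

    trait_id: str
    mode: ScoreMode
    weights: tuple[ScoreWeight, ...]
    provenance: str = ""

    def __post_init__(self):
        self.weights = tuple(self.weights)
        rsids = [w.rsid for w in self.weights]
        if len(set(rsids)) != len(rsids):
            raise ValueError(f"panel {self.trait_id} has duplicate rsids")

    @property
    def rsids(self) -> tuple[str, ...]:
        return tuple(w.rsid for w in self.weights)

    @property
    def betas(self) -> np.ndarray:
        return np.array([w.beta for w in self.weights])

    def frequencies(self, population: str) -> np.ndarray:
        try:
            return np.array(
                [w.effect_allele_frequency[population] for w in self.weights]
            )
        except KeyError:
            raise UnknownPopulation(population) from None

    def __len__(self) -> int:
        return len(self.weights)


@dataclass
class PRSResult:
    """One trait × one profile, with coverage accounting."""

    trait_id: str
    raw_sum: float
    zero_centered: float
    z_score: float
    population: str
    scaling: ScalingMode
    n_used: int
    n_frequency_filled: int
    n_missing: int
    warnings: list[str] = field(default_factory=list)


# ---------------------------------------------------------------------------
# the three score equations
# ---------------------------------------------------------------------------

def population_score(weight: ScoreWeight, population: str) -> float:
    """Expected per-SNP contribution for a population member: f × 2 × β."""
    try:
        f = weight.effect_allele_frequency[population]
    except KeyError:
        raise UnknownPopulation(population) from None
    return f * 2 * weight.beta


def _contributions(
    dosages: DosageVector, panel: WeightPanel, population: str
) -> np.ndarray:
    """Per-SNP centered contributions β·x − f·2·β, 0.0 where missing.

    A frequency-filled SNP contributes ``β·(2f) − f·2·β`` which is exactly
    0.0 in floating point, making FREQUENCY_FILL and SKIP bit-identical for
    the centered score.
    """
    out = np.empty(len(panel.weights))
    for i, w in enumerate(panel.weights):
        x = dosages.values[i]
        if np.isnan(x):
            out[i] = 0.0
        else:
            out[i] = w.beta * x - population_score(w, population)
    return out


def zero_centered_score(
    dosages: DosageVector, panel: WeightPanel, population: str
) -> float:
    """Σ over non-missing SNPs of β × dosage − population score.

    Missing SNPs contribute 0; if *every* SNP is missing a warning is issued
    and the placeholder 0.0 is returned (it is not an informative score).
    """
    if int(np.sum(np.isnan(dosages.values))) == len(panel.weights):
        warnings.warn(
            f"no panel SNP attained for trait {panel.trait_id}; score is not informative",
            EmptyOverlapWarning,
            stacklevel=2,
        )
        return 0.0
    contrib = _contributions(dosages, panel, population)
    return float(np.sum(contrib))


def population_sd(panel: WeightPanel, population: str) -> float:
    """Analytic score SD under HWE and linkage equilibrium:
    sqrt(Σ β² · 2f(1−f))."""
    f = panel.frequencies(population)
    b = panel.betas
    var = float(np.sum(b * b * 2.0 * f * (1.0 - f)))
    if var <= 0.0:
        raise ZeroVariancePanel(
            f"panel {panel.trait_id} has zero score variance in {population}"
        )
    return float(np.sqrt(var))


def z_score(zero_centered: float, sd: float) -> float:
    """Zero-centered score divided by the population SD; no truncation."""
    if not sd > 0:
        raise ZeroVariancePanel("population SD must be positive")
    return zero_centered / sd


def empirical_normalize(
    score: float,
    reference_scores: Sequence[float],
    min_reference: int = MIN_EMPIRICAL_REFERENCE,
) -> float:
    """Standardize against prior scores from ancestry-matched profiles."""
    ref = np.asarray(reference_scores, dtype=float)
    if ref.size < min_reference:
        raise InsufficientReference(
            f"need >= {min_reference} reference scores, got {ref.size}"
        )
    sd = float(np.std(ref, ddof=1))
    if not sd > 0:
        raise ZeroVariancePanel("reference scores have zero variance")
    return (score - float(np.mean(ref))) / sd


def score_profile(
    profile: Union[AlignedProfile, DosageVector, "GenomeProfile"],
    panel: WeightPanel,
    population: str = "EUR",
    missing_policy: MissingPolicy = MissingPolicy.SKIP,
    scaling: ScalingMode = ScalingMode.ANALYTIC_1KG,
    sites=None,
    reference_scores: Optional[Sequence[float]] = None,
) -> PRSResult:
    """Full per-trait pipeline: dosages → centered score → Z.

    Accepts a pre-computed :class:`DosageVector`, or a (raw or aligned)
    profile together with reference ``sites``.
    """
    if isinstance(profile, DosageVector):
        dosages = profile
    else:
        if sites is None:
            raise ValueError("scoring a profile requires reference sites")
        dosages = dosage_against_panel(
            profile, panel, sites, missing_policy, population
        )

    notes: list[str] = []
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always", EmptyOverlapWarning)
        centered = zero_centered_score(dosages, panel, population)
    for w in caught:
        notes.append(str(w.message))

    attained = ~np.isnan(dosages.values)
    raw = float(np.sum(panel.betas[attained] * dosages.values[attained]))

    if scaling is ScalingMode.EMPIRICAL:
        if reference_scores is None:
            raise InsufficientReference(
                "EMPIRICAL scaling requires reference_scores"
            )
        z = empirical_normalize(centered, reference_scores)
    else:
        z = z_score(centered, population_sd(panel, population))

    return PRSResult(
        trait_id=panel.trait_id,
        raw_sum=raw,
        zero_centered=centered,
        z_score=z,
        population=population,
        scaling=scaling,
        n_used=dosages.n_genotyped,
        n_frequency_filled=dosages.n_frequency_filled,
        n_missing=dosages.n_missing,
        warnings=notes,
    )


# ---------------------------------------------------------------------------
# vectorized cohort scoring (used by the simulation experiment)
# ---------------------------------------------------------------------------

def cohort_zero_centered(
    dosage_matrix: np.ndarray, panel: WeightPanel, population: str
) -> np.ndarray:
    """Zero-centered scores for an (individuals × SNPs) dosage matrix.

    NaN entries are missing SNPs and contribute 0 (SKIP semantics).
    """
    b = panel.betas
    f = panel.frequencies(population)
    contrib = dosage_matrix * b - 2.0 * f * b
    return np.nansum(contrib, axis=1)


def cohort_raw_scores(dosage_matrix: np.ndarray, panel: WeightPanel) -> np.ndarray:
    """Naive un-centered weighted sums Σ β·x over attained SNPs.

    This is what raw-data scoring without population centering computes; its
    mean depends on *which* SNPs each individual attained, which is exactly
    the mechanism that breaks ranking across mixed vendor SNP sets.
    """
    return np.nansum(dosage_matrix * panel.betas, axis=1)


# ---------------------------------------------------------------------------
# single-variant carrier reports
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class RiskVariant:
    rsid: str
    risk_allele: str
    magnitude: float


@dataclass
class CarrierReport:
    carrier: bool
    hits: list[str]          # rsids with >= 1 risk allele present
    n_considered: int        # variants passing the magnitude filter


def carrier_report(
    profile,
    risk_variants: Sequence[RiskVariant],
    magnitude_min: float = 1.5,
) -> CarrierReport:
    """SNPedia-style presence/absence report: does the profile carry at
    least one risk allele among variants above the magnitude threshold?

    Missing genotypes count as non-carrier for that variant.
    """
    if not risk_variants:
        raise ValueError("risk variant list is empty")
    considered = [v for v in risk_variants if v.magnitude > magnitude_min]
    calls = profile.by_rsid() if hasattr(profile, "by_rsid") else profile
    hits = []
    for v in considered:
        call = calls.get(v.rsid)
        genotype = getattr(call, "genotype", call)
        if genotype and v.risk_allele in genotype:
            hits.append(v.rsid)
    return CarrierReport(carrier=bool(hits), hits=hits, n_considered=len(considered))


def read_risk_variants(path_or_buf) -> list[RiskVariant]:
    """Tab-delimited risk-variant list: rsid, risk_allele, magnitude."""
    df = pd.read_csv(path_or_buf, sep="\t")
    return [
        RiskVariant(r.rsid, r.risk_allele, float(r.magnitude))
        for r in df.itertuples(index=False)
    ]


# ---------------------------------------------------------------------------
# weight-panel file I/O
# ---------------------------------------------------------------------------

def read_weight_panel(path_or_buf) -> WeightPanel:
    """Read a tab-delimited weight panel.

    Leading ``#key=value`` lines carry trait_id, mode and provenance;
    columns: rsid, effect_allele, other_allele, beta, freq_AFR .. freq_SAS.
    """
    if hasattr(path_or_buf, "read"):
        text = path_or_buf.read()
    else:
        with open(path_or_buf) as fh:
            text = fh.read()
    meta: dict[str, str] = {}
    body_lines = []
    for line in text.splitlines():
        if line.startswith("#") and "=" in line:
            key, _, value = line.lstrip("#").partition("=")
            meta[key.strip()] = value.strip()
        elif line.strip():
            body_lines.append(line)
    import io as _io

    df = pd.read_csv(_io.StringIO("\n".join(body_lines)), sep="\t")
    weights = tuple(
        ScoreWeight(
            rsid=r.rsid,
            effect_allele=r.effect_allele,
            other_allele=r.other_allele,
            beta=float(r.beta),
            effect_allele_frequency={
                p: float(getattr(r, f"freq_{p}")) for p in POPULATIONS
            },
        )
        for r in df.itertuples(index=False)
    )
    return WeightPanel(
        trait_id=meta.get("trait_id", "unknown_trait"),
        mode=ScoreMode(meta.get("mode", "TOP_SNP")),
        weights=weights,
        provenance=meta.get("provenance", ""),
    )


def write_weight_panel(panel: WeightPanel, path_or_buf) -> None:
    rows = [
        {
            "rsid": w.rsid,
            "effect_allele": w.effect_allele,
            "other_allele": w.other_allele,
            "beta": w.beta,
            **{f"freq_{p}": w.effect_allele_frequency[p] for p in POPULATIONS},
        }
        for w in panel.weights
    ]
    header = (
        f"#trait_id={panel.trait_id}\n#mode={panel.mode.value}\n"
        f"#provenance={panel.provenance}\n"
    )
    body = pd.DataFrame(rows).to_csv(sep="\t", index=False)
    if hasattr(path_or_buf, "write"):
        path_or_buf.write(header + body)
    else:
        with open(path_or_buf, "w") as fh:
            fh.write(header + body)
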