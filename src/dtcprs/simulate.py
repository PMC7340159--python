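"""Synthetic cohorts, vendor SNP-set masks, and the uniform/mixed experiment.

The restricted case/control cohort the scoring pipeline was originally
validated on cannot be shipped, so this module generates structural
analogs: weight panels with Normal(0, β_sd²) effects, cohorts of
Binomial(2, f) genotypes in linkage equilibrium, and a liability-threshold
phenotype — disease status is liability > Φ⁻¹(1−K), where liability is the
standardized genetic score scaled to contribute h² of the variance plus
Normal residual noise.

Vendor chips are emulated as random subsets of the panel (real chip
manifests are proprietary); an optional shared backbone models the large
common content real arrays have. The experiment driver reproduces the
uniform-versus-mixed vendor comparison: predictive strength is measured on
complete data, on each vendor's SNP set alone (every sample shares the
mask), and on per-sample vendor mixtures drawn at the live-user
proportions 55/30/15 — the condition under which un-imputed, un-normalized
scoring collapses.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .errors import EmptyMask, ZeroVariancePanel
from .evaluation import auc as _auc
from .evaluation import nagelkerke_r2 as _nagelkerke
from .scoring import (
    POPULATIONS,
    ScoreMode,
    ScoreWeight,
    WeightPanel,
    cohort_raw_scores,
    cohort_zero_centered,
    population_sd,
)
from .harmonize import ReferencePanelSite

#: observed live-user shares of 23andMe / Ancestry / MyHeritage uploads
DEFAULT_MIX_PROPORTIONS = (0.55, 0.30, 0.15)

DEFAULT_FREQ_RANGE = (0.05, 0.95)


@dataclass
class SimConfig:
    """Conditions of one simulated cohort. ``seed`` is mandatory."""

    n_individuals: int
    n_snps: int
    h2: float                      # liability-scale SNP heritability
    prevalence: float              # K, case fraction of the population
    seed: int
    population: str = "EUR"
    freq_range: tuple[float, float] = DEFAULT_FREQ_RANGE

    def __post_init__(self):
        if not 0.0 <= self.h2 <= 1.0:
            raise ValueError("h2 must lie in [0, 1]")
        if not 0.0 < self.prevalence < 1.0:
            raise ValueError("prevalence must lie in (0, 1)")
        if self.seed is None:
            raise ValueError("a seed is mandatory")


@dataclass
class VendorMask:
    """A vendor's genotyped subset of a panel's SNP ids."""

    name: str
    snp_ids: frozenset[str]

    def __post_init__(self):
        self.snp_ids = frozenset(self.snp_ids)


@dataclass
class SyntheticCohort:
    """Dosage matrix with liability-threshold phenotype.

    ``dosages`` is individuals × SNPs with values 0/1/2 (float NaN marks
    masked-out SNPs in derived views).
    """

    dosages: np.ndarray
    liability: np.ndarray
    phenotype: np.ndarray
    population: str
    panel: WeightPanel
    config: Optional[SimConfig] = None

    @property
    def n(self) -> int:
        return self.dosages.shape[0]


def simulate_weights(
    n_snps: int,
    beta_sd: float = 0.1,
    freq_range: tuple[float, float] = DEFAULT_FREQ_RANGE,
    seed: int = 0,
    trait_id: str = "sim_trait",
    mode: ScoreMode = ScoreMode.TOP_SNP,
    population_divergence: float = 0.0,
) -> WeightPanel:
    """Draw a synthetic weight panel.

    Frequencies are uniform on ``freq_range`` and copied to all five
    super-populations; ``population_divergence`` > 0 instead jitters each
    population's frequency on the logit scale by that SD.
    """
    if n_snps < 1:
        raise ValueError("n_snps must be >= 1")
    rng = np.random.default_rng(seed)
    lo, hi = freq_range
    base = rng.uniform(lo, hi, size=n_snps)
    betas = rng.normal(0.0, beta_sd, size=n_snps)
    weights = []
    for j in range(n_snps):
        if population_divergence > 0:
            logit = np.log(base[j] / (1 - base[j]))
            freqs = {}
            for p in POPULATIONS:
                lj = logit + rng.normal(0.0, population_divergence)
                freqs[p] = float(np.clip(1 / (1 + np.exp(-lj)), lo, hi))
        else:
            freqs = {p: float(base[j]) for p in POPULATIONS}
        weights.append(
            ScoreWeight(
                rsid=f"rs{j + 1}",
                effect_allele="A",
                other_allele="G",
                beta=float(betas[j]),
                effect_allele_frequency=freqs,
            )
        )
    return WeightPanel(
        trait_id=trait_id,
        mode=mode,
        weights=tuple(weights),
        provenance=f"simulated beta_sd={beta_sd} seed={seed}",
    )


def simulate_reference_sites(
    n_sites: int,
    seed: int = 0,
    divergence: float = 0.0,
    freq_range: tuple[float, float] = DEFAULT_FREQ_RANGE,
) -> list[ReferencePanelSite]:
    """Synthetic reference panel sites (A/G, never strand-ambiguous).

    ``divergence`` is the per-population logit-scale frequency jitter SD;
    0 makes all populations identical.
    """
    rng = np.random.default_rng(seed)
    lo, hi = freq_range
    base = rng.uniform(lo, hi, size=n_sites)
    sites = []
    for j in range(n_sites):
        if divergence > 0:
            logit = np.log(base[j] / (1 - base[j]))
            freqs = {
                p: float(
                    np.clip(
                        1 / (1 + np.exp(-(logit + rng.normal(0.0, divergence)))),
                        lo,
                        hi,
                    )
                )
                for p in POPULATIONS
            }
        else:
            freqs = {p: float(base[j]) for p in POPULATIONS}
        chrom = str(j % 22 + 1)
        sites.append(
            ReferencePanelSite(
                rsid=f"rs{j + 1}",
                chromosome=chrom,
                position=10_000 + j * 100,
                ref="G",
                alt="A",
                alt_frequency=freqs,
            )
        )
    return sites


def simulate_cohort(config: SimConfig, panel: WeightPanel) -> SyntheticCohort:
    """Draw genotypes and a liability-threshold phenotype from a panel.

    Dosages are Binomial(2, f) per SNP (linkage equilibrium); the genetic
    value is the zero-centered score, scaled so its variance equals h²;
    residual liability noise is Normal(0, 1−h²); case iff liability exceeds
    Φ⁻¹(1−K).
    """
    if len(panel) != config.n_snps:
        raise ValueError("panel size must equal config.n_snps")
    rng = np.random.default_rng(config.seed)
    f = panel.frequencies(config.population)
    dosages = rng.binomial(2, f, size=(config.n_individuals, config.n_snps))

    g = cohort_zero_centered(dosages.astype(float), panel, config.population)
    if config.h2 > 0:
        sd_g = population_sd(panel, config.population)  # ZeroVariancePanel if 0
        a = np.sqrt(config.h2) / sd_g
    else:
        a = 0.0
    e = rng.normal(0.0, np.sqrt(1.0 - config.h2), size=config.n_individuals)
    liability = a * g + e
    threshold = stats.norm.ppf(1.0 - config.prevalence)
    phenotype = (liability > threshold).astype(np.int8)
    return SyntheticCohort(
        dosages=dosages,
        liability=liability,
        phenotype=phenotype,
        population=config.population,
        panel=panel,
        config=config,
    )


# ---------------------------------------------------------------------------
# vendor masks
# ---------------------------------------------------------------------------

def make_vendor_masks(
    snp_ids: Sequence[str],
    n_vendors: int = 3,
    coverage: float = 0.5,
    seed: int = 0,
    shared_backbone: float = 0.0,
    names: Optional[Sequence[str]] = None,
) -> list[VendorMask]:
    """Draw vendor masks as random panel subsets.

    Each vendor covers ``coverage`` of the panel. ``shared_backbone`` is the
    panel fraction every vendor genotypes in common (real arrays share most
    GWAS content); the remainder of each vendor's coverage is drawn
    independently from the non-backbone SNPs.
    """
    if not 0.0 <= shared_backbone <= coverage <= 1.0:
        raise ValueError("need 0 <= shared_backbone <= coverage <= 1")
    rng = np.random.default_rng(seed)
    ids = np.asarray(snp_ids)
    m = ids.size
    backbone_n = int(round(shared_backbone * m))
    perm = rng.permutation(m)
    backbone = set(ids[perm[:backbone_n]])
    rest = ids[perm[backbone_n:]]
    extra_rate = (
        (coverage - shared_backbone) / (1.0 - shared_backbone)
        if shared_backbone < 1.0
        else 0.0
    )
    extra_n = int(round(extra_rate * rest.size))
    if names is None:
        names = [f"vendor_{chr(ord('A') + i)}" for i in range(n_vendors)]
    masks = []
    for name in names[:n_vendors]:
        chosen = rng.permutation(rest.size)[:extra_n]
        masks.append(VendorMask(name, backbone | set(rest[chosen])))
    return masks


def apply_vendor_mask(cohort: SyntheticCohort, mask: VendorMask) -> SyntheticCohort:
    """Cohort view with off-mask SNPs set missing (NaN) for every individual."""
    panel_ids = cohort.panel.rsids
    keep = np.array([rsid in mask.snp_ids for rsid in panel_ids])
    if not keep.any():
        raise EmptyMask(f"mask {mask.name} covers no panel SNP")
    dosages = cohort.dosages.astype(float).copy()
    dosages[:, ~keep] = np.nan
    return SyntheticCohort(
        dosages=dosages,
        liability=cohort.liability,
        phenotype=cohort.phenotype,
        population=cohort.population,
        panel=cohort.panel,
        config=cohort.config,
    )


def draw_mixed_masks(
    masks: Sequence[VendorMask],
    proportions: Sequence[float] = DEFAULT_MIX_PROPORTIONS,
    n_individuals: int = 0,
    seed: int = 0,
) -> np.ndarray:
    """Independently assign each individual a vendor index ~ proportions."""
    props = np.asarray(proportions, dtype=float)
    if len(props) != len(masks):
        raise ValueError("need one proportion per mask")
    if not np.isclose(props.sum(), 1.0):
        raise ValueError("proportions must sum to 1")
    rng = np.random.default_rng(seed)
    return rng.choice(len(masks), size=n_individuals, p=props)


# ---------------------------------------------------------------------------
# the uniform / mixed SNP-set experiment
# ---------------------------------------------------------------------------

@dataclass
class ExperimentResult:
    """Condition table of the uniform/mixed experiment."""

    table: pd.DataFrame  # condition, auc, auc_sd, r2, r2_sd, n_snps

    def value(self, condition: str, metric: str) -> float:
        row = self.table[self.table.condition == condition]
        return float(row[metric].iloc[0])

    @property
    def auc_full(self) -> float:
        return self.value("FULL", "auc")

    @property
    def auc_uniform(self) -> float:
        sel = self.table.condition.str.startswith("UNIFORM")
        return float(self.table.loc[sel, "auc"].mean())

    @property
    def auc_mixed(self) -> float:
        return self.value("MIXED", "auc")


def run_snpset_experiment(
    cohort: SyntheticCohort,
    panel: WeightPanel,
    masks: Sequence[VendorMask],
    n_draws: int = 100,
    seed: int = 0,
    proportions: Sequence[float] = DEFAULT_MIX_PROPORTIONS,
) -> ExperimentResult:
    """Predictive strength under FULL / UNIFORM / MIXED SNP-set conditions.

    FULL scores complete dosages. UNIFORM scores each vendor's mask applied
    to every individual (three rows). MIXED redraws a per-individual vendor
    assignment ``n_draws`` times and reports mean ± SD. Masked conditions
    use the naive un-centered sum over attained SNPs with no
    renormalization — the same panel but different attained SNP sets, which
    is precisely what un-imputed uploads look like. AUC and Nagelkerke R²
    are invariant to the shared constant separating the naive and centered
    scores, so the FULL row is unaffected by this choice.
    """
    y = cohort.phenotype
    rows = []

    full_scores = cohort_raw_scores(cohort.dosages.astype(float), panel)
    rows.append(
        {
            "condition": "FULL",
            "auc": _auc(full_scores, y),
            "auc_sd": 0.0,
            "r2": _nagelkerke(full_scores, y),
            "r2_sd": 0.0,
            "n_snps": len(panel),
        }
    )

    uniform_scores = np.empty((len(masks), cohort.n))
    for k, mask in enumerate(masks):
        masked = apply_vendor_mask(cohort, mask)
        uniform_scores[k] = cohort_raw_scores(masked.dosages, panel)
        rows.append(
            {
                "condition": f"UNIFORM_{mask.name}",
                "auc": _auc(uniform_scores[k], y),
                "auc_sd": 0.0,
                "r2": _nagelkerke(uniform_scores[k], y),
                "r2_sd": 0.0,
                "n_snps": len(mask.snp_ids & set(panel.rsids)),
            }
        )

    # an individual assigned vendor v scores exactly as under uniform-v,
    # so each mixed draw is an indexed mixture of the uniform score vectors
    aucs = np.empty(n_draws)
    r2s = np.empty(n_draws)
    rng = np.random.default_rng(seed)
    for d in range(n_draws):
        assign = draw_mixed_masks(
            masks, proportions, cohort.n, seed=int(rng.integers(2**31))
        )
        mixed = uniform_scores[assign, np.arange(cohort.n)]
        aucs[d] = _auc(mixed, y)
        r2s[d] = _nagelkerke(mixed, y)
    rows.append(
        {
            "condition": "MIXED",
            "auc": float(aucs.mean()),
            "auc_sd": float(aucs.std(ddof=1)),
            "r2": float(r2s.mean()),
            "r2_sd": float(r2s.std(ddof=1)),
            "n_snps": len(panel),
        }
    )
    return ExperimentResult(pd.DataFrame(rows))


# ---------------------------------------------------------------------------
# cohort export through the vendor dialects (end-to-end fixture path)
# ---------------------------------------------------------------------------

def cohort_to_calls(cohort: SyntheticCohort, individual: int, sites=None):
    """One individual's dosage row as VariantCalls (effect/other alleles)."""
    from .genotype_io import VariantCall

    calls = []
    for j, w in enumerate(cohort.panel.weights):
        d = cohort.dosages[individual, j]
        if np.isnan(d):
            genotype = None
        else:
            d = int(d)
            genotype = tuple(
                [w.effect_allele] * d + [w.other_allele] * (2 - d)
            )
        if sites is not None:
            site = sites[j]
            chrom, pos = site.chromosome, site.position
        else:
            chrom, pos = str(j % 22 + 1), 10_000 + j * 100
        calls.append(VariantCall(w.rsid, chrom, pos, genotype))
    return calls
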