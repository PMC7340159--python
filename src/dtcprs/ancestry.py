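"""Super-population assignment from genotype dosages.

The scaling population for PRS normalization is chosen by a naive-Bayes
classifier: for each 1000 Genomes super-population, sum the Hardy-Weinberg
genotype log-likelihoods log P(g | f_pop) over the profile's non-missing
autosomal reference sites and take the argmax. This needs nothing beyond
the reference panel's per-population frequencies — no external PC loadings —
and is fully testable on synthetic frequency tables. Ties break
deterministically in the fixed order AFR, AMR, EAS, EUR, SAS.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping, Sequence, Union

import numpy as np

from .errors import InsufficientSites
from .genotype_io import AUTOSOMES
from .harmonize import ReferencePanelSite

POPULATIONS = ("AFR", "AMR", "EAS", "EUR", "SAS")

#: frequency clamp keeping fixed alleles from producing -inf log-likelihoods
FREQ_EPS = 1e-4

#: minimum number of informative sites for an assignment
MIN_SITES = 100


@dataclass
class AncestryCall:
    """An assigned super-population with its evidence."""

    label: str
    avg_loglik: dict[str, float]  # per-population average log-likelihood
    margin: float                 # best minus second-best average log-likelihood
    n_sites: int

    def report_line(self) -> str:
        return f"{self.label}\tmargin={self.margin:.6g}\tn_sites={self.n_sites}"


def _genotype_loglik(dosage: np.ndarray, f: np.ndarray) -> float:
    """Sum of log P(g | f) under HWE for integral dosages 0/1/2."""
    f = np.clip(f, FREQ_EPS, 1.0 - FREQ_EPS)
    p0 = (1.0 - f) ** 2
    p1 = 2.0 * f * (1.0 - f)
    p2 = f ** 2
    probs = np.where(dosage == 0, p0, np.where(dosage == 1, p1, p2))
    return float(np.sum(np.log(probs)))


def assign_population(
    dosages: Union[np.ndarray, Mapping[str, float]],
    sites: Sequence[ReferencePanelSite],
    min_sites: int = MIN_SITES,
) -> AncestryCall:
    """Assign the maximum-likelihood super-population.

    ``dosages`` is either an array of alt-allele counts aligned to ``sites``
    (NaN = missing) or a mapping rsid → count. Only autosomal sites with an
    integral non-missing dosage are informative.
    """
    sites = list(sites)
    if isinstance(dosages, Mapping):
        arr = np.array(
            [dosages.get(s.rsid, np.nan) for s in sites], dtype=float
        )
    else:
        arr = np.asarray(dosages, dtype=float)
        if arr.shape[0] != len(sites):
            raise ValueError("dosage vector length must match the site list")

    autosomal = np.array([s.chromosome in AUTOSOMES for s in sites])
    usable = autosomal & ~np.isnan(arr) & (arr == np.round(arr))
    n = int(np.sum(usable))
    if n < min_sites:
        raise InsufficientSites(
            f"ancestry assignment needs >= {min_sites} non-missing autosomal "
            f"sites, got {n}"
        )

    d = arr[usable]
    freq = {
        pop: np.array([s.alt_frequency[pop] for s, u in zip(sites, usable) if u])
        for pop in POPULATIONS
    }
    avg = {pop: _genotype_loglik(d, freq[pop]) / n for pop in POPULATIONS}

    # argmax with deterministic tie-break in POPULATIONS order
    label = max(POPULATIONS, key=lambda p: (avg[p], -POPULATIONS.index(p)))
    runner_up = max(
        (avg[p] for p in POPULATIONS if p != label), default=float("-inf")
    )
    return AncestryCall(
        label=label,
        avg_loglik=avg,
        margin=avg[label] - runner_up,
        n_sites=n,
    )
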