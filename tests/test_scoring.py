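"""The score equations, population scaling, and carrier reports."""

import itertools
from fractions import Fraction

import numpy as np
import pytest

from dtcprs.errors import (
    EmptyOverlapWarning,
    InsufficientReference,
    UnknownPopulation,
    ZeroVariancePanel,
)
from dtcprs.harmonize import DosageVector, MissingPolicy, Provenance
from dtcprs.scoring import (
    CarrierReport,
    RiskVariant,
    ScoreMode,
    ScoreWeight,
    WeightPanel,
    carrier_report,
    empirical_normalize,
    population_score,
    population_sd,
    score_profile,
    z_score,
    zero_centered_score,
)

from conftest import FIVE_SNP_SPEC, uniform_freqs


def make_panel(betas, freqs, trait="t"):
    weights = tuple(
        ScoreWeight(f"rs{i+1}", "A", "G", b, uniform_freqs(f))
        for i, (b, f) in enumerate(zip(betas, freqs))
    )
    return WeightPanel(trait, ScoreMode.TOP_SNP, weights)


def vector(values, panel):
    values = np.asarray(values, dtype=float)
    prov = np.where(np.isnan(values), Provenance.MISSING, Provenance.GENOTYPED)
    return DosageVector(values, prov.astype(np.int8), panel.rsids)


class TestPopulationScore:
    @pytest.mark.parametrize(
        "f,beta,expected", [(0.5, 0.2, 0.2), (0.0, 1.3, 0.0), (0.25, -0.4, -0.2)]
    )
    def test_frequency_times_two_beta(self, f, beta, expected):
        w = ScoreWeight("rs1", "A", "G", beta, uniform_freqs(f))
        assert population_score(w, "EUR") == pytest.approx(expected)

    def test_unknown_population(self):
        w = ScoreWeight("rs1", "A", "G", 0.1, {"EUR": 0.5})
        with pytest.raises(UnknownPopulation):
            population_score(w, "AFR")


class TestZeroCenteredScore:
    def test_expected_dosage_everywhere_centers_to_zero(self):
        panel = make_panel([0.2, -0.4, 1.0], [0.1, 0.5, 0.9])
        dosages = vector([0.2, 1.0, 1.8], panel)  # each = 2f
        assert zero_centered_score(dosages, panel, "EUR") == pytest.approx(0.0, abs=1e-15)

    def test_single_snp_hand_value(self):
        panel = make_panel([1.0], [0.5])
        assert zero_centered_score(vector([2], panel), panel, "EUR") == pytest.approx(1.0)

    def test_five_snp_case_matches_term_by_term_oracle(self, five_snp_panel):
        dosages = [2, 1, 0, 1, np.nan]
        expected = sum(
            (
                Fraction(str(beta)) * d - Fraction(str(f)) * 2 * Fraction(str(beta))
                for (_, _, _, beta, f), d in zip(FIVE_SNP_SPEC, dosages)
                if not np.isnan(d)
            ),
            Fraction(0),
        )
        got = zero_centered_score(vector(dosages, five_snp_panel), five_snp_panel, "EUR")
        assert got == pytest.approx(float(expected), rel=1e-12)

    def test_all_missing_warns_and_returns_placeholder_zero(self, five_snp_panel):
        dosages = vector([np.nan] * 5, five_snp_panel)
        with pytest.warns(EmptyOverlapWarning):
            assert zero_centered_score(dosages, five_snp_panel, "EUR") == 0.0


class TestPopulationSd:
    def test_single_snp_closed_form(self):
        panel = make_panel([1.0], [0.5])
        assert population_sd(panel, "EUR") == pytest.approx(np.sqrt(0.5))

    def test_zero_betas_raise(self):
        panel = make_panel([0.0, 0.0], [0.3, 0.4])
        with pytest.raises(ZeroVariancePanel):
            population_sd(panel, "EUR")

    def test_three_snp_panel_matches_exhaustive_genotype_enumeration(self):
        """Oracle: SD over all 27 genotype combinations weighted by HWE."""
        betas, freqs = [0.3, -0.2, 0.7], [0.2, 0.5, 0.8]
        panel = make_panel(betas, freqs)

        def hwe_prob(g, f):
            return [(1 - f) ** 2, 2 * f * (1 - f), f**2][g]

        mean_sq = mean = 0.0
        for combo in itertools.product(range(3), repeat=3):
            p = np.prod([hwe_prob(g, f) for g, f in zip(combo, freqs)])
            s = sum(b * (g - 2 * f) for b, g, f in zip(betas, combo, freqs))
            mean += p * s
            mean_sq += p * s * s
        oracle_sd = np.sqrt(mean_sq - mean**2)
        assert population_sd(panel, "EUR") == pytest.approx(oracle_sd, rel=1e-12)


class TestZScore:
    @pytest.mark.parametrize("zc,sd,expected", [(0.0, 2.3, 0.0), (1.0, 1.0, 1.0), (0.35, 0.7, 0.5)])
    def test_ratio(self, zc, sd, expected):
        assert z_score(zc, sd) == pytest.approx(expected)

    def test_nonpositive_sd_raises(self):
        with pytest.raises(ZeroVariancePanel):
            z_score(1.0, 0.0)


class TestEmpiricalNormalize:
    def test_score_at_reference_mean_is_zero(self):
        ref = np.arange(40, dtype=float)
        assert empirical_normalize(float(ref.mean()), ref) == pytest.approx(0.0)

    def test_matches_analytic_z_on_population_sample(self):
        """Reference cohort drawn from the scaling population: the empirical
        z agrees with the analytic one within sampling error (3/sqrt(n))."""
        rng = np.random.default_rng(11)
        m, n = 100, 2000
        freqs = rng.uniform(0.05, 0.95, m)
        betas = rng.normal(0, 0.1, m)
        panel = make_panel(betas, freqs)
        dosage_matrix = rng.binomial(2, freqs, size=(n, m)).astype(float)
        centered = (dosage_matrix - 2 * freqs) @ betas
        sd = population_sd(panel, "EUR")
        score = sd * 1.0  # an individual one analytic SD above the mean
        z_emp = empirical_normalize(score, centered)
        assert abs(z_emp - 1.0) < 3 / np.sqrt(n) * 2

    def test_too_few_reference_scores(self):
        with pytest.raises(InsufficientReference):
            empirical_normalize(0.0, [1.0] * 29)

    def test_constant_reference_scores(self):
        with pytest.raises(ZeroVariancePanel):
            empirical_normalize(0.0, [1.0] * 40)


class TestScoreProfile:
    def test_composition_matches_hand_pipeline(self, five_snp_panel):
        dosages = vector([2, 1, 0, 1, np.nan], five_snp_panel)
        res = score_profile(dosages, five_snp_panel, "EUR")
        centered = zero_centered_score(dosages, five_snp_panel, "EUR")
        assert res.zero_centered == centered
        assert res.z_score == centered / population_sd(five_snp_panel, "EUR")
        assert res.n_used == 4 and res.n_missing == 1

    def test_all_filled_profile_scores_exactly_zero(self, five_snp_panel):
        values = np.array([2 * w.effect_allele_frequency["EUR"] for w in five_snp_panel.weights])
        prov = np.full(5, Provenance.FREQUENCY_FILLED, dtype=np.int8)
        res = score_profile(DosageVector(values, prov, five_snp_panel.rsids),
                            five_snp_panel, "EUR")
        assert res.z_score == 0.0
        assert res.n_frequency_filled == len(five_snp_panel)

    def test_deterministic_bit_identical(self, five_snp_panel):
        dosages = vector([2, 1, 0, 1, np.nan], five_snp_panel)
        a = score_profile(dosages, five_snp_panel, "EUR")
        b = score_profile(dosages, five_snp_panel, "EUR")
        assert (a.raw_sum, a.zero_centered, a.z_score) == (b.raw_sum, b.zero_centered, b.z_score)


class TestInvariants:
    def test_frequency_fill_equals_skip_bitwise(self, five_snp_panel):
        """A filled SNP contributes β·2f − f·2·β = exactly 0.0."""
        rng = np.random.default_rng(5)
        for _ in range(50):
            genotyped = rng.random(5) < 0.5
            base = rng.integers(0, 3, 5).astype(float)
            skip_vals = np.where(genotyped, base, np.nan)
            fill_vals = np.array([
                base[i] if genotyped[i]
                else 2 * five_snp_panel.weights[i].effect_allele_frequency["EUR"]
                for i in range(5)
            ])
            prov_skip = np.where(genotyped, Provenance.GENOTYPED, Provenance.MISSING)
            prov_fill = np.where(genotyped, Provenance.GENOTYPED, Provenance.FREQUENCY_FILLED)
            if not genotyped.any():
                continue
            s = zero_centered_score(
                DosageVector(skip_vals, prov_skip.astype(np.int8), five_snp_panel.rsids),
                five_snp_panel, "EUR")
            f = zero_centered_score(
                DosageVector(fill_vals, prov_fill.astype(np.int8), five_snp_panel.rsids),
                five_snp_panel, "EUR")
            assert s == f  # bit-identical, not approx

    def test_disjoint_panels_scores_add_variances_add(self):
        rng = np.random.default_rng(3)
        b1, f1 = rng.normal(0, 0.2, 4), rng.uniform(0.1, 0.9, 4)
        b2, f2 = rng.normal(0, 0.2, 6), rng.uniform(0.1, 0.9, 6)
        p1 = make_panel(b1, f1)
        weights2 = tuple(
            ScoreWeight(f"rs{i+5}", "A", "G", b, uniform_freqs(f))
            for i, (b, f) in enumerate(zip(b2, f2))
        )
        p2 = WeightPanel("t2", ScoreMode.TOP_SNP, weights2)
        p12 = WeightPanel("t12", ScoreMode.TOP_SNP, p1.weights + p2.weights)
        d1 = rng.integers(0, 3, 4).astype(float)
        d2 = rng.integers(0, 3, 6).astype(float)
        s1 = zero_centered_score(vector(d1, p1), p1, "EUR")
        s2 = zero_centered_score(vector(d2, p2), p2, "EUR")
        s12 = zero_centered_score(vector(np.concatenate([d1, d2]), p12), p12, "EUR")
        assert s12 == pytest.approx(s1 + s2, rel=1e-12)
        assert population_sd(p12, "EUR") ** 2 == pytest.approx(
            population_sd(p1, "EUR") ** 2 + population_sd(p2, "EUR") ** 2, rel=1e-12
        )

    def test_more_effect_alleles_at_positive_beta_never_lower_z(self, five_snp_panel):
        base = [1, 1, 1, 1, 1]
        j = 2  # rs3, beta +0.4
        zs = []
        for d in (0, 1, 2):
            dos = list(base)
            dos[j] = d
            zs.append(score_profile(vector(dos, five_snp_panel), five_snp_panel, "EUR").z_score)
        assert zs[0] <= zs[1] <= zs[2]


class TestCarrierReport:
    VARIANTS = [
        RiskVariant("rs1", "A", 2.0),
        RiskVariant("rs2", "T", 1.8),
        RiskVariant("rs3", "C", 1.2),  # below the default magnitude cut
    ]

    def _profile(self, genotypes):
        from dtcprs.genotype_io import GenomeProfile, VariantCall, VendorDialect

        calls = [
            VariantCall(rsid, "1", 1000 + i, g)
            for i, (rsid, g) in enumerate(genotypes.items())
        ]
        return GenomeProfile("id_000000000", "0" * 32, VendorDialect.GENERIC, calls, {})

    def test_all_non_risk_homozygotes_not_carrier(self):
        rep = carrier_report(
            self._profile({"rs1": ("G", "G"), "rs2": ("C", "C")}), self.VARIANTS
        )
        assert rep.carrier is False and rep.hits == []

    def test_one_het_risk_genotype_is_carrier(self):
        rep = carrier_report(
            self._profile({"rs1": ("A", "G"), "rs2": ("C", "C")}), self.VARIANTS
        )
        assert rep.carrier is True and rep.hits == ["rs1"]

    def test_low_magnitude_variant_excluded(self):
        rep = carrier_report(self._profile({"rs3": ("C", "C")}), self.VARIANTS)
        assert rep.n_considered == 2  # rs3 (magnitude 1.2) filtered out
        assert rep.carrier is False

    def test_missing_genotype_counts_as_non_carrier(self):
        rep = carrier_report(self._profile({"rs1": None}), self.VARIANTS)
        assert rep.carrier is False

    def test_carrier_fractions_uninformative_while_prs_separates(self):
        """The single-variant reporting style is not predictive even when
        the aggregated PRS is: carrier fractions in cases and controls are
        statistically indistinguishable (p > 0.05) while the PRS reaches
        AUC > 0.6 on the same cohort."""
        from dtcprs.evaluation import auc, two_proportion_test
        from dtcprs.scoring import cohort_zero_centered
        from dtcprs.simulate import SimConfig, simulate_cohort, simulate_weights

        m = 100
        panel = simulate_weights(m, seed=17)
        cohort = simulate_cohort(
            SimConfig(400, m, h2=0.5, prevalence=0.3, seed=17), panel
        )
        prs = cohort_zero_centered(cohort.dosages.astype(float), panel, "EUR")
        assert auc(prs, cohort.phenotype) > 0.6

        # "risk variants": the largest positive-effect low-frequency SNPs
        idx = [
            j for j in np.argsort(-panel.betas)
            if panel.weights[j].effect_allele_frequency["EUR"] < 0.3
        ][:8]
        variants = [
            RiskVariant(panel.weights[j].rsid, panel.weights[j].effect_allele, 2.0)
            for j in idx
        ]
        def genotype(d):  # simulated weights use effect allele A, other G
            return tuple(["A"] * int(d) + ["G"] * (2 - int(d)))

        carrier = np.array([
            carrier_report(
                {panel.weights[j].rsid: genotype(cohort.dosages[i, j]) for j in idx},
                variants,
            ).carrier
            for i in range(cohort.n)
        ])
        cases = cohort.phenotype == 1
        p = two_proportion_test(
            int(carrier[cases].sum()), int(cases.sum()),
            int(carrier[~cases].sum()), int((~cases).sum()),
        )
        assert p > 0.05
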