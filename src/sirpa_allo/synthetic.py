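"""Synthetic cohort, genotype and CFSE-histogram generator.

Everything the pipeline consumes can be generated here with the statistical
structure the analysis assumes: haplotypes drawn i.i.d. from the cohort
allele frequencies (V1 35.7%, V2 62.4%, V9 1.3%, NV1 0.3%, NV2 0.3%),
transplant pairs with eight baseline covariates, acute-rejection outcomes
whose probability depends on the pair's alloresponse group, and CFSE
generation histograms from an explicit division-destiny branching process
that also returns its ground truth for oracle testing.

The generator emulates the study's marginal structure, not its biology: no
linkage disequilibrium beyond i.i.d. allele draws, no division kinetics
beyond a truncated-Poisson destiny, and covariates independent of genotype
unless a confounding knob is turned.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Mapping

import numpy as np
import pandas as pd

from .alloscore import FunctionalGenotype, RiskGroup, pair_score
from .cfse import MAX_GENERATION, CFSEHistogram
from .cohort_stats import COVARIATES
from .haplotyping import HaplotypePanel, UnphasedGenotype, collapse_functional

#: Cohort allele frequencies (fractions) used as generator defaults.
DEFAULT_ALLELE_FREQS = {"V1": 0.357, "V2": 0.624, "V9": 0.013, "NV1": 0.003, "NV2": 0.003}

#: Synthetic group-wise acute-rejection probabilities, ordered LOW < INT < HIGH
#: to mirror the reported direction of effect; not the study's estimates.
DEFAULT_AR_PROBS = {RiskGroup.LOW: 0.10, RiskGroup.INTERMEDIATE: 0.30, RiskGroup.HIGH: 0.45}


@dataclass(frozen=True)
class CovariateModel:
    """Marginal distributions of the eight matching covariates."""

    recipient_age_mean: float = 54.0
    recipient_age_sd: float = 10.0
    donor_age_mean: float = 38.0
    donor_age_sd: float = 11.0
    p_recipient_male: float = 0.5
    p_donor_male: float = 0.55
    p_autoimmune: float = 0.25
    p_first_degree: float = 0.7
    hla_mismatch_probs: tuple[float, float, float] = (0.2, 0.5, 0.3)  # P(0), P(1), P(2)


@dataclass(frozen=True)
class CFSEModel:
    """Division-destiny model per stimulation condition.

    Each seeded precursor draws a destiny d ~ Poisson(mean) truncated to
    {0..max_generation} and contributes 2^d cells at generation d.
    """

    cells_seeded: int = 1000
    max_generation: int = MAX_GENERATION
    mean_divisions: Mapping[str, float] = field(
        default_factory=lambda: {
            "IgG1": 0.3,
            "SIRPA_V1_FC": 0.5,
            "SIRPA_V2_FC": 1.0,
            "SELF": 0.2,
            "DONOR": 0.8,
            "THIRD_PARTY": 1.0,
        }
    )
    #: conditions listed here use a point-mass destiny (every precursor divides
    #: exactly this many times) instead of the truncated Poisson
    fixed_destiny: Mapping[str, int] = field(default_factory=dict)
    noise_sigma: float = 0.0  # multiplicative log-normal noise on counts; off by default


@dataclass(frozen=True)
class SimulationConfig:
    seed: int = 0
    n_pairs: int = 154
    allele_freqs: Mapping[str, float] = field(default_factory=lambda: dict(DEFAULT_ALLELE_FREQS))
    ar_prob_by_group: Mapping[RiskGroup, float] = field(
        default_factory=lambda: dict(DEFAULT_AR_PROBS)
    )
    covariates: CovariateModel = field(default_factory=CovariateModel)
    cfse: CFSEModel = field(default_factory=CFSEModel)
    #: years added to recipient age per group step LOW→INT→HIGH, to exercise
    #: covariate–group confounding in the propensity adjustment
    confounding_age_shift: float = 0.0

    def __post_init__(self) -> None:
        total = float(sum(self.allele_freqs.values()))
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"allele frequencies sum to {total}, not 1")
        for p in [*self.allele_freqs.values(), *self.ar_prob_by_group.values()]:
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"probability {p} outside [0, 1]")

    def with_seed(self, seed: int) -> "SimulationConfig":
        return replace(self, seed=seed)


def _rng(cfg: SimulationConfig) -> np.random.Generator:
    return np.random.default_rng(cfg.seed)


def _draw_haplotypes(cfg: SimulationConfig, rng: np.random.Generator, n: int) -> np.ndarray:
    names = sorted(cfg.allele_freqs)
    probs = np.array([cfg.allele_freqs[k] for k in names])
    return rng.choice(names, size=n, p=probs / probs.sum())


# ---------------------------------------------------------------------------
# Genotypes
# ---------------------------------------------------------------------------

def simulate_genotypes(
    cfg: SimulationConfig, panel: HaplotypePanel, n_subjects: int | None = None
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Draw per-subject haplotype pairs and derive phased and unphased tables.

    Returns ``(phased, unphased, truth)``: the phased table (subject_id,
    hap_index, one column per site), the unphased table obtained by dropping
    phase (cells like "A/G"), and the ground-truth pair per subject.
    Deterministic per config seed.
    """
    if missing := set(cfg.allele_freqs) - set(panel.names):
        raise ValueError(f"panel lacks haplotypes named {sorted(missing)}")
    n = cfg.n_pairs * 2 if n_subjects is None else n_subjects
    rng = _rng(cfg)
    draws = _draw_haplotypes(cfg, rng, 2 * n).reshape(n, 2)
    site_ids = [s.site_id for s in panel.sites]

    phased_rows, unphased_rows, truth_rows = [], [], []
    for i, (name1, name2) in enumerate(draws):
        subject = f"S{i + 1:04d}"
        h1, h2 = panel[name1], panel[name2]
        for k, h in enumerate((h1, h2), start=1):
            phased_rows.append({"subject_id": subject, "hap_index": k, **dict(zip(site_ids, h.alleles))})
        g = UnphasedGenotype.from_pair(subject, h1, h2)
        unphased_rows.append(
            {"subject_id": subject, **{sid: "/".join(c) for sid, c in zip(site_ids, g.calls)}}
        )
        truth_rows.append({"subject_id": subject, "hap1": name1, "hap2": name2})
    return (
        pd.DataFrame(phased_rows),
        pd.DataFrame(unphased_rows),
        pd.DataFrame(truth_rows),
    )


# ---------------------------------------------------------------------------
# Cohort
# ---------------------------------------------------------------------------

def _functional(cfg: SimulationConfig, panel: HaplotypePanel | None, name: str) -> str:
    if panel is not None and name in panel.names:
        return collapse_functional(panel[name], panel).allele.value
    # without a panel, V2 is V2 and every other named allele is V1-like
    return "V2" if name == "V2" else "V1LIKE"


def simulate_cohort(
    cfg: SimulationConfig,
    panel: HaplotypePanel | None = None,
    n_per_group: Mapping[RiskGroup, int] | None = None,
) -> pd.DataFrame:
    """Simulate a transplant cohort table: genotypes, covariates, AR outcomes.

    Each pair draws two recipient and two donor haplotypes i.i.d. from the
    allele frequencies; the pair's alloresponse group follows from its score
    and its AR outcome is Bernoulli with the group's configured probability.
    ``n_per_group`` instead fixes the number of pairs per group (genotypes are
    redrawn until they land in the target group), which the balanced designs
    used for calibration experiments need.
    """
    rng = _rng(cfg)
    cov = cfg.covariates

    targets: list[RiskGroup | None]
    if n_per_group is None:
        targets = [None] * cfg.n_pairs
    else:
        targets = [g for g, k in n_per_group.items() for _ in range(k)]

    rows = []
    for i, target in enumerate(targets):
        while True:
            alleles = [
                _functional(cfg, panel, name) for name in _draw_haplotypes(cfg, rng, 4)
            ]
            rec = FunctionalGenotype(alleles[0], alleles[1])
            don = FunctionalGenotype(alleles[2], alleles[3])
            score = pair_score(rec, don)
            if target is None or score.group is target:
                break
        group = score.group
        shift = cfg.confounding_age_shift * {
            RiskGroup.LOW: 0,
            RiskGroup.INTERMEDIATE: 1,
            RiskGroup.HIGH: 2,
        }[group]
        rows.append(
            {
                "id": f"P{i + 1:04d}",
                "recipient_age": max(0.0, rng.normal(cov.recipient_age_mean + shift, cov.recipient_age_sd)),
                "recipient_sex": "M" if rng.random() < cov.p_recipient_male else "F",
                "primary_disease": "autoimmune" if rng.random() < cov.p_autoimmune else "other",
                "donor_relationship": "first_degree" if rng.random() < cov.p_first_degree else "other",
                "hla_class1_mismatches": int(rng.choice(3, p=cov.hla_mismatch_probs)),
                "hla_class2_mismatches": int(rng.choice(3, p=cov.hla_mismatch_probs)),
                "donor_age": max(0.0, rng.normal(cov.donor_age_mean, cov.donor_age_sd)),
                "donor_sex": "M" if rng.random() < cov.p_donor_male else "F",
                "recipient_allele1": rec.allele1.value,
                "recipient_allele2": rec.allele2.value,
                "donor_allele1": don.allele1.value,
                "donor_allele2": don.allele2.value,
                "score": score.score,
                "allo_group": group.value,
                "ar_within_90d": bool(rng.random() < cfg.ar_prob_by_group[group]),
            }
        )
    columns = [
        "id", *COVARIATES,
        "recipient_allele1", "recipient_allele2", "donor_allele1", "donor_allele2",
        "score", "allo_group", "ar_within_90d",
    ]
    return pd.DataFrame(rows, columns=columns)


# ---------------------------------------------------------------------------
# CFSE
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class CFSETruth:
    """Branching-process ground truth behind a simulated histogram."""

    precursors: int
    events: int
    per_generation_precursors: np.ndarray

    @property
    def pi(self) -> float:
        return self.events / self.precursors


def simulate_cfse(
    cfg: SimulationConfig,
    condition: str,
    rng: np.random.Generator | None = None,
) -> tuple[CFSEHistogram, CFSETruth]:
    """Simulate one CFSE histogram from an explicit division-destiny process.

    Each of ``cells_seeded`` precursors draws a destiny d (truncated Poisson
    with the condition's mean), contributing 2^d cells at generation d and
    2^d − 1 division events; the returned ground truth lets deconvolution be
    checked exactly.  Optional log-normal measurement noise perturbs the
    counts (and only the counts).
    """
    model = cfg.cfse
    if condition not in model.mean_divisions and condition not in model.fixed_destiny:
        raise KeyError(f"no division-destiny model configured for condition {condition!r}")
    if rng is None:
        rng = _rng(cfg)
    G = model.max_generation
    if condition in model.fixed_destiny:
        destinies = np.full(model.cells_seeded, min(model.fixed_destiny[condition], G))
    else:
        destinies = np.minimum(rng.poisson(model.mean_divisions[condition], model.cells_seeded), G)
    per_gen_precursors = np.bincount(destinies, minlength=G + 1).astype(float)
    counts = per_gen_precursors * np.exp2(np.arange(G + 1))
    truth = CFSETruth(
        precursors=int(model.cells_seeded),
        events=int((np.exp2(destinies) - 1).sum()),
        per_generation_precursors=per_gen_precursors,
    )
    if model.noise_sigma > 0:
        counts = counts * rng.lognormal(0.0, model.noise_sigma, counts.size)
    return CFSEHistogram(counts, condition), truth


def simulate_cfse_table(cfg: SimulationConfig, subjects: list[str] | None = None) -> pd.DataFrame:
    """Long-format histogram table (subject_id, condition, generation, count)
    covering every configured condition."""
    rng = _rng(cfg)
    subjects = subjects or ["S0001"]
    rows = []
    for subject in subjects:
        for condition in cfg.cfse.mean_divisions:
            hist, _ = simulate_cfse(cfg, condition, rng)
            for g, c in enumerate(hist.counts):
                rows.append(
                    {"subject_id": subject, "condition": condition, "generation": g, "count": c}
                )
    return pd.DataFrame(rows)
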