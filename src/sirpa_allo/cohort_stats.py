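"""Propensity-score matching and acute-rejection comparison across alloresponse groups.

Because alloresponse groups are genotype-defined rather than randomized,
baseline differences between groups are adjusted by 1:1 propensity-score
matching before comparing acute-rejection (AR) incidence.  The propensity
model is a logistic regression of group membership on eight covariates
(recipient age and sex, primary disease, donor relationship, HLA class I and
class II mismatch counts, donor age and sex); matching is greedy nearest
neighbor without replacement under a caliper of 0.1 on the propensity scale.
Matched incidences are compared with a chi-square test (Fisher's exact test
when any expected cell is below 5), with McNemar's test on discordant pairs
reported alongside as the orthodox paired alternative.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Hashable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
import statsmodels.api as sm
from statsmodels.stats.contingency_tables import mcnemar
from statsmodels.tools.sm_exceptions import PerfectSeparationError, PerfectSeparationWarning

logger = logging.getLogger("sirpa_allo")

#: The eight matching covariates, in cohort-table column order.
COVARIATES = (
    "recipient_age",
    "recipient_sex",
    "primary_disease",
    "donor_relationship",
    "hla_class1_mismatches",
    "hla_class2_mismatches",
    "donor_age",
    "donor_sex",
)

#: Binary covariate encodings (level mapped to 1).
_BINARY_LEVELS = {
    "recipient_sex": "M",
    "donor_sex": "M",
    "primary_disease": "autoimmune",
    "donor_relationship": "first_degree",
}

DEFAULT_CALIPER = 0.1

GROUP_COLUMN = "allo_group"
OUTCOME_COLUMN = "ar_within_90d"


def design_matrix(cohort: pd.DataFrame) -> pd.DataFrame:
    """Numeric design matrix over the eight covariates (binary levels → 0/1)."""
    if missing := set(COVARIATES) - set(cohort.columns):
        raise ValueError(f"cohort table lacks covariate columns {sorted(missing)}")
    X = pd.DataFrame(index=cohort.index)
    for cov in COVARIATES:
        if cov in _BINARY_LEVELS:
            X[cov] = (cohort[cov] == _BINARY_LEVELS[cov]).astype(float)
        else:
            X[cov] = pd.to_numeric(cohort[cov], errors="coerce")
    return X


@dataclass(frozen=True)
class PropensityResult:
    """Per-subject propensity scores with the fitted model's coefficients."""

    scores: pd.Series  # indexed by subject id, P(membership in group_a)
    groups: pd.Series  # group label per scored subject
    coefficients: pd.Series
    group_a: str
    group_b: str
    n_dropped: int
    used_fallback: bool


def fit_propensity(
    cohort: pd.DataFrame,
    group_a: str,
    group_b: str,
    group_col: str = GROUP_COLUMN,
    id_col: str = "id",
) -> PropensityResult:
    """Logistic propensity model of group membership on the eight covariates.

    Rows outside the two compared groups are ignored; rows with missing
    covariates are dropped with a logged count (complete-case analysis).  On
    complete separation or a failed maximum-likelihood fit, a ridge-penalized
    logistic fit is used instead and flagged on the result.
    """
    sub = cohort[cohort[group_col].isin([group_a, group_b])]
    X = design_matrix(sub)
    keep = X.notna().all(axis=1)
    n_dropped = int((~keep).sum())
    if n_dropped:
        logger.info("fit_propensity: dropped %d rows with missing covariates", n_dropped)
    sub, X = sub[keep], X[keep]
    y = (sub[group_col] == group_a).astype(float)
    if y.sum() < 2 or (1 - y).sum() < 2:
        raise ValueError("need at least 2 complete-case subjects per group")

    X_const = sm.add_constant(X, has_constant="add")
    used_fallback = False
    params = None
    import warnings

    with warnings.catch_warnings():
        warnings.simplefilter("error", PerfectSeparationWarning)
        warnings.simplefilter("ignore", RuntimeWarning)
        try:
            fit = sm.Logit(y, X_const).fit(disp=0, maxiter=200)
            if fit.mle_retvals.get("converged", False) and np.all(np.isfinite(fit.params)):
                params = fit.params
                scores = np.asarray(fit.predict(X_const))
        except (PerfectSeparationError, PerfectSeparationWarning, np.linalg.LinAlgError):
            params = None
    if params is None or np.ptp(scores) > 1 - 1e-8:
        used_fallback = True
        logger.warning("fit_propensity: separation or non-convergence; ridge-penalized fit used")
        clf = LogisticRegression(C=1.0, max_iter=1000)
        clf.fit(X.to_numpy(), y.to_numpy())
        scores = clf.predict_proba(X.to_numpy())[:, 1]
        params = pd.Series(
            np.concatenate(([clf.intercept_[0]], clf.coef_[0])), index=["const", *COVARIATES]
        )

    ids = sub[id_col] if id_col in sub.columns else sub.index
    return PropensityResult(
        scores=pd.Series(scores, index=pd.Index(ids, name=id_col)),
        groups=pd.Series(sub[group_col].to_numpy(), index=pd.Index(ids, name=id_col)),
        coefficients=pd.Series(params, index=["const", *COVARIATES]),
        group_a=group_a,
        group_b=group_b,
        n_dropped=n_dropped,
        used_fallback=used_fallback,
    )


@dataclass(frozen=True)
class MatchedCohort:
    """1:1 matched pairs (id_a, id_b, |Δ propensity|) under a caliper."""

    pairs: tuple[tuple[Hashable, Hashable, float], ...]
    caliper: float
    group_a: str
    group_b: str
    propensity_coefficients: pd.Series | None = field(default=None, repr=False)

    @property
    def n_pairs(self) -> int:
        return len(self.pairs)

    @property
    def ids_a(self) -> list[Hashable]:
        return [p[0] for p in self.pairs]

    @property
    def ids_b(self) -> list[Hashable]:
        return [p[1] for p in self.pairs]


def match_1to1(
    scores_a: pd.Series,
    scores_b: pd.Series,
    caliper: float = DEFAULT_CALIPER,
    seed: int = 0,
    caliper_scale: Literal["probability", "logit_sd"] = "probability",
    group_a: str = "A",
    group_b: str = "B",
    propensity_coefficients: pd.Series | None = None,
) -> MatchedCohort:
    """Greedy 1:1 nearest-neighbor matching without replacement under a caliper.

    Subjects of the smaller group are processed in descending propensity
    order; each takes its nearest still-unmatched counterpart unless the
    score difference exceeds the caliper.  Exact-distance ties are broken by
    the seeded RNG, making the pairing deterministic given the seed.  The
    caliper applies on the propensity-probability scale by default, or as
    ``caliper × SD(logit(propensity))`` with ``caliper_scale="logit_sd"``.
    """
    if caliper <= 0:
        raise ValueError("caliper must be > 0")
    rng = np.random.default_rng(seed)
    if caliper_scale == "logit_sd":
        pooled = np.clip(
            np.concatenate([scores_a.to_numpy(), scores_b.to_numpy()]), 1e-12, 1 - 1e-12
        )
        effective_caliper = caliper * float(np.std(np.log(pooled / (1 - pooled)), ddof=1))
    elif caliper_scale == "probability":
        effective_caliper = caliper
    else:
        raise ValueError(f"unknown caliper scale {caliper_scale!r}")

    swap = len(scores_b) < len(scores_a)
    small, large = (scores_b, scores_a) if swap else (scores_a, scores_b)

    order = small.sort_values(ascending=False, kind="stable").index
    avail_ids = list(large.index)
    avail_scores = large.to_numpy(dtype=float).copy()
    taken = np.zeros(len(avail_ids), dtype=bool)
    pairs = []
    for sid in order:
        d = np.abs(avail_scores - float(small[sid]))
        d[taken] = np.inf
        dmin = d.min()
        if not np.isfinite(dmin) or dmin > effective_caliper:
            continue
        candidates = np.flatnonzero(d == dmin)
        pick = int(candidates[0]) if len(candidates) == 1 else int(rng.choice(candidates))
        taken[pick] = True
        pair = (avail_ids[pick], sid, float(dmin)) if swap else (sid, avail_ids[pick], float(dmin))
        pairs.append(pair)

    return MatchedCohort(
        tuple(pairs), effective_caliper, group_a, group_b, propensity_coefficients
    )


def match_groups(
    cohort: pd.DataFrame,
    group_a: str,
    group_b: str,
    caliper: float = DEFAULT_CALIPER,
    seed: int = 0,
    caliper_scale: Literal["probability", "logit_sd"] = "probability",
) -> MatchedCohort:
    """Fit the propensity model and match the two groups in one step."""
    ps = fit_propensity(cohort, group_a, group_b)
    return match_1to1(
        ps.scores[ps.groups == group_a],
        ps.scores[ps.groups == group_b],
        caliper=caliper,
        seed=seed,
        caliper_scale=caliper_scale,
        group_a=group_a,
        group_b=group_b,
        propensity_coefficients=ps.coefficients,
    )


def incidence_percent(n_events: int, n_total: int) -> float:
    """Incidence as a percentage, one decimal place (27 of 85 → 31.8)."""
    if n_total <= 0:
        raise ValueError("empty denominator")
    return round(100.0 * n_events / n_total, 1)


@dataclass(frozen=True)
class ARComparison:
    """Matched acute-rejection incidence comparison between two arms."""

    n_pairs: int
    events_a: int
    events_b: int
    incidence_a: float  # percent, one decimal
    incidence_b: float
    test: str  # "chi-square" or "fisher"
    statistic: float
    p_value: float
    mcnemar_statistic: float
    mcnemar_p: float
    group_a: str
    group_b: str


def compare_ar(matched: MatchedCohort, outcomes: Mapping[Hashable, bool]) -> ARComparison:
    """AR incidence per matched arm with chi-square/Fisher and McNemar tests.

    The 2×2 incidence table is tested by Pearson's chi-square (no continuity
    correction) or by Fisher's exact test when any expected cell is below 5;
    McNemar's exact test on the discordant pairs is reported alongside.
    """
    if matched.n_pairs < 1:
        raise ValueError("no matched pairs to compare")
    out_a = np.array([bool(outcomes[i]) for i in matched.ids_a])
    out_b = np.array([bool(outcomes[i]) for i in matched.ids_b])
    n = matched.n_pairs
    ea, eb = int(out_a.sum()), int(out_b.sum())
    table = np.array([[ea, n - ea], [eb, n - eb]], dtype=float)

    if np.any(table.sum(axis=0) == 0):
        # degenerate margin (all-AR or no-AR in both arms): no association testable
        test, statistic, p = "chi-square", 0.0, 1.0
    else:
        expected = stats.contingency.expected_freq(table)
        if np.any(expected < 5):
            test = "fisher"
            statistic, p = stats.fisher_exact(table.astype(int), alternative="two-sided")
        else:
            test = "chi-square"
            res = stats.chi2_contingency(table, correction=False)
            statistic, p = float(res.statistic), float(res.pvalue)

    discordant = np.array(
        [
            [int(np.sum(out_a & out_b)), int(np.sum(out_a & ~out_b))],
            [int(np.sum(~out_a & out_b)), int(np.sum(~out_a & ~out_b))],
        ]
    )
    mc = mcnemar(discordant, exact=True)

    return ARComparison(
        n_pairs=n,
        events_a=ea,
        events_b=eb,
        incidence_a=incidence_percent(ea, n),
        incidence_b=incidence_percent(eb, n),
        test=test,
        statistic=float(statistic),
        p_value=float(p),
        mcnemar_statistic=float(mc.statistic),
        mcnemar_p=float(mc.pvalue),
        group_a=matched.group_a,
        group_b=matched.group_b,
    )


def rank_tests(
    x: Sequence[float], y: Sequence[float], paired: bool = False
) -> tuple[float, float]:
    """Two-sided Mann–Whitney U (unpaired) or Wilcoxon signed-rank (paired).

    Exact null distributions are used for n ≤ 25 without ties; larger or tied
    samples use the normal approximation with continuity correction.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size < 1 or y.size < 1:
        raise ValueError("samples must be non-empty")
    if paired:
        if x.size != y.size:
            raise ValueError("paired samples must have equal length")
        d = x - y
        if np.all(d == 0):
            return 0.0, 1.0
        nz = d[d != 0]
        exact_ok = nz.size <= 25 and np.unique(np.abs(nz)).size == nz.size and nz.size == d.size
        res = stats.wilcoxon(
            x, y, zero_method="wilcox", correction=True,
            method="exact" if exact_ok else "approx", alternative="two-sided",
        )
    else:
        pooled = np.concatenate([x, y])
        exact_ok = max(x.size, y.size) <= 25 and np.unique(pooled).size == pooled.size
        res = stats.mannwhitneyu(
            x, y, alternative="two-sided",
            method="exact" if exact_ok else "asymptotic", use_continuity=True,
        )
    return float(res.statistic), float(res.pvalue)
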