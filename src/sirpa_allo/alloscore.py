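"""Donor–recipient SIRPα alloresponse score and risk grouping.

The CD47 signal delivered to T cells is stronger through V2 SIRPα (weight 2,
"++") than through V1-like SIRPα (weight 1, "+").  Because both direct (donor
APC) and indirect (recipient APC) presentation contribute, the presumed
magnitude of the T cell alloresponse for a transplant pair is the sum of the
weights of all four alleles — two recipient, two donor — giving an integer
score from 4 to 8, partitioned into low {4,5}, intermediate {6} and high
{7,8} alloresponse groups.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from enum import Enum

import pandas as pd

from .haplotyping import FunctionalAllele

logger = logging.getLogger("sirpa_allo")

#: Semiquantified CD47→T-cell signal strength per allele: V1-like "+", V2 "++".
ALLELE_WEIGHTS = {FunctionalAllele.V1LIKE: 1, FunctionalAllele.V2: 2}

SCORE_MIN = 4
SCORE_MAX = 8


class RiskGroup(str, Enum):
    LOW = "LOW"
    INTERMEDIATE = "INTERMEDIATE"
    HIGH = "HIGH"


_GROUP_BY_SCORE = {
    4: RiskGroup.LOW,
    5: RiskGroup.LOW,
    6: RiskGroup.INTERMEDIATE,
    7: RiskGroup.HIGH,
    8: RiskGroup.HIGH,
}

_ALIASES = {
    "V1LIKE": FunctionalAllele.V1LIKE,
    "V1": FunctionalAllele.V1LIKE,
    "V2": FunctionalAllele.V2,
}


def as_functional(a: FunctionalAllele | str) -> FunctionalAllele:
    """Coerce an allele symbol to a functional allele ('V1' aliases V1LIKE)."""
    if isinstance(a, FunctionalAllele):
        return a
    try:
        return _ALIASES[str(a).upper()]
    except KeyError:
        raise ValueError(f"not a functional allele: {a!r}") from None


def allele_weight(a: FunctionalAllele | str) -> int:
    """Signal-strength weight of one allele: V1-like → 1, V2 → 2."""
    return ALLELE_WEIGHTS[as_functional(a)]


@dataclass(frozen=True)
class FunctionalGenotype:
    """Unordered pair of functional alleles; V1/V1, V1/V2 or V2/V2."""

    allele1: FunctionalAllele
    allele2: FunctionalAllele

    def __post_init__(self) -> None:
        object.__setattr__(self, "allele1", as_functional(self.allele1))
        object.__setattr__(self, "allele2", as_functional(self.allele2))

    @property
    def weight_sum(self) -> int:
        return allele_weight(self.allele1) + allele_weight(self.allele2)

    @property
    def label(self) -> str:
        short = {FunctionalAllele.V1LIKE: "V1", FunctionalAllele.V2: "V2"}
        return "/".join(sorted((short[self.allele1], short[self.allele2])))


#: The three functional genotypes, for exhaustive 3×3 enumeration.
GENOTYPES = (
    FunctionalGenotype(FunctionalAllele.V1LIKE, FunctionalAllele.V1LIKE),
    FunctionalGenotype(FunctionalAllele.V1LIKE, FunctionalAllele.V2),
    FunctionalGenotype(FunctionalAllele.V2, FunctionalAllele.V2),
)


@dataclass(frozen=True)
class AlloScore:
    score: int
    group: RiskGroup
    recipient_sum: int
    donor_sum: int

    def __post_init__(self) -> None:
        assert self.score == self.recipient_sum + self.donor_sum


def group_for_score(score: int) -> RiskGroup:
    try:
        return _GROUP_BY_SCORE[score]
    except KeyError:
        raise ValueError(f"alloresponse score {score} outside [{SCORE_MIN}, {SCORE_MAX}]") from None


def pair_score(recipient: FunctionalGenotype, donor: FunctionalGenotype) -> AlloScore:
    """Alloresponse score for one transplant pair: sum of the four allele weights."""
    r, d = recipient.weight_sum, donor.weight_sum
    return AlloScore(r + d, group_for_score(r + d), r, d)


_GENOTYPE_COLUMNS = ("recipient_allele1", "recipient_allele2", "donor_allele1", "donor_allele2")


def score_cohort(pairs: pd.DataFrame) -> pd.DataFrame:
    """Score every recipient–donor row of a cohort table.

    Expects the four allele columns ``recipient_allele1/2`` and
    ``donor_allele1/2`` with values V1/V1LIKE/V2.  Rows with missing or
    unresolvable alleles are flagged (``score_ok = False``), left unscored and
    counted in the log; all other rows gain ``score``, ``group``,
    ``recipient_sum`` and ``donor_sum`` columns.
    """
    missing = set(_GENOTYPE_COLUMNS) - set(pairs.columns)
    if missing:
        raise ValueError(f"cohort table lacks columns {sorted(missing)}")
    out = pairs.copy()
    out["score"] = pd.NA
    out["group"] = pd.NA
    out["recipient_sum"] = pd.NA
    out["donor_sum"] = pd.NA
    out["score_ok"] = False
    n_bad = 0
    for idx, row in pairs.iterrows():
        try:
            rec = FunctionalGenotype(row["recipient_allele1"], row["recipient_allele2"])
            don = FunctionalGenotype(row["donor_allele1"], row["donor_allele2"])
        except (ValueError, TypeError):
            n_bad += 1
            continue
        s = pair_score(rec, don)
        out.loc[idx, ["score", "group", "recipient_sum", "donor_sum", "score_ok"]] = (
            s.score,
            s.group.value,
            s.recipient_sum,
            s.donor_sum,
            True,
        )
    if n_bad:
        logger.info("score_cohort: %d of %d rows had unresolved genotypes", n_bad, len(pairs))
    return out
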