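"""Family Longevity Selection Score (FLoSS).

The score has two components.  The first is the summed survival
exceptionality of a proband sibship: for each sibling, minus the log
tail probability of their survival status under the appropriate
age/sex/birth-cohort life table.  Under the table, -log S(T) for a
random lifespan T is unit-exponential, so each sibling contributes 1 in
expectation; subtracting the sibship size centers the component at zero
("survival exactly as expected") and makes its expectation independent
of sibship size.  A living sibling of age t contributes the conditional
expectation E[-log S(T) | T > t] = -log S(t) + 1 (memorylessness of the
exponential on the -log S scale).  The second component is a bonus per
living sibling, favouring larger families available for prospective
follow-up.

Study eligibility mirrors the cohort rule: FLoSS >= 7 and a minimum
family of proband, at least one living proband-generation sibling, and
at least one offspring.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .lifetables import LifeTable
from .pedigree import Individual, Pedigree

__all__ = ["SibshipScore", "sib_exceptionality", "floss_score", "eligible",
           "DEFAULT_BONUS", "DEFAULT_THRESHOLD"]

DEFAULT_BONUS = 0.5      # per living sib; the original coefficient is in the
                         # FLoSS methodology literature, exposed as config here
DEFAULT_THRESHOLD = 7.0
DEFAULT_MIN_SIZE = 3


@dataclass
class SibshipScore:
    family_id: str
    n_sibs: int
    n_alive: int
    exceptionality_sum: float
    centered_component: float
    bonus: float
    floss: float
    n_excluded: int = 0
    per_sib: dict[str, float] = field(default_factory=dict)


def sib_exceptionality(individual: Individual, table: LifeTable) -> float:
    """Survival exceptionality of one sibling: -log tail probability.

    Dead at age a: -log S(a).  Alive at age a: -log S(a) + 1, the mean of
    -log S(T) conditional on surviving past a.
    """
    if individual.vital_status not in ("alive", "dead"):
        raise ValueError(
            f"sibling {individual.person_id}: vital_status missing or unknown")
    if individual.age_years is None:
        raise ValueError(f"sibling {individual.person_id}: age_years missing")
    if individual.birth_year is None:
        raise ValueError(f"sibling {individual.person_id}: birth_year missing")
    h = float(table.cumulative_hazard(individual.sex, individual.birth_year,
                                      individual.age_years))
    return h + 1.0 if individual.vital_status == "alive" else h


def floss_score(sibship, table: LifeTable,
                bonus_per_living: float = DEFAULT_BONUS,
                family_id: str | None = None) -> SibshipScore:
    """FLoSS for a proband sibship.

    Sibs with unknown vital status are excluded from the sum and counted
    in ``n_excluded`` rather than silently imputed.
    """
    sibship = list(sibship)
    if not sibship:
        raise ValueError("empty sibship")
    usable = [s for s in sibship if s.vital_status in ("alive", "dead")]
    n_excl = len(sibship) - len(usable)
    if not usable:
        raise ValueError("no sibling with known vital status")
    per_sib = {s.person_id: sib_exceptionality(s, table) for s in usable}
    n_sibs = len(usable)
    n_alive = sum(1 for s in usable if s.vital_status == "alive")
    total = sum(per_sib.values())
    centered = total - n_sibs
    bonus = bonus_per_living * n_alive
    fid = family_id if family_id is not None else usable[0].family_id
    return SibshipScore(fid, n_sibs, n_alive, total, centered, bonus,
                        centered + bonus, n_excl, per_sib)


def eligible(family: Pedigree, score: SibshipScore,
             threshold: float = DEFAULT_THRESHOLD,
             min_size: int = DEFAULT_MIN_SIZE) -> tuple[bool, list[str]]:
    """Study eligibility of a family given its proband-sibship score.

    Requires FLoSS >= threshold plus structure: a proband, at least one
    living proband-generation sibling, and at least one offspring.
    Returns (eligible, list of failed criteria).
    """
    reasons: list[str] = []
    if score.floss < threshold:
        reasons.append("score below threshold")
    probands = family.members("proband")
    if not probands:
        reasons.append("no proband")
    living_sibs = [p for p in probands
                   if p.vital_status == "alive"]
    # the proband themselves is alive by construction of recruitment; require
    # at least two living members of the proband generation (proband + sib)
    if len(living_sibs) < 2:
        reasons.append("no living sibling")
    if not family.members("offspring"):
        reasons.append("no offspring")
    if len(family) < min_size:
        reasons.append("family below minimum size")
    return (not reasons, reasons)
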