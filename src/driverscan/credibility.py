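"""Credibility assessment of a pooled association.

Three ingredients grade how much a significant meta-analysis result can
be trusted:

* statistical power of the combined sample to detect the alternative
  odds ratio (two-proportion z-test, normal approximation);
* the false-positive report probability (FPRP) — the posterior
  probability that a claimed association is false, given a prior on the
  association being real and the study's power at the alternative;
* the Venice interim criteria, which grade amount of evidence (A/B/C by
  n_minor, the count of subjects carrying the least frequent genotype),
  replication (A/B/C by I-squared) and protection from bias, and combine
  them into strong / moderate / weak cumulative evidence.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

from scipy import stats

__all__ = [
    "CredibilityReport",
    "two_proportion_power",
    "fprp",
    "venice_grade",
]


@dataclass(frozen=True)
class CredibilityReport:
    n_minor: int
    i2: float
    grade_amount: str
    grade_replication: str
    grade_bias: str
    overall: str
    bias_checks: dict[str, bool] = field(default_factory=dict)
    power: float | None = None
    fprp_by_prior: dict[float, float] = field(default_factory=dict)


def two_proportion_power(
    n_cases: int,
    n_controls: int,
    p0: float,
    or_alt: float,
    alpha: float = 0.05,
) -> float:
    """Power of the two-sided uncorrected two-proportion z-test.

    ``p0`` is the exposure (present-genotype) prevalence among controls;
    the case prevalence under the alternative odds ratio ``or_alt`` is
    p1 = or_alt * p0 / (1 - p0 + or_alt * p0).  The null standard error
    uses the pooled proportion, the alternative standard error the two
    distinct proportions (standard normal-approximation construction).
    """
    if not 0.0 < p0 < 1.0:
        raise ValueError("p0 must be in (0, 1)")
    if or_alt <= 0:
        raise ValueError("or_alt must be positive")
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must be in (0, 1)")
    if n_cases < 2 or n_controls < 2:
        raise ValueError("arm sizes must be >= 2")
    p1 = or_alt * p0 / (1.0 - p0 + or_alt * p0)
    pbar = (n_cases * p1 + n_controls * p0) / (n_cases + n_controls)
    se0 = math.sqrt(pbar * (1 - pbar) * (1.0 / n_cases + 1.0 / n_controls))
    se1 = math.sqrt(p1 * (1 - p1) / n_cases + p0 * (1 - p0) / n_controls)
    z_crit = stats.norm.isf(alpha / 2.0)
    delta = p1 - p0
    # two-sided rejection region; both tails contribute
    upper = stats.norm.sf((z_crit * se0 - delta) / se1)
    lower = stats.norm.cdf((-z_crit * se0 - delta) / se1)
    return float(upper + lower)


def fprp(p_obs: float, power_at_alt: float, prior: float) -> float:
    """False-positive report probability (Wacholder construction).

    FPRP = p (1 - pi) / (p (1 - pi) + power * pi) where p is the observed
    significance level, pi the prior probability of a true association,
    and power the probability of detecting the stated alternative.
    """
    for name, v in (("p_obs", p_obs), ("power_at_alt", power_at_alt),
                    ("prior", prior)):
        if not 0.0 < v <= 1.0:
            raise ValueError(f"{name} must be in (0, 1], got {v}")
    num = p_obs * (1.0 - prior)
    return num / (num + power_at_alt * prior)


def _grade_amount(n_minor: int) -> str:
    if n_minor > 1000:
        return "A"
    if n_minor >= 100:
        return "B"
    return "C"


def _grade_replication(i2: float) -> str:
    if i2 < 25.0:
        return "A"
    if i2 <= 50.0:
        return "B"
    return "C"


def venice_grade(
    n_minor: int,
    i2: float,
    bias_checks: dict[str, bool],
    power: float | None = None,
    fprp_by_prior: dict[float, float] | None = None,
) -> CredibilityReport:
    """Venice interim criteria grades and the overall credibility call.

    Amount of evidence: A for n_minor > 1000, B for 100-1000 (inclusive),
    C below 100.  Replication: A for I2 < 25%, B for 25-50%, C above 50%.
    Bias protection: A if any of the supplied checks passes
    (``or_in_null_band``, ``genotyping_ok``, ``robust_to_first_study``,
    ``no_small_study_effects``), else C.  Overall: strong when all three
    grades are A, weak when any grade is C, moderate otherwise.
    """
    if n_minor < 0:
        raise ValueError("n_minor must be nonnegative")
    if not 0.0 <= i2 <= 100.0:
        raise ValueError("i2 must be in [0, 100]")
    ga = _grade_amount(n_minor)
    gr = _grade_replication(i2)
    gb = "A" if any(bias_checks.values()) else "C"
    grades = (ga, gr, gb)
    if all(g == "A" for g in grades):
        overall = "strong"
    elif any(g == "C" for g in grades):
        overall = "weak"
    else:
        overall = "moderate"
    return CredibilityReport(
        n_minor=n_minor,
        i2=i2,
        grade_amount=ga,
        grade_replication=gr,
        grade_bias=gb,
        overall=overall,
        bias_checks=dict(bias_checks),
        power=power,
        fprp_by_prior=dict(fprp_by_prior or {}),
    )
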