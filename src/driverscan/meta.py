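"""Case-control meta-analysis of genotype 2x2 tables.

Each study contributes a 2x2 table of null vs present genotype counts in
cases and controls.  The effect measure is the odds ratio for carrying
the *present* genotype (any retained gene copy) in cases versus controls:

    OR = (case_present * control_null) / (case_null * control_present)

so OR < 1 means the present genotype is protective.  Per-study log odds
ratios with Woolf variances are pooled with DerSimonian-Laird random
effects (the default for fewer than 20 studies) or Mantel-Haenszel fixed
effects (20 or more), with Cochran's Q, I-squared and its
Higgins-Thompson 95% CI, leave-one-out sensitivity, and Harbord's
score-based test for small-study effects.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "TwoByTwoStudy",
    "StudyEffect",
    "PooledResult",
    "read_studies_csv",
    "study_effect",
    "genotype_chisq",
    "cochran_q",
    "i_squared",
    "pool_dl",
    "pool_mh",
    "pool",
    "select_model",
    "leave_one_out",
    "harbord_test",
    "genotype_totals",
]

Z95 = 1.959963984540054  # two-sided 95% normal critical value


@dataclass(frozen=True)
class TwoByTwoStudy:
    """Genotype counts for one case-control study.

    ``*_null`` counts homozygous whole-gene deletions; ``*_present``
    counts carriers of at least one gene copy.
    """

    study_id: str
    ethnicity: str
    case_null: int
    case_present: int
    control_null: int
    control_present: int

    def __post_init__(self):
        counts = (self.case_null, self.case_present,
                  self.control_null, self.control_present)
        if any(c < 0 for c in counts):
            raise ValueError(f"{self.study_id}: negative genotype count")
        if self.case_null + self.case_present < 1:
            raise ValueError(f"{self.study_id}: no cases")
        if self.control_null + self.control_present < 1:
            raise ValueError(f"{self.study_id}: no controls")

    @property
    def n_cases(self) -> int:
        return self.case_null + self.case_present

    @property
    def n_controls(self) -> int:
        return self.control_null + self.control_present

    @property
    def n_total(self) -> int:
        return self.n_cases + self.n_controls

    def table(self) -> np.ndarray:
        """2x2 array [[case_null, case_present], [control_null, control_present]]."""
        return np.array(
            [[self.case_null, self.case_present],
             [self.control_null, self.control_present]],
            dtype=np.float64,
        )


@dataclass(frozen=True)
class StudyEffect:
    """Log odds ratio (present vs null genotype) with Woolf standard error."""

    study_id: str
    log_or: float
    se: float
    corrected: bool  # Haldane-Anscombe +0.5 applied (a zero cell occurred)

    @property
    def odds_ratio(self) -> float:
        return math.exp(self.log_or)

    def ci(self, z: float = Z95) -> tuple[float, float]:
        return math.exp(self.log_or - z * self.se), math.exp(self.log_or + z * self.se)


@dataclass(frozen=True)
class PooledResult:
    model: str                 # "DL_random" or "MH_fixed"
    pooled_or: float
    ci_low: float
    ci_high: float
    z: float
    p: float
    Q: float
    df: int
    q_p: float
    tau2: float
    i2: float
    i2_ci_low: float
    i2_ci_high: float
    k: int

    @property
    def log_or(self) -> float:
        return math.log(self.pooled_or)


def read_studies_csv(path_or_buffer) -> list[TwoByTwoStudy]:
    """Load studies from a CSV with header
    ``study_id,ethnicity,case_null,case_present,control_null,control_present``.
    """
    df = pd.read_csv(path_or_buffer, comment="#")
    required = ["study_id", "ethnicity", "case_null", "case_present",
                "control_null", "control_present"]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise ValueError(f"study CSV missing columns: {missing}")
    return [
        TwoByTwoStudy(
            study_id=str(r.study_id),
            ethnicity=str(r.ethnicity),
            case_null=int(r.case_null),
            case_present=int(r.case_present),
            control_null=int(r.control_null),
            control_present=int(r.control_present),
        )
        for r in df.itertuples()
    ]


def study_effect(s: TwoByTwoStudy) -> StudyEffect:
    """Per-study log OR (present vs null) with Woolf variance.

    If any cell is zero, the Haldane-Anscombe correction adds 0.5 to all
    four cells before both the OR and its variance are computed.
    """
    a, b = float(s.case_present), float(s.control_present)
    c, d = float(s.case_null), float(s.control_null)
    if (a + b == 0) or (c + d == 0) or (a + c == 0) or (b + d == 0):
        raise ValueError(f"{s.study_id}: a margin of the 2x2 table is zero")
    corrected = min(a, b, c, d) == 0
    if corrected:
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
    log_or = math.log((a * d) / (b * c))
    se = math.sqrt(1 / a + 1 / b + 1 / c + 1 / d)
    return StudyEffect(study_id=s.study_id, log_or=log_or, se=se, corrected=corrected)


def genotype_chisq(s: TwoByTwoStudy) -> tuple[float, float]:
    """Uncorrected Pearson chi-square (1 df) on the genotype 2x2 table."""
    tab = s.table()
    if np.any(tab.sum(axis=0) == 0) or np.any(tab.sum(axis=1) == 0):
        raise ValueError(f"{s.study_id}: zero margin")
    chi2, p, _, _ = stats.chi2_contingency(tab, correction=False)
    return float(chi2), float(p)


def _weights(effects: list[StudyEffect]) -> tuple[np.ndarray, np.ndarray]:
    y = np.array([e.log_or for e in effects])
    w = np.array([1.0 / e.se**2 for e in effects])
    return y, w


def cochran_q(effects: list[StudyEffect]) -> tuple[float, int, float]:
    """Cochran's heterogeneity Q with inverse-variance weights."""
    if len(effects) < 2:
        raise ValueError("Cochran's Q needs at least 2 studies")
    y, w = _weights(effects)
    ybar = (w * y).sum() / w.sum()
    q = float((w * (y - ybar) ** 2).sum())
    df = len(effects) - 1
    return q, df, float(stats.chi2.sf(q, df))


def i_squared(Q: float, df: int) -> tuple[float, float, float]:
    """I-squared with its Higgins-Thompson test-based 95% CI.

    I2 = max(0, (Q - df)/Q) * 100.  The CI is built on ln H with
    H = sqrt(Q/df): se(ln H) = (ln Q - ln df) / (2 (sqrt(2Q) - sqrt(2 df - 1)))
    when Q > df, else the small-Q closed form
    sqrt((1 - 1/(3 (df-1)^2)) / (2 (df - 1))); the interval is
    back-transformed through I2 = (H^2 - 1)/H^2 and truncated to [0, 100].
    """
    if df < 1:
        raise ValueError("df must be >= 1")
    if Q < 0:
        raise ValueError("Q must be nonnegative")
    i2 = 0.0 if Q <= 0 else max(0.0, (Q - df) / Q) * 100.0
    if Q > df:
        se_ln_h = 0.5 * (math.log(Q) - math.log(df)) / (
            math.sqrt(2 * Q) - math.sqrt(2 * df - 1)
        )
    elif df > 1:
        se_ln_h = math.sqrt(
            (1.0 - 1.0 / (3 * (df - 1) ** 2)) / (2.0 * (df - 1))
        )
    else:
        se_ln_h = float("nan")
    ln_h = 0.5 * math.log(max(Q, 1e-300) / df)

    def to_i2(x: float) -> float:
        h2 = math.exp(2 * x)
        return min(100.0, max(0.0, (h2 - 1.0) / h2 * 100.0))

    if math.isnan(se_ln_h):
        return i2, float("nan"), float("nan")
    return i2, to_i2(ln_h - Z95 * se_ln_h), to_i2(ln_h + Z95 * se_ln_h)


def pool_dl(effects: list[StudyEffect]) -> PooledResult:
    """DerSimonian-Laird random-effects pooled odds ratio.

    The moment estimator tau2 = max(0, (Q - df) / (S1 - S2/S1)) with
    S1 = sum(w), S2 = sum(w^2) inflates the inverse-variance weights;
    the 95% CI uses the normal critical value.
    """
    if len(effects) < 2:
        raise ValueError("pooling needs at least 2 studies")
    y, w = _weights(effects)
    q, df, q_p = cochran_q(effects)
    s1, s2 = w.sum(), (w**2).sum()
    tau2 = max(0.0, (q - df) / (s1 - s2 / s1))
    w_star = 1.0 / (1.0 / w + tau2)
    mu = float((w_star * y).sum() / w_star.sum())
    se = float(1.0 / math.sqrt(w_star.sum()))
    z = mu / se
    p = float(2 * stats.norm.sf(abs(z)))
    i2, lo, hi = i_squared(q, df)
    return PooledResult(
        model="DL_random",
        pooled_or=math.exp(mu),
        ci_low=math.exp(mu - Z95 * se),
        ci_high=math.exp(mu + Z95 * se),
        z=z, p=p, Q=q, df=df, q_p=q_p, tau2=tau2,
        i2=i2, i2_ci_low=lo, i2_ci_high=hi, k=len(effects),
    )


def pool_mh(studies: list[TwoByTwoStudy]) -> PooledResult:
    """Mantel-Haenszel fixed-effect pooled odds ratio.

    OR_MH = sum(a_i d_i / n_i) / sum(b_i c_i / n_i) with a = case_present,
    b = control_present, c = case_null, d = control_null; the CI uses the
    Robins-Breslow-Greenland variance of log OR_MH.  Heterogeneity (Q,
    I2) is still reported from the inverse-variance log ORs.
    """
    if len(studies) < 2:
        raise ValueError("pooling needs at least 2 studies")
    a = np.array([s.case_present for s in studies], dtype=np.float64)
    b = np.array([s.control_present for s in studies], dtype=np.float64)
    c = np.array([s.case_null for s in studies], dtype=np.float64)
    d = np.array([s.control_null for s in studies], dtype=np.float64)
    n = a + b + c + d
    r, s_ = a * d / n, b * c / n
    R, S = r.sum(), s_.sum()
    if R == 0 or S == 0:
        raise ValueError("Mantel-Haenszel denominator sum is zero")
    or_mh = R / S
    # Robins-Breslow-Greenland variance of log(OR_MH)
    p_ = (a + d) / n
    q_ = (b + c) / n
    var = (
        (p_ * r).sum() / (2 * R**2)
        + ((p_ * s_ + q_ * r)).sum() / (2 * R * S)
        + (q_ * s_).sum() / (2 * S**2)
    )
    se = math.sqrt(var)
    mu = math.log(or_mh)
    z = mu / se
    p = float(2 * stats.norm.sf(abs(z)))
    effects = [study_effect(s) for s in studies]
    q, df, q_p = cochran_q(effects)
    i2, lo, hi = i_squared(q, df)
    return PooledResult(
        model="MH_fixed",
        pooled_or=or_mh,
        ci_low=math.exp(mu - Z95 * se),
        ci_high=math.exp(mu + Z95 * se),
        z=z, p=p, Q=q, df=df, q_p=q_p, tau2=0.0,
        i2=i2, i2_ci_low=lo, i2_ci_high=hi, k=len(studies),
    )


def select_model(k: int) -> str:
    """Random effects below 20 studies, Mantel-Haenszel fixed at 20 or more."""
    if k < 2:
        raise ValueError("need at least 2 studies")
    return "DL_random" if k < 20 else "MH_fixed"


def pool(studies: list[TwoByTwoStudy], model: str | None = None) -> PooledResult:
    """Pool studies under ``model`` (default: chosen by study count)."""
    if model is None:
        model = select_model(len(studies))
    if model == "DL_random":
        return pool_dl([study_effect(s) for s in studies])
    if model == "MH_fixed":
        return pool_mh(studies)
    raise ValueError(f"unknown model {model!r}")


def leave_one_out(
    studies: list[TwoByTwoStudy], model: str
) -> tuple[list[tuple[str, PooledResult]], float, float]:
    """Re-pool k times, omitting one study each time.

    Returns the per-omission results plus the min and max of the
    overall-effect p-values.  Sensitivity analysis is conventionally run
    under the model *not* used for the primary pooling.
    """
    if len(studies) < 3:
        raise ValueError("leave-one-out needs at least 3 studies")
    out = []
    for omit in studies:
        rest = [s for s in studies if s is not omit]
        out.append((omit.study_id, pool(rest, model=model)))
    ps = [r.p for _, r in out]
    return out, min(ps), max(ps)


def harbord_test(studies: list[TwoByTwoStudy]) -> tuple[float, float, float, float]:
    """Harbord's score-based test for small-study effects.

    Per study the efficient score of the log OR is
    Z = a - (a + b)(a + c)/n and its variance
    V = (a + b)(c + d)(a + c)(b + d) / (n^2 (n - 1)), with a =
    case_present, b = control_present, c = case_null, d = control_null.
    Z/sqrt(V) is regressed on sqrt(V) by ordinary least squares and the
    intercept tested against zero with a t-test on k - 2 df; an intercept
    far from zero signals asymmetry consistent with small-study effects.

    Returns (intercept, se, t, p).
    """
    if len(studies) < 3:
        raise ValueError("Harbord's test needs at least 3 studies")
    zs, vs = [], []
    for s in studies:
        a, b = s.case_present, s.control_present
        c, d = s.case_null, s.control_null
        n = a + b + c + d
        z = a - (a + b) * (a + c) / n
        v = (a + b) * (c + d) * (a + c) * (b + d) / (n**2 * (n - 1))
        if v <= 0:
            raise ValueError(f"{s.study_id}: zero score variance")
        zs.append(z)
        vs.append(v)
    x = np.sqrt(np.array(vs))
    yv = np.array(zs) / x
    X = np.column_stack([np.ones_like(x), x])
    beta, *_ = np.linalg.lstsq(X, yv, rcond=None)
    resid = yv - X @ beta
    k = len(studies)
    s2 = float((resid**2).sum() / (k - 2))
    cov = s2 * np.linalg.inv(X.T @ X)
    se = math.sqrt(cov[0, 0])
    if se == 0.0:
        # perfect fit (points exactly collinear): no evidence against a zero
        # intercept when the fitted intercept is itself zero
        t = 0.0 if abs(beta[0]) < 1e-10 else math.copysign(math.inf, beta[0])
    else:
        t = beta[0] / se
    p = float(2 * stats.t.sf(abs(t), k - 2))
    return float(beta[0]), se, float(t), p


def genotype_totals(studies: list[TwoByTwoStudy]) -> dict[str, float]:
    """Aggregate genotype counts and frequencies across studies.

    ``n_minor`` is the total number of cases plus controls carrying the
    least frequent genotype — the Venice amount-of-evidence quantity.
    """
    cn = sum(s.case_null for s in studies)
    cp = sum(s.case_present for s in studies)
    tn = sum(s.control_null for s in studies)
    tp = sum(s.control_present for s in studies)
    total_null, total_present = cn + tn, cp + tp
    return {
        "case_null": cn, "case_present": cp,
        "control_null": tn, "control_present": tp,
        "n_cases": cn + cp, "n_controls": tn + tp,
        "case_null_freq": 100.0 * cn / (cn + cp),
        "control_null_freq": 100.0 * tn / (tn + tp),
        "n_minor": min(total_null, total_present),
        "minor_genotype": "null" if total_null <= total_present else "present",
    }
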