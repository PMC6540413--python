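"""Morphologic TIL scoring and clinicopathologic association statistics.

The TIL (tumor-infiltrating lymphocyte) score of a tumor is the maximum
number of lymphocyte/plasma-cell foci seen on any H&E slide, capped at 4.
Two dichotomization cut-offs are supported: ``cut2`` (scores 2-4 high) and
``cut3`` (scores 3-4 high). Association with recurrence and pathologic
covariates uses 2x2 odds ratios with Woolf CIs, Pearson chi-square tests,
logistic regression (IRLS maximum likelihood via statsmodels) and variance
inflation factors for collinearity screening.

``COHORT_TABLES`` bundles the published cross-tabulations of the UAB
(discovery, n=159) and FCCC (validation, n=198) localized-ccRCC cohorts so
the printed univariate odds ratios can be recomputed from counts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
import statsmodels.api as sm

logger = logging.getLogger("rccimmune")

SCHEMES = ("cut2", "cut3")
MAX_TIL_SCORE = 4
SEPARATION_COEF_LIMIT = 15.0
VIF_FLAG_LEVEL = 5.0


class MorphologyError(ValueError):
    pass


class SeparationError(MorphologyError):
    """Complete separation: the MLE diverges."""


# ---------------------------------------------------------------------------
# TIL scoring
# ---------------------------------------------------------------------------


def aggregate_til_score(foci: list[int]) -> int:
    """TIL score = max per-slide foci count, capped at 4.

    E.g. slides with 2 and 3 foci score 3; a slide with 7 foci scores 4.
    An empty slide list is an error — no imputation.
    """
    if len(foci) == 0:
        raise MorphologyError("TIL score requires at least one reviewed slide")
    if any(f < 0 for f in foci):
        raise MorphologyError("foci counts must be non-negative")
    return min(max(foci), MAX_TIL_SCORE)


def dichotomize(score: int, scheme: str) -> str:
    """Map a 0-4 TIL score to 'low'/'high' under the given cut-off scheme."""
    if score not in range(MAX_TIL_SCORE + 1):
        raise MorphologyError(f"TIL score must be in 0..4, got {score!r}")
    if scheme == "cut2":
        return "high" if score >= 2 else "low"
    if scheme == "cut3":
        return "high" if score >= 3 else "low"
    raise MorphologyError(f"unknown scheme {scheme!r}; choose from {SCHEMES}")


# ---------------------------------------------------------------------------
# contingency statistics
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class ContingencyTable2x2:
    """Cells of an exposed/unexposed x event/no-event table:
    a = exposed events, b = exposed non-events,
    c = unexposed events, d = unexposed non-events."""

    a: int
    b: int
    c: int
    d: int

    def __post_init__(self) -> None:
        if min(self.a, self.b, self.c, self.d) < 0:
            raise MorphologyError("contingency cells must be non-negative")

    @classmethod
    def from_margins(cls, events_exposed, n_exposed, events_unexposed, n_unexposed):
        return cls(
            a=events_exposed,
            b=n_exposed - events_exposed,
            c=events_unexposed,
            d=n_unexposed - events_unexposed,
        )

    def as_array(self) -> np.ndarray:
        return np.array([[self.a, self.b], [self.c, self.d]], dtype=float)


@dataclass
class ORResult:
    odds_ratio: float
    ci_low: float
    ci_high: float
    method: str
    chi2: float
    p: float


def odds_ratio(table: ContingencyTable2x2, haldane: bool = False) -> ORResult:
    """Cross-product odds ratio (a*d)/(b*c) with 95% Woolf/Wald CI.

    A zero cell makes the OR or its CI degenerate; pass ``haldane=True`` to
    apply the Haldane-Anscombe +0.5 correction (off by default; the method
    tag records it). The Pearson chi-square statistic and p for the same
    table are attached.
    """
    a, b, c, d = table.a, table.b, table.c, table.d
    method = "woolf_wald"
    if min(a, b, c, d) == 0:
        if not haldane:
            raise MorphologyError(
                "zero cell in 2x2 table; pass haldane=True for the +0.5 correction"
            )
        a, b, c, d = a + 0.5, b + 0.5, c + 0.5, d + 0.5
        method = "woolf_wald_haldane"
    orat = (a * d) / (b * c)
    se = np.sqrt(1.0 / a + 1.0 / b + 1.0 / c + 1.0 / d)
    lo, hi = np.exp(np.log(orat) - 1.96 * se), np.exp(np.log(orat) + 1.96 * se)
    chi2, p = chi_square(table.as_array())
    return ORResult(float(orat), float(lo), float(hi), method, chi2, p)


def chi_square(table, yates: bool = False) -> tuple[float, float]:
    """Pearson chi-square on a 2xk table (no continuity correction by
    default; Yates behind the flag). Zero expected counts are an error."""
    arr = np.asarray(table, dtype=float)
    if arr.ndim != 2 or arr.shape[0] != 2:
        raise MorphologyError("chi_square expects a 2 x k table")
    row = arr.sum(axis=1, keepdims=True)
    col = arr.sum(axis=0, keepdims=True)
    expected = row @ col / arr.sum()
    if (expected <= 0).any():
        raise MorphologyError("zero expected count; chi-square undefined")
    chi2, p, _, _ = stats.chi2_contingency(arr, correction=yates)
    return float(chi2), float(p)


# ---------------------------------------------------------------------------
# logistic regression + VIF
# ---------------------------------------------------------------------------


@dataclass
class LogisticFit:
    params: pd.Series
    bse: pd.Series
    ci_low: pd.Series
    ci_high: pd.Series
    odds_ratios: pd.Series
    converged: bool
    iterations: int


def logistic_fit(design: pd.DataFrame, outcome, max_iter: int = 100) -> LogisticFit:
    """Maximum-likelihood logistic regression (Newton/IRLS via statsmodels).

    ``design`` must contain an intercept column (add one with
    ``sm.add_constant``). For a single binary covariate the exponentiated
    coefficient equals the sample odds ratio. Complete separation — detected
    as a diverging coefficient — raises SeparationError.
    """
    y = np.asarray(outcome, dtype=float)
    X = design.astype(float)
    if X.shape[0] <= X.shape[1]:
        raise MorphologyError("need more observations than covariates")
    const = X.nunique(axis=0) == 1
    non_intercept_const = [c for c in X.columns[const] if not X[c].eq(1).all()]
    if non_intercept_const:
        raise MorphologyError(f"constant covariate(s): {non_intercept_const}")
    try:
        import warnings

        with warnings.catch_warnings():
            warnings.simplefilter("ignore", sm.tools.sm_exceptions.PerfectSeparationWarning)
            result = sm.Logit(y, X).fit(disp=0, maxiter=max_iter, method="newton")
    except (np.linalg.LinAlgError, sm.tools.sm_exceptions.PerfectSeparationError) as exc:
        raise SeparationError(f"logistic fit failed: {exc}") from exc
    if np.abs(result.params).max() > SEPARATION_COEF_LIMIT:
        raise SeparationError(
            "complete separation suspected: "
            f"|coefficient| exceeds {SEPARATION_COEF_LIMIT}"
        )
    if not result.mle_retvals.get("converged", False):
        raise MorphologyError(
            f"logistic fit did not converge in {max_iter} iterations: {result.mle_retvals}"
        )
    conf = result.conf_int()
    return LogisticFit(
        params=result.params,
        bse=result.bse,
        ci_low=conf[0],
        ci_high=conf[1],
        odds_ratios=np.exp(result.params),
        converged=True,
        iterations=int(result.mle_retvals.get("iterations", 0)),
    )


def vif(design: pd.DataFrame, flag_level: float = VIF_FLAG_LEVEL) -> pd.DataFrame:
    """Variance inflation factor per non-intercept covariate.

    VIF_k = 1/(1 - R^2_k) from an OLS regression of covariate k on the other
    covariates (with intercept). Perfect collinearity yields an infinite VIF
    reported as a flagged sentinel rather than an error.
    """
    X = design.astype(float)
    cols = [c for c in X.columns if not X[c].eq(1).all()]
    if len(cols) < 2:
        raise MorphologyError("VIF needs >=2 non-intercept covariates")
    rows = []
    for col in cols:
        others = sm.add_constant(X[[c for c in cols if c != col]])
        r2 = sm.OLS(X[col], others).fit().rsquared
        value = np.inf if r2 >= 1.0 - 1e-12 else 1.0 / (1.0 - r2)
        rows.append((col, value, value >= flag_level))
    return pd.DataFrame(rows, columns=["covariate", "vif", "flagged"]).set_index("covariate")


# ---------------------------------------------------------------------------
# cohort annotation helpers
# ---------------------------------------------------------------------------


def read_annotation_csv(path: str) -> pd.DataFrame:
    """Read a cohort annotation CSV (sample_id index; foci column holds
    semicolon-joined per-slide counts). Derives til_score when absent."""
    ann = pd.read_csv(path, index_col="sample_id")
    if "foci" in ann.columns and "til_score" not in ann.columns:
        ann["til_score"] = ann["foci"].map(
            lambda s: aggregate_til_score(parse_foci(s))
        )
    return ann


def parse_foci(serialized: str) -> list[int]:
    return [int(tok) for tok in str(serialized).split(";") if tok != ""]


def recurrence_table(
    annotation: pd.DataFrame, covariate: str, high_level: str, scheme: str | None = None
) -> ContingencyTable2x2:
    """2x2 table of a binary covariate against recurrence.

    For ``covariate='til_score'`` pass a dichotomization ``scheme``; for
    other covariates ``high_level`` names the exposed level.
    """
    if covariate == "til_score":
        if scheme is None:
            raise MorphologyError("til_score requires a dichotomization scheme")
        exposure = annotation["til_score"].map(lambda s: dichotomize(int(s), scheme))
        high_level = "high"
    else:
        exposure = annotation[covariate].astype(str)
    event = annotation["recurrence"].astype(str) == "recurrent"
    exposed = exposure == high_level
    return ContingencyTable2x2(
        a=int((exposed & event).sum()),
        b=int((exposed & ~event).sum()),
        c=int((~exposed & event).sum()),
        d=int((~exposed & ~event).sum()),
    )


# ---------------------------------------------------------------------------
# published cohort cross-tabulations
# ---------------------------------------------------------------------------

#: Published UAB/FCCC cross-tabulations: per stratum (n_total, n_recurrent).
#: TIL strata are keyed by score; binary covariates by level.
COHORT_TABLES: dict[str, dict] = {
    "UAB": {
        "n": 159,
        "til": {0: (10, 0), 1: (56, 7), 2: (30, 9), 3: (33, 7), 4: (30, 10)},
        "necrosis": {"yes": (48, 18), "no": (111, 15)},
        "grade": {"3-4": (116, 27), "1-2": (43, 6)},
        "stage": {">T1": (97, 29), "T1": (62, 4)},
        "printed_or": {
            "til_cut2": 3.08, "til_cut3": 1.99,
            "necrosis": 3.8, "grade": 8.2, "stage": 6.11,
        },
    },
    "FCCC": {
        "n": 198,
        "til": {0: (27, 5), 1: (44, 10), 2: (48, 9), 3: (31, 10), 4: (48, 19)},
        "necrosis": {"yes": (61, 28), "no": (137, 25)},
        "grade": {"3-4": (140, 44), "1-2": (58, 9)},
        "stage": {">T1": (109, 36), "T1": (89, 17)},
        "printed_or": {
            "til_cut2": 1.59, "til_cut3": 2.29,
            "necrosis": 3.5, "grade": 2.48, "stage": 2.62,
        },
    },
}


def cohort_til_table(cohort: str, scheme: str) -> ContingencyTable2x2:
    """Collapse a cohort's TIL score distribution into a 2x2 table under a
    dichotomization scheme."""
    strata = COHORT_TABLES[cohort]["til"]
    cut = 2 if scheme == "cut2" else 3 if scheme == "cut3" else None
    if cut is None:
        raise MorphologyError(f"unknown scheme {scheme!r}")
    n_hi = sum(n for s, (n, _) in strata.items() if s >= cut)
    r_hi = sum(r for s, (_, r) in strata.items() if s >= cut)
    n_lo = sum(n for s, (n, _) in strata.items() if s < cut)
    r_lo = sum(r for s, (_, r) in strata.items() if s < cut)
    return ContingencyTable2x2.from_margins(r_hi, n_hi, r_lo, n_lo)


def cohort_covariate_table(cohort: str, covariate: str) -> ContingencyTable2x2:
    """2x2 recurrence table for a bundled binary covariate (exposed level is
    the risk level: necrosis yes, grade 3-4, stage >T1)."""
    strata = COHORT_TABLES[cohort][covariate]
    (hi_level, (n_hi, r_hi)), (lo_level, (n_lo, r_lo)) = strata.items()
    return ContingencyTable2x2.from_margins(r_hi, n_hi, r_lo, n_lo)
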