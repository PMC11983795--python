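"""Interaction OLS models with a fixed-budget Bonferroni correction.

Each model regresses the epigenetic prediction on the phenotype, the
modifier (race/ethnicity with NH White reference, or sex with female
reference), their interaction, and covariates.  The phenotype main effect is
the reference-group slope on the converted natural scale; each interaction
term is the additional slope in that group.

Adjustment levels:

* ``minimal`` — adds the other demographic variable (sex for race models,
  race/ethnicity for sex models);
* ``full``    — additionally adjusts for education, poverty-to-income ratio
  and the six DNAm cell-proportion estimates, and is refused for
  cell-proportion predictors.

The Bonferroni budget is a fixed constant: 150 tests for minimally adjusted
models (15 predictors x 5 race/ethnicity groups x 2 sex groups) and 120 for
fully adjusted models (12 non-cell predictors x 5 x 2); ``m_tests``
overrides it for reuse outside that design.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.formula.api as smf

from .qc_conversions import AnalysisSet, DNAM_CELL_COLUMNS

__all__ = [
    "RegressionFit",
    "fit_interaction_model",
    "bonferroni",
    "significance_tiers",
    "MINIMAL_TEST_BUDGET",
    "FULL_TEST_BUDGET",
    "REFERENCE_GROUPS",
]

MINIMAL_TEST_BUDGET = 150
FULL_TEST_BUDGET = 120

REFERENCE_GROUPS = {"race_ethnicity": "NH White", "sex": "female"}

_TERM_ROLES = ("phenotype_main", "group_main", "interaction", "covariate", "intercept")


@dataclass
class RegressionFit:
    predictor: str
    modifier: str
    adjustment: str
    reference_group: str
    table: pd.DataFrame  # index: term; columns: role, group, estimate, ci_low, ci_high, p_unadjusted, p_bonferroni
    n_used: int
    n_dropped_missing: int
    m_tests: int
    rsquared: float
    results: object = field(default=None, repr=False, compare=False)

    def term(self, role: str, group: str | None = None) -> pd.Series:
        """Fetch the single coefficient row with the given role (and group)."""
        sub = self.table[self.table["role"] == role]
        if group is not None:
            sub = sub[sub["group"] == group]
        if len(sub) != 1:
            raise KeyError(f"expected exactly one term with role={role!r} group={group!r}")
        return sub.iloc[0]


def bonferroni(p: float, m: int) -> float:
    """min(1, p * m)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    if int(m) != m or m < 1:
        raise ValueError("m must be a positive integer")
    return min(1.0, float(p) * int(m))


def _classify(term: str, modifier: str) -> tuple[str, str]:
    """(role, group) for one design-matrix term name."""
    if term == "Intercept":
        return "intercept", ""
    if ":" in term:
        if "phenotype" in term and f"C({modifier}" in term:
            return "interaction", _dummy_level(term)
        return "covariate", ""
    if term == "phenotype":
        return "phenotype_main", ""
    if term.startswith(f"C({modifier}"):
        return "group_main", _dummy_level(term)
    return "covariate", ""


def _dummy_level(term: str) -> str:
    # e.g. "C(race_ethnicity, Treatment('NH White'))[T.NH Black]:phenotype"
    start = term.find("[T.")
    if start == -1:
        return ""
    return term[start + 3 : term.find("]", start)]


def fit_interaction_model(
    analysis_set: AnalysisSet,
    modifier: str,
    adjustment: str = "minimal",
    alpha: float = 0.05,
    m_tests: int | None = None,
) -> RegressionFit:
    """Fit one interaction model and return its tidy coefficient table.

    Rows with missing covariates are dropped listwise for this model only and
    counted in ``n_dropped_missing``.  Wald 95% confidence intervals come
    from the OLS covariance.
    """
    if modifier not in REFERENCE_GROUPS:
        raise ValueError(f"modifier must be one of {sorted(REFERENCE_GROUPS)}")
    if adjustment not in ("minimal", "full"):
        raise ValueError(f"unknown adjustment {adjustment!r}")
    spec = analysis_set.spec
    if adjustment == "full" and spec.family == "cell":
        raise ValueError(
            "full adjustment is not defined for cell-proportion predictors "
            "(they are excluded from the fully adjusted analysis)"
        )

    reference = REFERENCE_GROUPS[modifier]
    other = "sex" if modifier == "race_ethnicity" else "race_ethnicity"
    needed = ["prediction", "phenotype", modifier, other]
    if adjustment == "full":
        needed += ["education", "pir", *DNAM_CELL_COLUMNS]
    missing_cols = [c for c in needed if c not in analysis_set.frame.columns]
    if missing_cols:
        raise ValueError(f"analysis set lacks required columns: {missing_cols}")

    data = analysis_set.frame[needed].copy()
    n0 = len(data)
    data = data.dropna()
    n_dropped = n0 - len(data)

    if reference not in set(data[modifier]):
        raise ValueError(f"empty reference category {reference!r} for modifier {modifier!r}")
    counts = data[modifier].value_counts()
    empty = [lvl for lvl, c in counts.items() if c == 0]
    if empty:
        raise ValueError(f"empty modifier categories: {empty}")

    formula = (
        f"prediction ~ phenotype * C({modifier}, Treatment({reference!r}))"
        f" + C({other}, Treatment({REFERENCE_GROUPS[other]!r}))"
    )
    if adjustment == "full":
        formula += " + C(education) + pir + " + " + ".join(DNAM_CELL_COLUMNS)

    results = smf.ols(formula, data=data).fit()
    m = m_tests if m_tests is not None else (
        MINIMAL_TEST_BUDGET if adjustment == "minimal" else FULL_TEST_BUDGET
    )

    conf = results.conf_int(alpha=alpha)
    rows = []
    for term in results.params.index:
        role, group = _classify(term, modifier)
        p = float(results.pvalues[term])
        rows.append(
            {
                "term": term,
                "role": role,
                "group": group,
                "estimate": float(results.params[term]),
                "ci_low": float(conf.loc[term, 0]),
                "ci_high": float(conf.loc[term, 1]),
                "p_unadjusted": p,
                "p_bonferroni": bonferroni(min(max(p, 0.0), 1.0), m),
            }
        )
    table = pd.DataFrame(rows).set_index("term")
    return RegressionFit(
        predictor=spec.name,
        modifier=modifier,
        adjustment=adjustment,
        reference_group=reference,
        table=table,
        n_used=int(results.nobs),
        n_dropped_missing=n_dropped,
        m_tests=m,
        rsquared=float(results.rsquared),
        results=results,
    )


def significance_tiers(fit: RegressionFit, alpha: float = 0.05) -> pd.Series:
    """Per-term tier: ``significant`` (Bonferroni p < alpha), ``suggestive``
    (unadjusted p < alpha only), else ``null``."""
    def tier(row: pd.Series) -> str:
        if row["p_bonferroni"] < alpha:
            return "significant"
        if row["p_unadjusted"] < alpha:
            return "suggestive"
        return "null"

    return fit.table.apply(tier, axis=1).rename("tier")
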