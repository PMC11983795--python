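"""Exclusion rules, unit conversions, and derived-variable construction.

This module turns a raw participant table into per-predictor analysis sets:
paired (phenotype, prediction) vectors with strata and covariates, plus a
full audit trail of every removed record and the reason it was removed.

Rules implemented:

* removal of participants whose DNAm-predicted sex disagrees with reported sex;
* removal of top-coded ages (exactly 85) for predictors that target
  chronological age;
* per-measure exclusion of missing laboratory values;
* exclusion of laboratory values >= ``k`` standard deviations from the mean
  on the log scale (default ``k = 3``), applied to laboratory-derived
  phenotypes only, never to DNAm predictions;
* unit conversion of telomere T/S ratios to kilobase pairs;
* exponentiation of log-scale CRP / HbA1c predictions;
* aggregation of B + CD4 + CD8 DNAm proportions into a total-lymphocyte
  prediction.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PredictorSpec",
    "QCReport",
    "AnalysisSet",
    "DEFAULT_SPECS",
    "spec_by_name",
    "validate_spec_set",
    "exclude_sex_mismatch",
    "exclude_topcoded_age",
    "ts_to_kbp",
    "aggregate_lymphocytes",
    "filter_log_outliers",
    "exponentiate_predictions",
    "build_analysis_set",
    "apply_global_qc",
]

TOPCODED_AGE = 85.0

#: DNAm cell-proportion columns summed into the total-lymphocyte prediction.
LYMPHOCYTE_COMPONENTS = ("dnam_b", "dnam_cd4t", "dnam_cd8t")

#: All six DNAm cell-proportion columns (used as covariates in full models).
DNAM_CELL_COLUMNS = (
    "dnam_cd8t",
    "dnam_cd4t",
    "dnam_nk",
    "dnam_b",
    "dnam_monocyte",
    "dnam_neutrophil",
)

CLOCK_NAMES = (
    "horvath",
    "hannum",
    "skin_blood",
    "lin",
    "weidner",
    "vidal_bralo",
    "zhang",
)

_COVARIATE_COLUMNS = (
    "id",
    "race_ethnicity",
    "sex",
    "education",
    "pir",
) + DNAM_CELL_COLUMNS


@dataclass(frozen=True)
class PredictorSpec:
    """Metadata binding one DNAm prediction to its target phenotype.

    Parameters
    ----------
    name
        Short predictor label (e.g. ``"hannum"``, ``"cystatin_c"``).
    prediction_column, phenotype_column
        Column names in the participant table.  For the total-lymphocyte
        predictor the prediction column is derived by summing
        :data:`LYMPHOCYTE_COMPONENTS`.
    prediction_transform
        ``"identity"`` or ``"exponentiate"`` (log-scale CRP / HbA1c
        predictions are exponentiated before analysis).
    phenotype_transform
        ``"identity"``, ``"ts_to_kbp"`` (telomere) or ``"sum_lymphocytes"``
        (marks the predictor whose prediction is the B + CD4 + CD8 sum).
    uses_age
        True only for chronological-age predictors; triggers top-coded-age
        exclusion.
    units
        Display units of the converted phenotype scale.
    family
        One of ``clock``, ``telomere``, ``protein``, ``cell``.
    """

    name: str
    prediction_column: str
    phenotype_column: str
    prediction_transform: str = "identity"
    phenotype_transform: str = "identity"
    uses_age: bool = False
    units: str = ""
    family: str = "clock"

    def __post_init__(self) -> None:
        if self.prediction_transform not in ("identity", "exponentiate"):
            raise ValueError(f"unknown prediction_transform {self.prediction_transform!r}")
        if self.phenotype_transform not in ("identity", "ts_to_kbp", "sum_lymphocytes"):
            raise ValueError(f"unknown phenotype_transform {self.phenotype_transform!r}")
        if self.family not in ("clock", "telomere", "protein", "cell"):
            raise ValueError(f"unknown family {self.family!r}")
        if self.prediction_transform == "exponentiate" and self.name not in ("crp", "hba1c"):
            raise ValueError("exponentiate transform is reserved for crp and hba1c")
        if self.phenotype_transform == "ts_to_kbp" and self.name != "dnamtl":
            raise ValueError("ts_to_kbp transform is reserved for dnamtl")
        if self.phenotype_transform == "sum_lymphocytes" and self.name != "lymphocytes":
            raise ValueError("sum_lymphocytes transform is reserved for lymphocytes")
        if self.uses_age != (self.family == "clock"):
            raise ValueError("uses_age must hold exactly for chronological-age predictors")


def _clock(name: str) -> PredictorSpec:
    return PredictorSpec(
        name=name,
        prediction_column=f"dnam_{name}",
        phenotype_column="age_years",
        uses_age=True,
        units="years",
        family="clock",
    )


#: The default 15-predictor spec set: 7 age predictors, the telomere-length
#: estimator, 4 plasma-protein predictors, and 3 cell-proportion predictors.
DEFAULT_SPECS: tuple[PredictorSpec, ...] = tuple(
    [_clock(n) for n in CLOCK_NAMES]
    + [
        PredictorSpec(
            name="dnamtl",
            prediction_column="dnamtl_kbp",
            phenotype_column="telomere_ts_ratio",
            phenotype_transform="ts_to_kbp",
            units="kbp",
            family="telomere",
        ),
        PredictorSpec(
            name="b2m",
            prediction_column="dnam_b2m",
            phenotype_column="b2m_mg_l",
            units="mg/L",
            family="protein",
        ),
        PredictorSpec(
            name="crp",
            prediction_column="dnam_log_crp",
            phenotype_column="crp_mg_l",
            prediction_transform="exponentiate",
            units="mg/L",
            family="protein",
        ),
        PredictorSpec(
            name="cystatin_c",
            prediction_column="dnam_cystatin_c",
            phenotype_column="cystatin_c_mg_l",
            units="mg/L",
            family="protein",
        ),
        PredictorSpec(
            name="hba1c",
            prediction_column="dnam_log_hba1c",
            phenotype_column="hba1c_pct",
            prediction_transform="exponentiate",
            units="%",
            family="protein",
        ),
        PredictorSpec(
            name="lymphocytes",
            prediction_column="dnam_lymphocytes",
            phenotype_column="lymphocyte_prop",
            phenotype_transform="sum_lymphocytes",
            units="proportion",
            family="cell",
        ),
        PredictorSpec(
            name="monocytes",
            prediction_column="dnam_monocyte",
            phenotype_column="monocyte_prop",
            units="proportion",
            family="cell",
        ),
        PredictorSpec(
            name="neutrophils",
            prediction_column="dnam_neutrophil",
            phenotype_column="neutrophil_prop",
            units="proportion",
            family="cell",
        ),
    ]
)

PREDICTOR_NAMES: tuple[str, ...] = tuple(s.name for s in DEFAULT_SPECS)


def spec_by_name(name: str) -> PredictorSpec:
    for spec in DEFAULT_SPECS:
        if spec.name == name:
            return spec
    raise KeyError(f"unknown predictor {name!r}")


def validate_spec_set(specs: Sequence[PredictorSpec]) -> None:
    """Check set-level invariants (uses_age exactly for the clocks, etc.)."""
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("duplicate predictor names in spec set")
    for spec in specs:
        if spec.uses_age and spec.name not in CLOCK_NAMES:
            raise ValueError(f"uses_age set for non-clock predictor {spec.name}")


# ---------------------------------------------------------------------------
# QC report
# ---------------------------------------------------------------------------


@dataclass
class QCReport:
    """Removal audit for one QC pass.

    ``counts`` maps rule name -> number of rows failing that rule; a row can
    fail several rules, so the sum of counts may exceed the number of
    distinct removed rows (``n_removed_distinct``).
    """

    n_in: int = 0
    n_out: int = 0
    counts: dict = field(default_factory=dict)
    removed: dict = field(default_factory=dict)  # rule -> list of ids
    unanalysable_strata: list = field(default_factory=list)

    def record(self, rule: str, ids: Iterable) -> None:
        ids = list(ids)
        self.counts[rule] = self.counts.get(rule, 0) + len(ids)
        self.removed.setdefault(rule, []).extend(ids)

    @property
    def n_removed_distinct(self) -> int:
        distinct: set = set()
        for ids in self.removed.values():
            distinct.update(ids)
        return len(distinct)

    def to_dict(self) -> dict:
        return {
            "n_in": self.n_in,
            "n_out": self.n_out,
            "n_removed_distinct": self.n_removed_distinct,
            "counts": dict(self.counts),
            "unanalysable_strata": list(self.unanalysable_strata),
        }

    def to_text(self) -> str:
        lines = [f"rows in\t{self.n_in}", f"rows out\t{self.n_out}"]
        for rule in sorted(self.counts):
            lines.append(f"{rule}\t{self.counts[rule]}")
        if self.unanalysable_strata:
            lines.append("unanalysable strata\t" + ", ".join(map(str, self.unanalysable_strata)))
        return "\n".join(lines)


@dataclass
class AnalysisSet:
    """Paired analysis-ready data for one predictor.

    ``frame`` holds converted ``phenotype`` and ``prediction`` columns plus
    whatever strata / covariate columns were available in the input.
    """

    spec: PredictorSpec
    frame: pd.DataFrame
    report: QCReport

    @property
    def phenotype(self) -> np.ndarray:
        return self.frame["phenotype"].to_numpy(float)

    @property
    def prediction(self) -> np.ndarray:
        return self.frame["prediction"].to_numpy(float)


# ---------------------------------------------------------------------------
# Individual rules and conversions
# ---------------------------------------------------------------------------


def _row_ids(table: pd.DataFrame, mask: np.ndarray) -> list:
    if "id" in table.columns:
        return table.loc[mask, "id"].tolist()
    return table.index[mask].tolist()


def exclude_sex_mismatch(table: pd.DataFrame) -> tuple[pd.DataFrame, QCReport]:
    """Drop rows whose DNAm-predicted sex differs from reported sex."""
    for col in ("sex", "dnam_predicted_sex"):
        if col not in table.columns:
            raise ValueError(f"missing required column {col!r}")
    report = QCReport(n_in=len(table))
    mismatch = (table["sex"] != table["dnam_predicted_sex"]).to_numpy()
    report.record("sex_mismatch", _row_ids(table, mismatch))
    kept = table.loc[~mismatch]
    report.n_out = len(kept)
    if len(kept) == 0 and len(table) > 0:
        warnings.warn("all rows removed by sex-mismatch rule", stacklevel=2)
    return kept, report


def exclude_topcoded_age(table: pd.DataFrame) -> tuple[pd.DataFrame, QCReport]:
    """Drop rows with top-coded (== 85) age.

    Scoped by the caller to predictors with ``uses_age=True``; the rule never
    applies to telomere, protein, or cell analyses.
    """
    if "age_years" not in table.columns:
        raise ValueError("missing required column 'age_years'")
    report = QCReport(n_in=len(table))
    if "age_topcoded" in table.columns:
        top = table["age_topcoded"].astype(bool).to_numpy()
    else:
        top = (table["age_years"] >= TOPCODED_AGE).to_numpy()
    report.record("topcoded_age", _row_ids(table, top))
    kept = table.loc[~top]
    report.n_out = len(kept)
    return kept, report


def ts_to_kbp(ts):
    """Convert telomere T/S ratio to kilobase pairs: (3274 + 2413*ts)/1000.

    Accepts scalars or arrays; NaN propagates; negative ratios are an error.
    """
    arr = np.asarray(ts, dtype=float)
    if np.any(arr[~np.isnan(arr)] < 0):
        raise ValueError("negative T/S ratio")
    out = (3274.0 + 2413.0 * arr) / 1000.0
    if np.isscalar(ts) or arr.ndim == 0:
        return float(out)
    return out


def aggregate_lymphocytes(b, cd4, cd8):
    """Total-lymphocyte prediction: sum of B, CD4 and CD8 DNAm proportions.

    Missing components propagate to a missing sum.  Components outside
    [0, 1] are an error; a sum above 1 is allowed (noisy deconvolution) but
    triggers a warning.
    """
    b, cd4, cd8 = (np.asarray(v, dtype=float) for v in (b, cd4, cd8))
    for comp in (b, cd4, cd8):
        finite = comp[~np.isnan(comp)]
        if np.any((finite < 0) | (finite > 1)):
            raise ValueError("cell proportion outside [0, 1]")
    total = b + cd4 + cd8
    if np.any(total[~np.isnan(total)] > 1):
        warnings.warn("lymphocyte proportion sum exceeds 1", stacklevel=2)
    if total.ndim == 0:
        return float(total)
    return total


@dataclass
class OutlierResult:
    keep: np.ndarray          # True where the value survives the rule
    n_outlier: int
    n_missing: int
    n_nonpositive: int
    outlier_mask: np.ndarray  # True exactly where the rule fired
    nonpositive_mask: np.ndarray


def filter_log_outliers(values, k: float = 3.0, nonpositive: str = "error") -> OutlierResult:
    """Flag values >= ``k`` standard deviations from the mean on the log scale.

    The mean and SD are computed once over all non-missing positive values
    (single pass, no iterative re-filtering).  The ``>= k`` comparison is
    inclusive.  If the log-scale SD is zero the rule is vacuous and removes
    nothing.  Missing entries are counted as missing, not outliers.

    ``nonpositive`` controls values where the log is undefined: ``"error"``
    (default) raises, ``"exclude"`` drops them with their own reason count.
    """
    if k <= 0:
        raise ValueError("k must be positive")
    if nonpositive not in ("error", "exclude"):
        raise ValueError("nonpositive must be 'error' or 'exclude'")
    v = np.asarray(values, dtype=float)
    missing = np.isnan(v)
    nonpos = (~missing) & (v <= 0)
    if nonpos.any():
        if nonpositive == "error":
            raise ValueError("non-positive value where log is required")
    usable = (~missing) & (~nonpos)
    outlier = np.zeros_like(missing)
    if usable.sum() >= 2:
        logs = np.log(v[usable])
        mu = logs.mean()
        sd = logs.std(ddof=1)
        if sd > 0:
            z = np.abs(np.log(v[usable]) - mu) / sd
            out_usable = z >= k
            idx = np.flatnonzero(usable)
            outlier[idx[out_usable]] = True
    keep = usable & (~outlier)
    return OutlierResult(
        keep=keep,
        n_outlier=int(outlier.sum()),
        n_missing=int(missing.sum()),
        n_nonpositive=int(nonpos.sum()),
        outlier_mask=outlier,
        nonpositive_mask=nonpos,
    )


def exponentiate_predictions(table: pd.DataFrame, spec: PredictorSpec) -> pd.DataFrame:
    """Replace a log-scale prediction column by its exponential.

    No-op for identity-transform specs.
    """
    if spec.prediction_transform != "exponentiate":
        return table
    out = table.copy()
    out[spec.prediction_column] = np.exp(out[spec.prediction_column].to_numpy(float))
    return out


def apply_global_qc(table: pd.DataFrame) -> tuple[pd.DataFrame, QCReport]:
    """QC applied once to the whole table (sex-mismatch removal)."""
    return exclude_sex_mismatch(table)


# ---------------------------------------------------------------------------
# Analysis-set construction
# ---------------------------------------------------------------------------


def build_analysis_set(
    table: pd.DataFrame,
    spec: PredictorSpec,
    k_outlier: float = 3.0,
    min_stratum_n: int = 3,
) -> AnalysisSet:
    """Compose all per-predictor QC rules and conversions.

    The input table is expected to have already passed global QC
    (sex-mismatch removal).  Steps, in order: top-coded-age exclusion (only
    if ``spec.uses_age``), derived-prediction construction, missing-value
    exclusion, log-scale outlier exclusion of the laboratory phenotype (never
    applied to chronological age or to DNAm predictions), then unit
    conversions.  Every removal is recorded in the returned
    :class:`QCReport`.
    """
    report = QCReport(n_in=len(table))
    work = table

    if spec.uses_age:
        work, sub = exclude_topcoded_age(work)
        report.record("topcoded_age", sub.removed.get("topcoded_age", []))

    # Derived / transformed prediction column
    if spec.phenotype_transform == "sum_lymphocytes":
        missing_comp = [c for c in LYMPHOCYTE_COMPONENTS if c not in work.columns]
        if missing_comp:
            raise ValueError(f"missing lymphocyte component columns: {missing_comp}")
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            prediction = aggregate_lymphocytes(
                work[LYMPHOCYTE_COMPONENTS[0]],
                work[LYMPHOCYTE_COMPONENTS[1]],
                work[LYMPHOCYTE_COMPONENTS[2]],
            )
        prediction = np.asarray(prediction, dtype=float)
    else:
        if spec.prediction_column not in work.columns:
            raise ValueError(f"missing prediction column {spec.prediction_column!r}")
        prediction = work[spec.prediction_column].to_numpy(float)
        if spec.prediction_transform == "exponentiate":
            prediction = np.exp(prediction)

    if spec.phenotype_column not in work.columns:
        raise ValueError(f"missing phenotype column {spec.phenotype_column!r}")
    phenotype = work[spec.phenotype_column].to_numpy(float)

    miss_ph = np.isnan(phenotype)
    miss_pr = np.isnan(prediction)
    report.record("missing_phenotype", _row_ids(work, miss_ph))
    report.record("missing_prediction", _row_ids(work, miss_pr & ~miss_ph))

    # Outlier rule: laboratory-derived phenotypes only.
    outlier = np.zeros(len(work), dtype=bool)
    nonpos = np.zeros(len(work), dtype=bool)
    if spec.family != "clock":
        policy = "exclude" if spec.family == "cell" else "error"
        res = filter_log_outliers(phenotype, k=k_outlier, nonpositive=policy)
        outlier = res.outlier_mask
        nonpos = res.nonpositive_mask
        report.record("outlier", _row_ids(work, outlier))
        if nonpos.any():
            report.record("nonpositive_for_log", _row_ids(work, nonpos))

    drop = miss_ph | miss_pr | outlier | nonpos
    kept = work.loc[~drop]
    phenotype = phenotype[~drop]
    prediction = prediction[~drop]

    if spec.phenotype_transform == "ts_to_kbp":
        phenotype = ts_to_kbp(phenotype)

    frame = pd.DataFrame({"phenotype": phenotype, "prediction": prediction}, index=kept.index)
    for col in _COVARIATE_COLUMNS:
        if col in kept.columns:
            frame[col] = kept[col].to_numpy()

    report.n_out = len(frame)
    if "race_ethnicity" in frame.columns:
        for label, grp in frame.groupby("race_ethnicity", observed=True):
            if len(grp) < min_stratum_n:
                report.unanalysable_strata.append(str(label))
                warnings.warn(
                    f"stratum {label!r} has fewer than {min_stratum_n} analysable rows "
                    f"for predictor {spec.name!r}",
                    stacklevel=2,
                )
    return AnalysisSet(spec=spec, frame=frame, report=report)
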