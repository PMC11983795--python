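"""Synthetic participant-table generator with controllable statistical truth.

Generates cohorts that structurally mimic a two-cycle national survey DNAm
subsample: five self-reported race/ethnicity groups with fixed sizes, an
approximately even sex split, ages 50-84 with a configurable number of
top-coded (== 85) records, log-normal laboratory measures paired with
DNAm-derived predictions at known per-group correlation and bias, injected
extreme outliers, sex-prediction mismatches, and per-measure missingness.

Every defect is injected at an exactly known count on globally disjoint row
sets, so the downstream QC audit can be checked against the configuration to
the row.  Laboratory log draws are truncated at +/-2.5 generating SDs, which
guarantees that the >= 3-SD log-scale outlier rule fires on exactly the
injected rows and never on a natural draw.

Predictions are constructed so that the configured correlation holds on the
*analysis* scale (after the QC module's conversions): clock predictions
against age in years, the telomere estimator against the T/S ratio (the
kilobase conversion is affine, so r is unchanged), protein predictions
against natural-scale concentrations (CRP / HbA1c predictions are stored on
the log scale and exponentiated downstream, an exact round trip), and the
total-lymphocyte prediction as a Dirichlet split of a correlated sum.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, asdict
from typing import Mapping

import numpy as np
import pandas as pd
import yaml
from scipy.stats import truncnorm

from .qc_conversions import (
    DEFAULT_SPECS,
    PREDICTOR_NAMES,
    filter_log_outliers,
    spec_by_name,
)

__all__ = [
    "SimulationConfig",
    "generate_correlated_pair",
    "simulate_population",
    "truth_table",
    "write_population",
    "read_population",
    "write_config",
    "read_config",
    "RACE_LABELS",
    "SEX_LABELS",
    "EDUCATION_LEVELS",
]

RACE_LABELS = (
    "Mexican American",
    "Other Hispanic",
    "NH White",
    "NH Black",
    "Other/Multiracial",
)
SEX_LABELS = ("male", "female")
EDUCATION_LEVELS = (
    "<9th grade",
    "9-11th grade",
    "High school/GED",
    "Some college/AA",
    "College graduate+",
    "don't know",
)

DEFAULT_GROUP_SIZES = {
    "Mexican American": 694,
    "Other Hispanic": 159,
    "NH White": 1005,
    "NH Black": 533,
    "Other/Multiracial": 81,
}

#: Laboratory measures: log-normal (location, scale) on the log scale.
#: Placeholders — the source survey's within-group lab distributions are not
#: published, so these are loosely realistic defaults, not estimates.
DEFAULT_LAB_DISTRIBUTIONS = {
    "b2m": (0.55, 0.25),
    "cystatin_c": (-0.10, 0.22),
    "crp": (0.70, 1.00),
    "hba1c": (1.70, 0.10),
    "telomere": (0.00, 0.25),
    "lymphocytes": (-1.20, 0.18),
    "monocytes": (-2.59, 0.20),
    "neutrophils": (-0.545, 0.12),
}

#: Column holding each laboratory measure.
MEASURE_COLUMNS = {
    "b2m": "b2m_mg_l",
    "cystatin_c": "cystatin_c_mg_l",
    "crp": "crp_mg_l",
    "hba1c": "hba1c_pct",
    "telomere": "telomere_ts_ratio",
    "lymphocytes": "lymphocyte_prop",
    "monocytes": "monocyte_prop",
    "neutrophils": "neutrophil_prop",
}

#: Natural-scale (location, scale) of each prediction; clocks default to the
#: location/scale of the age vector they are generated against.
DEFAULT_PREDICTION_SCALES = {
    "dnamtl": (6.9, 0.60),
    "b2m": (1.8, 0.35),
    "crp": (2.5, 0.60),
    "cystatin_c": (0.95, 0.20),
    "hba1c": (5.6, 0.55),
    "lymphocytes": (0.30, 0.06),
    "monocytes": (0.075, 0.020),
    "neutrophils": (0.58, 0.07),
}

#: Default target correlations (overall-population values reported for these
#: predictor families in large survey samples).
DEFAULT_TARGET_CORRELATION = {
    "horvath": 0.80,
    "hannum": 0.82,
    "skin_blood": 0.87,
    "lin": 0.76,
    "weidner": 0.55,
    "vidal_bralo": 0.62,
    "zhang": 0.89,
    "dnamtl": 0.38,
    "b2m": 0.46,
    "crp": 0.35,
    "cystatin_c": 0.43,
    "hba1c": 0.41,
    "lymphocytes": 0.88,
    "monocytes": 0.75,
    "neutrophils": 0.88,
}

DEFAULT_N_OUTLIERS = {
    "cystatin_c": 39,
    "b2m": 43,
    "crp": 10,
    "hba1c": 63,
    "neutrophils": 27,
    "lymphocytes": 21,
    "monocytes": 22,
    "telomere": 13,
}

#: Per-measure missing counts; "cells" removes all three cell-proportion
#: measures jointly on the same rows.
DEFAULT_MISSINGNESS = {
    "cystatin_c": 28,
    "b2m": 31,
    "hba1c": 1,
    "telomere": 2,
    "cells": 13,
}

_MEASURE_FOR_PREDICTOR = {
    "dnamtl": "telomere",
    "b2m": "b2m",
    "crp": "crp",
    "cystatin_c": "cystatin_c",
    "hba1c": "hba1c",
    "lymphocytes": "lymphocytes",
    "monocytes": "monocytes",
    "neutrophils": "neutrophils",
}

# Natural log draws truncated at this many generating SDs; must stay below
# k_outlier * (truncated-sample SD / generating SD) so natural draws can
# never trip the 3-SD rule.
_TRUNC = 2.5
# Injected outliers sit at this many generating SDs on the log scale.
_INJECT_Z = 10.0


@dataclass
class SimulationConfig:
    """Full description of one synthetic cohort.

    Correlation and bias parameters accept a scalar (applied everywhere), a
    per-predictor mapping, or a per-predictor mapping of per-group mappings.
    ``None`` falls back to the documented defaults.
    """

    seed: int = 0
    group_sizes: dict = field(default_factory=lambda: dict(DEFAULT_GROUP_SIZES))
    sex_fraction_male: float = 1255 / 2472
    age_range: tuple = (50, 84)
    n_topcoded: int = 126
    n_sex_mismatch: int = 60
    predictors: tuple = PREDICTOR_NAMES
    target_correlation: object = None
    prediction_bias: object = None
    phenotype_distributions: dict = field(default_factory=lambda: dict(DEFAULT_LAB_DISTRIBUTIONS))
    prediction_scales: dict = field(default_factory=lambda: dict(DEFAULT_PREDICTION_SCALES))
    n_outliers: dict = field(default_factory=lambda: dict(DEFAULT_N_OUTLIERS))
    missingness: dict = field(default_factory=lambda: dict(DEFAULT_MISSINGNESS))

    # -- parameter resolution ------------------------------------------------

    def _resolve(self, value, predictor: str, group: str, default: float) -> float:
        if value is None:
            return default
        if isinstance(value, Mapping):
            sub = value.get(predictor, default)
            if isinstance(sub, Mapping):
                return float(sub.get(group, sub.get("default", default)))
            return float(sub)
        return float(value)

    def rho_for(self, predictor: str, group: str) -> float:
        return self._resolve(
            self.target_correlation, predictor, group, DEFAULT_TARGET_CORRELATION[predictor]
        )

    def bias_for(self, predictor: str, group: str) -> float:
        return self._resolve(self.prediction_bias, predictor, group, 0.0)

    # -- validation ----------------------------------------------------------

    def validate(self) -> None:
        for label, n in self.group_sizes.items():
            if n < 2:
                raise ValueError(f"group {label!r} must have at least 2 participants")
        if not 0.0 <= self.sex_fraction_male <= 1.0:
            raise ValueError("sex_fraction_male must be in [0, 1]")
        lo, hi = self.age_range
        if not (0 < lo <= hi < 85):
            raise ValueError("age_range must satisfy 0 < lo <= hi < 85")
        for name in self.predictors:
            if name not in PREDICTOR_NAMES:
                raise ValueError(f"unknown predictor {name!r}")
            for group in self.group_sizes:
                rho = self.rho_for(name, group)
                if not abs(rho) < 1.0:
                    raise ValueError(
                        f"target correlation for ({name}, {group}) must be strictly inside (-1, 1)"
                    )
        total = sum(self.group_sizes.values())
        n_defect = (
            self.n_topcoded
            + self.n_sex_mismatch
            + sum(self.n_outliers.values())
            + sum(self.missingness.values())
        )
        if n_defect > total:
            raise ValueError(
                f"infeasible counts: {n_defect} defects requested for {total} participants"
            )
        for key in self.n_outliers:
            if key not in MEASURE_COLUMNS:
                raise ValueError(f"unknown measure {key!r} in n_outliers")
        for key in self.missingness:
            if key not in MEASURE_COLUMNS and key != "cells":
                raise ValueError(f"unknown measure {key!r} in missingness")

    # -- (de)serialisation ---------------------------------------------------

    def to_dict(self) -> dict:
        d = asdict(self)
        d["age_range"] = list(self.age_range)
        d["predictors"] = list(self.predictors)
        for key in ("phenotype_distributions", "prediction_scales"):
            d[key] = {k: list(v) for k, v in d[key].items()}
        return d

    @classmethod
    def from_dict(cls, d: Mapping) -> "SimulationConfig":
        d = dict(d)
        if "age_range" in d:
            d["age_range"] = tuple(d["age_range"])
        if "predictors" in d:
            d["predictors"] = tuple(d["predictors"])
        for key in ("phenotype_distributions", "prediction_scales"):
            if key in d:
                d[key] = {k: tuple(v) for k, v in d[key].items()}
        return cls(**d)


# ---------------------------------------------------------------------------
# Correlated-pair construction
# ---------------------------------------------------------------------------


def generate_correlated_pair(
    x,
    rho: float,
    bias: float = 0.0,
    noise_seed=0,
    loc: float | None = None,
    scale: float | None = None,
) -> np.ndarray:
    """Generate predictions with expected Pearson correlation ``rho`` to ``x``.

    Construction: y = rho * z_x + sqrt(1 - rho^2) * z_noise, rescaled to the
    requested (or x's own) location/scale, plus ``bias``.  Deterministic for
    a fixed ``noise_seed``.
    """
    x = np.asarray(x, dtype=float)
    if x.size < 2:
        raise ValueError("need at least 2 phenotype values")
    if not abs(rho) < 1.0:
        raise ValueError("rho must be strictly inside (-1, 1)")
    sd = x.std()
    if sd == 0:
        raise ValueError("degenerate phenotype vector")
    rng = noise_seed if isinstance(noise_seed, np.random.Generator) else np.random.default_rng(noise_seed)
    zx = (x - x.mean()) / sd
    z = rho * zx + np.sqrt(1.0 - rho * rho) * rng.standard_normal(x.size)
    if loc is None:
        loc = x.mean()
    if scale is None:
        scale = sd
    return loc + scale * z + bias


# ---------------------------------------------------------------------------
# Population simulation
# ---------------------------------------------------------------------------


def _rng(seed: int, *spawn_key: int) -> np.random.Generator:
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=spawn_key))


def _trunc_lognormal(mu: float, sigma: float, n: int, rng: np.random.Generator) -> np.ndarray:
    z = truncnorm.rvs(-_TRUNC, _TRUNC, size=n, random_state=rng)
    return np.exp(mu + sigma * z)


def _clip_unit(v: np.ndarray) -> np.ndarray:
    return np.clip(v, 1e-6, 1.0 - 1e-6)


def simulate_population(config: SimulationConfig) -> pd.DataFrame:
    """Generate one participant table per the configuration.

    Row counts per group match ``group_sizes`` exactly, as do the counts of
    top-coded ages, sex-prediction mismatches, injected log-scale outliers
    and missing values.  All defect row sets are globally disjoint so the QC
    audit recovers each configured count exactly.  Identical seed and config
    yield an identical table.
    """
    config.validate()
    seed = config.seed
    predictors = list(config.predictors)
    group_frames = []

    for gi, (group, n) in enumerate(config.group_sizes.items()):
        demo = _rng(seed, 1, gi)
        lo, hi = config.age_range
        age = demo.integers(lo, hi + 1, size=n).astype(float)
        education = demo.choice(len(EDUCATION_LEVELS), size=n)
        pir = np.round(demo.gamma(shape=2.0, scale=1.3, size=n), 3)

        lab = {}
        for mi, measure in enumerate(sorted(MEASURE_COLUMNS)):
            mu, sigma = config.phenotype_distributions[measure]
            lab[measure] = _trunc_lognormal(mu, sigma, n, _rng(seed, 2, gi, mi))

        cols: dict[str, np.ndarray] = {
            "race_ethnicity": np.repeat(group, n),
            "age_years": age,
            "education": np.asarray(EDUCATION_LEVELS, dtype=object)[education],
            "pir": pir,
        }
        for measure, col in MEASURE_COLUMNS.items():
            cols[col] = lab[measure]

        for pi, name in enumerate(predictors):
            spec = spec_by_name(name)
            rho = config.rho_for(name, group)
            bias = config.bias_for(name, group)
            rng = _rng(seed, 3, gi, pi)
            if spec.family == "clock":
                cols[spec.prediction_column] = generate_correlated_pair(
                    age, rho, bias, noise_seed=rng
                )
            elif name == "dnamtl":
                loc, scale = config.prediction_scales["dnamtl"]
                cols["dnamtl_kbp"] = generate_correlated_pair(
                    lab["telomere"], rho, bias, noise_seed=rng, loc=loc, scale=scale
                )
            elif name in ("b2m", "cystatin_c"):
                loc, scale = config.prediction_scales[name]
                cols[spec.prediction_column] = generate_correlated_pair(
                    lab[name], rho, bias, noise_seed=rng, loc=loc, scale=scale
                )
            elif name in ("crp", "hba1c"):
                # Target correlation holds on the natural scale; the stored
                # log prediction round-trips exactly through the QC
                # exponentiation step.  Clipping at a small positive floor is
                # astronomically rare at the default scales.
                loc, scale = config.prediction_scales[name]
                natural = generate_correlated_pair(
                    lab[name], rho, bias, noise_seed=rng, loc=loc, scale=scale
                )
                cols[spec.prediction_column] = np.log(np.clip(natural, 1e-3, None))
            elif name == "lymphocytes":
                loc, scale = config.prediction_scales[name]
                total = generate_correlated_pair(
                    lab["lymphocytes"], rho, bias, noise_seed=rng, loc=loc, scale=scale
                )
                total = np.clip(total, 1e-3, 1.0 - 1e-3)
                wts = rng.dirichlet([2.0, 5.0, 3.0], size=n)
                cols["dnam_b"] = total * wts[:, 0]
                cols["dnam_cd4t"] = total * wts[:, 1]
                cols["dnam_cd8t"] = total * wts[:, 2]
            elif name == "monocytes":
                loc, scale = config.prediction_scales[name]
                cols["dnam_monocyte"] = _clip_unit(
                    generate_correlated_pair(
                        lab["monocytes"], rho, bias, noise_seed=rng, loc=loc, scale=scale
                    )
                )
            elif name == "neutrophils":
                loc, scale = config.prediction_scales[name]
                cols["dnam_neutrophil"] = _clip_unit(
                    generate_correlated_pair(
                        lab["neutrophils"], rho, bias, noise_seed=rng, loc=loc, scale=scale
                    )
                )

        if "dnam_b" in cols:  # NK completes the six deconvolution estimates
            nk_rng = _rng(seed, 4, gi)
            cols["dnam_nk"] = _clip_unit(
                np.exp(np.log(0.05) + 0.30 * nk_rng.standard_normal(n))
            )
        group_frames.append(pd.DataFrame(cols))

    df = pd.concat(group_frames, ignore_index=True)
    total = len(df)
    df.insert(0, "id", [f"P{i:06d}" for i in range(total)])
    df["age_topcoded"] = False

    defect = _rng(seed, 9)

    # Sex: exact global male count, randomly allocated.
    n_male = int(round(config.sex_fraction_male * total))
    sex = np.full(total, "female", dtype=object)
    order = defect.permutation(total)
    sex[order[:n_male]] = "male"
    df["sex"] = sex
    df["dnam_predicted_sex"] = sex.copy()

    # Disjoint defect sites from one global permutation.
    perm = defect.permutation(total)
    cursor = 0

    def take(k: int) -> np.ndarray:
        nonlocal cursor
        rows = perm[cursor : cursor + k]
        cursor += k
        return rows

    top_rows = take(config.n_topcoded)
    df.loc[top_rows, "age_years"] = 85.0
    df.loc[top_rows, "age_topcoded"] = True

    mm_rows = take(config.n_sex_mismatch)
    flipped = df.loc[mm_rows, "sex"].map({"male": "female", "female": "male"})
    df.loc[mm_rows, "dnam_predicted_sex"] = flipped.to_numpy()

    injected: dict[str, np.ndarray] = {}
    for measure in sorted(config.n_outliers):
        k = config.n_outliers[measure]
        rows = take(k)
        mu, sigma = config.phenotype_distributions[measure]
        signs = np.where(np.arange(k) % 2 == 0, 1.0, -1.0)
        df.loc[rows, MEASURE_COLUMNS[measure]] = np.exp(mu + signs * _INJECT_Z * sigma)
        injected[measure] = rows

    for measure in sorted(config.missingness):
        k = config.missingness[measure]
        rows = take(k)
        if measure == "cells":
            for m in ("lymphocytes", "monocytes", "neutrophils"):
                df.loc[rows, MEASURE_COLUMNS[m]] = np.nan
        else:
            df.loc[rows, MEASURE_COLUMNS[measure]] = np.nan

    # Verify the injection calibration: the single-pass 3-SD log rule must
    # fire on exactly the injected rows.
    for measure, rows in injected.items():
        res = filter_log_outliers(df[MEASURE_COLUMNS[measure]], k=3.0, nonpositive="exclude")
        flagged = set(np.flatnonzero(res.outlier_mask))
        if flagged != set(rows):
            raise RuntimeError(
                f"outlier injection mis-calibrated for {measure}: "
                f"{len(flagged)} flagged vs {len(rows)} injected"
            )

    if "dnam_b" in df.columns and {"dnam_monocyte", "dnam_neutrophil", "dnam_nk"} <= set(df.columns):
        six = (
            df[["dnam_cd8t", "dnam_cd4t", "dnam_nk", "dnam_b", "dnam_monocyte", "dnam_neutrophil"]]
            .sum(axis=1)
            .mean()
        )
        if not 0.95 <= six <= 1.05:
            warnings.warn(
                f"mean DNAm cell-proportion sum {six:.3f} outside [0.95, 1.05]", stacklevel=2
            )

    # Stable column order.
    lead = ["id", "race_ethnicity", "sex", "age_years", "age_topcoded", "education", "pir"]
    rest = [c for c in df.columns if c not in lead]
    return df[lead + rest]


def truth_table(config: SimulationConfig) -> pd.DataFrame:
    """Generating parameters, one row per (predictor, group)."""
    config.validate()
    rows = [
        {
            "predictor": name,
            "group": group,
            "true_rho": config.rho_for(name, group),
            "true_bias": config.bias_for(name, group),
        }
        for name in config.predictors
        for group in config.group_sizes
    ]
    return pd.DataFrame(rows, columns=["predictor", "group", "true_rho", "true_bias"])


# ---------------------------------------------------------------------------
# I/O
# ---------------------------------------------------------------------------


def write_population(df: pd.DataFrame, path) -> None:
    """Tab-delimited text, one-line header, missing values as empty fields."""
    df.to_csv(path, sep="\t", index=False, na_rep="")


def read_population(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    if "age_topcoded" in df.columns and df["age_topcoded"].dtype != bool:
        df["age_topcoded"] = df["age_topcoded"].astype(bool)
    return df


def write_config(config: SimulationConfig, path) -> None:
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False)


def read_config(path) -> SimulationConfig:
    with open(path) as fh:
        return SimulationConfig.from_dict(yaml.safe_load(fh))
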