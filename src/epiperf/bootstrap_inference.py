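"""Percentile-bootstrap inference on between-group metric differences.

Participants are resampled with replacement *jointly* (phenotype and
prediction stay paired) within each group, the metric is computed in each
group per iteration, and the difference (group A minus group B) is
summarised by its median and 2.5th/97.5th percentiles.  A difference is
flagged significant when the 95% interval excludes 0.

Two variants: ``standard`` resamples each group at its own size; ``equal_n``
resamples every group at a common cap (by default the smallest group's size)
to remove sample-size effects on metric precision.

Iterations on which a metric is undefined (a zero-variance resample) are
dropped and counted — never redrawn, which would bias the null in tiny
strata — and a warning is emitted if more than 1% of iterations are lost.

Reproducibility: each comparison row derives its own seed from the master
seed and the row's identity (predictor, metric, unordered group pair,
variant), and each group's resampling stream is keyed by the group label, so
swapping the orientation of a pair exactly negates the result.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd

from .qc_conversions import AnalysisSet

__all__ = [
    "BootstrapComparison",
    "bootstrap_group_difference",
    "bootstrap_equal_n",
    "all_pairwise_comparisons",
    "derive_seed_words",
    "DEFAULT_RACE_PAIRS",
    "DEFAULT_SEX_PAIRS",
]

#: Fixed comparison orientations (group_a - group_b).
DEFAULT_RACE_PAIRS = (
    ("Mexican American", "NH White"),
    ("NH Black", "NH White"),
    ("Mexican American", "NH Black"),
)
DEFAULT_SEX_PAIRS = (("male", "female"),)

_CHUNK_ELEMENTS = 4_000_000  # index-matrix elements per bootstrap chunk


@dataclass
class BootstrapComparison:
    predictor: str
    metric: str
    group_a: str
    group_b: str
    n_a: int
    n_b: int
    n_iter: int
    median_diff: float
    ci_low: float
    ci_high: float
    significant: bool
    n_degenerate: int
    variant: str
    seed: object
    status: str = "ok"

    def to_row(self) -> dict:
        d = self.__dict__.copy()
        d["seed"] = str(d["seed"])
        return d


def derive_seed_words(master_seed: int, *parts) -> list[int]:
    """Stable per-row entropy: master seed plus a hash of the row identity."""
    digest = hashlib.sha256("\x1f".join(map(str, parts)).encode()).digest()
    words = [int.from_bytes(digest[i : i + 4], "big") for i in range(0, 16, 4)]
    return [int(master_seed)] + words


def _group_rng(words: list[int], label: str) -> np.random.Generator:
    tag = int.from_bytes(hashlib.sha256(str(label).encode()).digest()[:4], "big")
    return np.random.default_rng(np.random.SeedSequence(words + [tag]))


def _boot_samples(x: np.ndarray, y: np.ndarray, n_iter: int, n_draw: int,
                  rng: np.random.Generator, metric: str) -> np.ndarray:
    """Metric value per bootstrap iteration; NaN where undefined."""
    n = x.size
    out = np.empty(n_iter)
    if metric == "mae":
        a = np.abs(y - x)
    chunk = max(1, _CHUNK_ELEMENTS // max(n_draw, 1))
    pos = 0
    while pos < n_iter:
        m = min(chunk, n_iter - pos)
        idx = rng.integers(0, n, size=(m, n_draw))
        if metric == "pearson_r":
            xs = x[idx]
            ys = y[idx]
            xc = xs - xs.mean(axis=1, keepdims=True)
            yc = ys - ys.mean(axis=1, keepdims=True)
            den = np.sqrt((xc * xc).sum(axis=1) * (yc * yc).sum(axis=1))
            num = (xc * yc).sum(axis=1)
            r = np.full(m, np.nan)
            ok = den > 0
            r[ok] = np.clip(num[ok] / den[ok], -1.0, 1.0)
            out[pos : pos + m] = r
        elif metric == "mae":
            out[pos : pos + m] = np.median(a[idx], axis=1)
        else:
            raise ValueError(f"unknown metric {metric!r}")
        pos += m
    return out


def _as_pair(pairs):
    if isinstance(pairs, AnalysisSet):
        return pairs.phenotype, pairs.prediction
    x, y = pairs
    return np.asarray(x, dtype=float), np.asarray(y, dtype=float)


def bootstrap_group_difference(
    pairs_a,
    pairs_b,
    metric: str = "pearson_r",
    n_iter: int = 10_000,
    seed=0,
    variant: str = "standard",
    n_cap: int | None = None,
    group_a: str = "a",
    group_b: str = "b",
    predictor: str = "",
    shared_stream: bool = False,
    return_samples: bool = False,
):
    """Bootstrap the (group A - group B) difference in one metric.

    ``seed`` may be an int or a list of entropy words from
    :func:`derive_seed_words`.  With ``shared_stream=True`` both groups use
    one resampling stream (meaningful only for self-comparisons of groups of
    equal size, where it forces a difference of exactly 0).
    """
    xa, ya = _as_pair(pairs_a)
    xb, yb = _as_pair(pairs_b)
    if xa.size < 3 or xb.size < 3:
        raise ValueError("each group needs at least 3 observations")
    if variant not in ("standard", "equal_n"):
        raise ValueError(f"unknown variant {variant!r}")
    if variant == "equal_n":
        if n_cap is None:
            n_cap = int(min(xa.size, xb.size))
        if n_cap < 3:
            raise ValueError("n_cap must be at least 3")
        if n_cap > min(xa.size, xb.size):
            raise ValueError("n_cap exceeds the smallest group size")
        draw_a = draw_b = n_cap
    else:
        draw_a, draw_b = xa.size, xb.size

    words = seed if isinstance(seed, list) else derive_seed_words(seed)
    if shared_stream:
        rng_a = _group_rng(words, "shared")
        rng_b = _group_rng(words, "shared")
    else:
        rng_a = _group_rng(words, group_a)
        rng_b = _group_rng(words, group_b)

    stat_a = _boot_samples(xa, ya, n_iter, draw_a, rng_a, metric)
    stat_b = _boot_samples(xb, yb, n_iter, draw_b, rng_b, metric)
    diff = stat_a - stat_b
    valid = ~np.isnan(diff)
    n_degenerate = int(n_iter - valid.sum())
    if n_degenerate > 0.01 * n_iter:
        warnings.warn(
            f"{n_degenerate}/{n_iter} bootstrap iterations degenerate for "
            f"({predictor or 'pair'}, {metric}, {group_a} vs {group_b})",
            stacklevel=2,
        )
    diff = diff[valid]
    if diff.size == 0:
        raise ValueError("all bootstrap iterations degenerate")
    ci_low, ci_high = np.percentile(diff, [2.5, 97.5])
    comparison = BootstrapComparison(
        predictor=predictor,
        metric=metric,
        group_a=group_a,
        group_b=group_b,
        n_a=int(xa.size),
        n_b=int(xb.size),
        n_iter=n_iter,
        median_diff=float(np.median(diff)),
        ci_low=float(ci_low),
        ci_high=float(ci_high),
        significant=bool(ci_low > 0 or ci_high < 0),
        n_degenerate=n_degenerate,
        variant=variant,
        seed=words,
    )
    if return_samples:
        return comparison, diff
    return comparison


def bootstrap_equal_n(pairs_a, pairs_b, metric: str = "pearson_r",
                      n_iter: int = 10_000, n_cap: int | None = None, seed=0, **kw):
    """Equal-n sensitivity variant: both groups resampled at size ``n_cap``."""
    return bootstrap_group_difference(
        pairs_a, pairs_b, metric=metric, n_iter=n_iter, seed=seed,
        variant="equal_n", n_cap=n_cap, **kw,
    )


def _orient(pair: tuple[str, str], strata_var: str) -> tuple[str, str]:
    canon = DEFAULT_RACE_PAIRS + DEFAULT_SEX_PAIRS
    unordered = frozenset(pair)
    for a, b in canon:
        if frozenset((a, b)) == unordered:
            return a, b
    return pair


def all_pairwise_comparisons(
    analysis_sets: dict,
    groups,
    metrics=("pearson_r", "mae"),
    variant: str = "standard",
    n_iter: int = 10_000,
    seed: int = 0,
    n_cap: int | None = None,
    strata_var: str = "race_ethnicity",
) -> pd.DataFrame:
    """All (predictor x metric x unordered group pair) comparisons.

    ``analysis_sets`` maps predictor name -> :class:`AnalysisSet`.  For the
    ``equal_n`` variant the default cap is the smallest requested group's
    size within each predictor's analysable data.  Unanalysable strata yield
    a flagged row rather than a silent drop.
    """
    groups = list(groups)
    pairs = [_orient(p, strata_var) for p in combinations(groups, 2)]
    rows = []
    for predictor, aset in analysis_sets.items():
        frame = aset.frame
        by_group = {
            g: (
                sub["phenotype"].to_numpy(float),
                sub["prediction"].to_numpy(float),
            )
            for g, sub in frame.groupby(strata_var, observed=True)
        }
        cap = n_cap
        if variant == "equal_n" and cap is None:
            sizes = [by_group[g][0].size for g in groups if g in by_group]
            cap = min(sizes) if sizes else None
        for metric in metrics:
            for ga, gb in pairs:
                words = derive_seed_words(seed, predictor, metric, *sorted((ga, gb)), variant)
                na = by_group[ga][0].size if ga in by_group else 0
                nb = by_group[gb][0].size if gb in by_group else 0
                if na < 3 or nb < 3:
                    rows.append(
                        BootstrapComparison(
                            predictor, metric, ga, gb, na, nb, n_iter,
                            np.nan, np.nan, np.nan, False, 0, variant, words,
                            status="unanalysable",
                        ).to_row()
                    )
                    continue
                comp = bootstrap_group_difference(
                    by_group[ga], by_group[gb], metric=metric, n_iter=n_iter,
                    seed=words, variant=variant, n_cap=cap,
                    group_a=ga, group_b=gb, predictor=predictor,
                )
                rows.append(comp.to_row())
    return pd.DataFrame(rows)
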