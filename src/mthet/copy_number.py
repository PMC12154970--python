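"""mtDNA copy number (mtCN) from WGS coverage, and covariate correction.

Raw copy number is twice the ratio of mean mtDNA to mean nuclear coverage
(mtDNA is effectively haploid per molecule while the nuclear genome is
diploid).  Because blood mtCN tracks platelet and leukocyte composition
and technical batch, the adjusted phenotype is the residual of log raw
mtCN on blood-composition and technical covariates, with smooth draw-time
and seasonal date effects modelled by natural cubic splines.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from scipy import linalg


def mean_nuclear_coverage(
    total_mapped_reads: float,
    singletons: float,
    mate_different_chr: float,
    duplicates: float,
    read_length: float,
    genome_length: float,
) -> float:
    """(total - singletons - mate-diff-chr - duplicates) * read_length / genome_length."""
    if genome_length <= 0:
        raise ValueError("genome length must be positive")
    usable = total_mapped_reads - singletons - mate_different_chr - duplicates
    if usable < 0:
        raise ValueError("inconsistent metrics: usable read count is negative")
    return usable * read_length / genome_length


def raw_mtcn(mean_mt_coverage: float, mean_nuc_coverage: float) -> float:
    """mtCN_raw = 2 * mean mtDNA coverage / mean nuclear coverage."""
    if mean_nuc_coverage <= 0:
        raise ValueError("mean nuclear coverage must be positive")
    return 2.0 * mean_mt_coverage / mean_nuc_coverage


def natural_spline_basis(x: np.ndarray, knots: np.ndarray) -> np.ndarray:
    """Natural (restricted) cubic spline basis, truncated-power construction.

    Returns ``len(knots) - 1`` columns (linear term plus one per interior
    knot), linear beyond the boundary knots; no intercept column.
    """
    x = np.asarray(x, dtype=float)
    knots = np.sort(np.unique(np.asarray(knots, dtype=float)))
    if len(knots) < 3:
        raise ValueError("need at least 3 distinct knots")
    kK, kK1 = knots[-1], knots[-2]

    def d(k):
        return (np.clip(x - k, 0, None) ** 3 - np.clip(x - kK, 0, None) ** 3) / (kK - k)

    dK1 = d(kK1)
    cols = [x] + [d(k) - dK1 for k in knots[:-2]]
    return np.column_stack(cols)


def quantile_knots(x: np.ndarray, df: int) -> np.ndarray:
    """Boundary knots at the range, df-1 interior knots at quantiles (R ns-style)."""
    qs = np.linspace(0, 1, df + 1)
    return np.quantile(np.asarray(x, dtype=float), qs)


def seasonal_knots(dates: np.ndarray, step_days: float = 91.3125) -> np.ndarray:
    """Knots on a 3-month grid anchored at the earliest date (numeric days)."""
    d = np.asarray(dates, dtype=float)
    grid = np.arange(d.min(), d.max() + step_days, step_days)
    if len(grid) < 3:
        grid = np.array([d.min(), 0.5 * (d.min() + d.max()), d.max()])
    return grid


def _indicator(series: pd.Series, prefix: str) -> pd.DataFrame:
    return pd.get_dummies(series.astype("category"), prefix=prefix, drop_first=True, dtype=float)


def adjust_mtcn(
    samples: pd.DataFrame,
    covariates: pd.DataFrame,
    blood_columns: list[str],
    draw_time_df: int = 5,
    outlier_sd: float = 4.0,
    fasting_bounds: tuple[int, int] = (1, 18),
) -> pd.DataFrame:
    """Residualise log raw mtCN on technical and blood covariates.

    ``samples`` needs ``sample_id`` and positive ``mtcn``; ``covariates``
    needs ``sample_id``, ``draw_time``, ``fasting_time``,
    ``assessment_date`` (numeric days), ``assessment_month``,
    ``assessment_center`` and the ``blood_columns``.

    Blood measurements more than ``outlier_sd`` standard deviations from
    their mean are blanked per variable; rows with any missing covariate
    are then dropped from the fit.  Fasting time is clamped to
    ``fasting_bounds`` and entered as hour indicators; draw time gets a
    natural spline with ``draw_time_df`` degrees of freedom and the date a
    natural spline with seasonal knots at 3-month increments; center and
    month are indicators.  Returns, per fitted sample, the residual
    (``mtcn_adjusted``) and a display-scale value (residual plus the
    pre-adjustment mean of log mtCN, exponentiated).
    """
    df = samples[["sample_id", "mtcn"]].merge(covariates, on="sample_id", how="inner").copy()
    if (df["mtcn"] <= 0).any():
        raise ValueError("raw mtCN must be positive to take logs")
    df["log_mtcn"] = np.log(df["mtcn"])

    for col in blood_columns:
        x = df[col].astype(float)
        z = (x - x.mean()) / x.std(ddof=0)
        df[col] = x.where(z.abs() <= outlier_sd)

    lo, hi = fasting_bounds
    fasting = df["fasting_time"].clip(lower=lo, upper=hi).round().astype(int)

    parts: list[pd.DataFrame] = []
    ns_time = natural_spline_basis(
        df["draw_time"].to_numpy(float), quantile_knots(df["draw_time"].to_numpy(float), draw_time_df)
    )
    parts.append(pd.DataFrame(ns_time, index=df.index,
                              columns=[f"draw_time_ns{i}" for i in range(ns_time.shape[1])]))
    dates = df["assessment_date"].to_numpy(float)
    ns_date = natural_spline_basis(dates, seasonal_knots(dates))
    parts.append(pd.DataFrame(ns_date, index=df.index,
                              columns=[f"date_ns{i}" for i in range(ns_date.shape[1])]))
    parts.append(_indicator(fasting, "fasting"))
    parts.append(_indicator(df["assessment_center"], "center"))
    parts.append(_indicator(df["assessment_month"], "month"))
    parts.append(df[blood_columns].astype(float))

    design = pd.concat(parts, axis=1)
    keep = design.notna().all(axis=1) & df["log_mtcn"].notna()
    design, y = design[keep], df.loc[keep, "log_mtcn"].to_numpy()

    X = np.column_stack([np.ones(len(design)), design.to_numpy(float)])
    names = ["intercept", *design.columns]
    rank = np.linalg.matrix_rank(X)
    if rank < X.shape[1]:
        _, r, piv = linalg.qr(X, mode="economic", pivoting=True)
        aliased = [names[piv[i]] for i in range(rank, X.shape[1])]
        raise ValueError(f"rank-deficient design; aliased columns: {aliased}")

    beta, *_ = np.linalg.lstsq(X, y, rcond=None)
    resid = y - X @ beta
    out = pd.DataFrame(
        {
            "sample_id": df.loc[keep, "sample_id"].to_numpy(),
            "log_mtcn": y,
            "mtcn_adjusted": resid,
            "mtcn_adjusted_display": np.exp(resid + y.mean()),
        }
    )
    return out
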