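"""Clonal-hematopoiesis comparisons and related inference.

CH prevalence rises steeply with age, so any naive CH-vs-rest comparison of
mutation burden is confounded by age.  The matched-resampling design
removes it: draw R (default 500) random control groups, each with exactly
the CH group's (age, sex) multiset, compute the statistic of interest in
the CH group and in every control group, and use the mean and SD of the
per-set CH-minus-control differences as the difference estimate and its
standard error; a normal z test (Bonferroni over the category count, 192
for strand-resolved context tables) gives significance.

Also here: sibling heteroplasmy sharing, proximity-based locus clumping of
association results, inverse-variance-weighted effect-size regression
(one-sided Mendelian randomization), logistic disease association for
mtDNA burden phenotypes, and positional-constraint score comparisons.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.proportion import proportion_confint


@dataclass
class MatchedSampleSet:
    """CH carrier ids plus R control id-sets with identical (age, sex) multisets."""

    ch_ids: np.ndarray
    control_sets: list[np.ndarray]
    seed: int | None = None

    @property
    def n_sets(self) -> int:
        return len(self.control_sets)


def match_controls(
    samples: pd.DataFrame,
    n_sets: int = 500,
    seed: int | np.random.Generator = 0,
    ch_col: str = "ch",
    age_col: str = "age",
    sex_col: str = "sex",
) -> MatchedSampleSet:
    """R random control groups age/sex-matched to the CH group.

    Within a set, sampling is without replacement per (age, sex) stratum;
    sets are drawn independently (a control may recur across sets).  Ages
    match on integer years.  Raises if any stratum's non-CH pool is smaller
    than its CH count.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    ch_mask = samples[ch_col].astype(bool)
    ch = samples[ch_mask]
    controls = samples[~ch_mask]
    strata = ch.groupby([age_col, sex_col], observed=True).size()
    pools = {
        key: grp["sample_id"].to_numpy()
        for key, grp in controls.groupby([age_col, sex_col], observed=True)
    }
    for key, need in strata.items():
        have = len(pools.get(key, ()))
        if have < need:
            raise ValueError(
                f"stratum (age={key[0]}, sex={key[1]}): need {need} controls, have {have}"
            )
    sets = []
    for _ in range(n_sets):
        parts = [rng.choice(pools[key], size=need, replace=False) for key, need in strata.items()]
        sets.append(np.concatenate(parts))
    # matching exactness is asserted on every generated set
    code = dict(
        zip(samples["sample_id"], zip(samples[age_col], samples[sex_col]))
    )
    ch_multiset = sorted(code[i] for i in ch["sample_id"])
    for s in sets:
        assert sorted(code[i] for i in s) == ch_multiset
    return MatchedSampleSet(
        ch_ids=ch["sample_id"].to_numpy(),
        control_sets=sets,
        seed=seed if isinstance(seed, int) else None,
    )


def matched_difference_test(
    statistic,
    matched: MatchedSampleSet,
    categories: list | None = None,
    bonferroni: int | None = None,
    permutation_p: bool = False,
) -> pd.DataFrame:
    """CH-vs-matched-controls difference test for a per-group statistic.

    ``statistic(sample_ids) -> array of per-category values`` (scalar
    allowed).  The control point estimate is the mean over the R sets and
    its SE the SD over sets; the difference statistic (CH minus control,
    per set) gives the difference estimate (mean) and SE (SD), a z value,
    two-sided normal p, and Bonferroni-adjusted p over ``bonferroni``
    comparisons (default: the category count).  ``permutation_p`` adds a
    rank-based two-sided p from the control statistics themselves.
    """
    s_ch = np.atleast_1d(np.asarray(statistic(matched.ch_ids), dtype=float))
    s_ctrl = np.vstack(
        [np.atleast_1d(np.asarray(statistic(ids), dtype=float)) for ids in matched.control_sets]
    )
    diffs = s_ch[None, :] - s_ctrl
    est = diffs.mean(axis=0)
    se = diffs.std(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        z = est / se
    p = 2.0 * stats.norm.sf(np.abs(z))
    degenerate = (se == 0) & (est != 0)
    if degenerate.any():
        warnings.warn("zero resampling SE with nonzero difference; p reported as 0")
        p = np.where(degenerate, 0.0, p)
    p = np.where((se == 0) & (est == 0), 1.0, p)
    k = bonferroni if bonferroni is not None else len(est)
    out = pd.DataFrame(
        {
            "category": categories if categories is not None else list(range(len(est))),
            "ch_stat": s_ch,
            "control_mean": s_ctrl.mean(axis=0),
            "control_se": s_ctrl.std(axis=0, ddof=1),
            "difference": est,
            "difference_se": se,
            "z": z,
            "p": p,
            "p_bonferroni": np.minimum(1.0, p * k),
        }
    )
    if permutation_p:
        r = matched.n_sets
        ge = (s_ctrl >= s_ch[None, :]).sum(axis=0)
        le = (s_ctrl <= s_ch[None, :]).sum(axis=0)
        out["p_permutation"] = np.minimum(1.0, 2.0 * (np.minimum(ge, le) + 1) / (r + 1))
    return out


def sibling_sharing(
    callset: pd.DataFrame,
    samples: pd.DataFrame,
    hl_bins: list[tuple[float, float]],
    min_carriers: int = 5,
    sib1: str = "deterministic",
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Proportion of sibling-1 heteroplasmies found in sibling 2, per HL bin.

    Pairs come from the ``sibling_pair`` column (>= 0).  Variants carried by
    fewer than ``min_carriers`` individuals cohort-wide are excluded as
    potential artefacts.  A variant is shared if present in both siblings at
    any heteroplasmy; the bin is the sibling-1 HL.  Sibling 1 is the lower
    sample id (``sib1="random"`` randomises the choice per pair).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    carriers = callset.groupby(["pos", "ref", "alt"])["sample_id"].nunique()
    common = carriers[carriers >= min_carriers].index
    calls = callset.set_index(["pos", "ref", "alt"]).loc[
        callset.set_index(["pos", "ref", "alt"]).index.isin(common)
    ].reset_index()

    by_sample = {sid: grp for sid, grp in calls.groupby("sample_id")}
    records = []
    paired = samples[samples["sibling_pair"] >= 0]
    for _, pair in paired.groupby("sibling_pair"):
        ids = sorted(pair["sample_id"])
        if len(ids) != 2:
            continue
        if sib1 == "random" and rng.random() < 0.5:
            ids = ids[::-1]
        s1, s2 = ids
        v1 = by_sample.get(s1)
        if v1 is None:
            continue
        v2 = by_sample.get(s2)
        seen2 = (
            set(zip(v2["pos"], v2["ref"], v2["alt"])) if v2 is not None else set()
        )
        for _, row in v1.iterrows():
            records.append(
                {"HL": row["HL"], "shared": (row["pos"], row["ref"], row["alt"]) in seen2}
            )
    obs = pd.DataFrame(records, columns=["HL", "shared"])
    rows = []
    for lo, hi in hl_bins:
        sel = obs[(obs["HL"] >= lo) & (obs["HL"] < hi)]
        n, k = len(sel), int(sel["shared"].sum()) if len(sel) else 0
        if n:
            ci_lo, ci_hi = proportion_confint(k, n, method="wilson")
            rows.append({"hl_bin": f"[{lo},{hi})", "n": n, "n_shared": k,
                         "proportion": k / n,
                         "ci_low": max(0.0, ci_lo), "ci_high": min(1.0, ci_hi)})
        else:
            rows.append({"hl_bin": f"[{lo},{hi})", "n": 0, "n_shared": 0,
                         "proportion": np.nan, "ci_low": np.nan, "ci_high": np.nan})
    return pd.DataFrame(rows)


def clump_loci(
    associations: pd.DataFrame,
    p_threshold: float = 5e-5,
    half_window: int = 100_000,
) -> pd.DataFrame:
    """Proximity-based clumping of association results into loci.

    Significant variants (p < threshold) get +/- ``half_window`` windows;
    overlapping windows are merged; each locus reports its most significant
    (lead) variant.  Needs ``pos`` and ``p`` columns (optional ``chrom``).
    """
    df = associations.copy()
    if "chrom" not in df.columns:
        df["chrom"] = "1"
    sig = df[df["p"] < p_threshold].sort_values(["chrom", "pos"])
    loci = []
    for chrom, grp in sig.groupby("chrom"):
        current: list[pd.Series] = []
        last_end = None
        for _, row in grp.iterrows():
            start = row["pos"] - half_window
            if last_end is None or start <= last_end:
                current.append(row)
            else:
                loci.append((chrom, pd.DataFrame(current)))
                current = [row]
            last_end = row["pos"] + half_window
        if current:
            loci.append((chrom, pd.DataFrame(current)))
    rows = []
    for i, (chrom, members) in enumerate(loci):
        lead = members.sort_values(["p", "pos"]).iloc[0]
        rows.append(
            {
                "locus": i,
                "chrom": chrom,
                "start": int(members["pos"].min()),
                "end": int(members["pos"].max()),
                "n_variants": len(members),
                "lead_pos": int(lead["pos"]),
                "lead_p": float(lead["p"]),
            }
        )
    return pd.DataFrame(
        rows, columns=["locus", "chrom", "start", "end", "n_variants", "lead_pos", "lead_p"]
    )


def ivw_effect_correlation(
    x: np.ndarray,
    se_x: np.ndarray,
    y: np.ndarray,
    se_y: np.ndarray,
    include_intercept: bool = False,
) -> dict:
    """Inverse-variance-weighted regression of effect sizes y on x.

    Weights are 1/SEx^2 * 1/SEy^2.  With alleles oriented so x is
    risk-increasing, a positive slope indicates the x-trait liability
    raises y.  No intercept by default (Mendelian-randomization
    convention).  Requires at least 3 pairs and finite positive SEs.
    """
    x, y = np.asarray(x, float), np.asarray(y, float)
    se_x, se_y = np.asarray(se_x, float), np.asarray(se_y, float)
    if len(x) < 3:
        raise ValueError("need at least 3 effect pairs")
    if np.any(se_x <= 0) or np.any(se_y <= 0) or not (
        np.all(np.isfinite(se_x)) and np.all(np.isfinite(se_y))
    ):
        raise ValueError("standard errors must be finite and positive")
    w = (1.0 / se_x**2) * (1.0 / se_y**2)
    X = sm.add_constant(x) if include_intercept else x[:, None]
    fit = sm.WLS(y, X, weights=w).fit()
    i = 1 if include_intercept else 0
    ci = fit.conf_int()
    return {
        "slope": float(fit.params[i]),
        "se": float(fit.bse[i]),
        "p": float(fit.pvalues[i]),
        "ci_low": float(ci[i][0]),
        "ci_high": float(ci[i][1]),
        "n": int(len(x)),
    }


def inverse_rank_normal(x: pd.Series) -> pd.Series:
    """Blom-offset inverse rank normal transform."""
    ranks = x.rank(method="average")
    return pd.Series(
        stats.norm.ppf((ranks - 0.375) / (len(x) + 0.25)), index=x.index, name=x.name
    )


def disease_association(
    samples: pd.DataFrame,
    burden: pd.Series,
    phenotype: pd.Series,
    ancestry_col: str = "ancestry",
    haplogroup_col: str = "haplogroup",
    smoking_col: str = "smoking",
    exclude_smokers: bool = True,
    min_group_cases: int = 3,
    irnt: bool = False,
) -> dict:
    """Logistic association between a disease phenotype and mtDNA burden.

    Covariates: age, sex, age*sex, age^2, age^2*sex, plus ancestry-group
    and haplogroup indicators.  Ever-smokers are excluded (smoking is a
    mutational confounder); ancestry groups with fewer than
    ``min_group_cases`` cases are excluded.  ``irnt`` inverse-rank-
    normalises the burden.  Separation or non-convergence is flagged
    rather than reported as an estimate.
    """
    df = samples.copy()
    df["burden"] = burden.reindex(df["sample_id"]).to_numpy(float)
    df["y"] = phenotype.reindex(df["sample_id"]).to_numpy(float)
    if exclude_smokers and smoking_col in df.columns:
        df = df[~df[smoking_col].astype(bool)]
    group_cases = df.groupby(ancestry_col, observed=True)["y"].sum()
    keep_groups = group_cases[group_cases >= min_group_cases].index
    df = df[df[ancestry_col].isin(keep_groups)].dropna(subset=["burden", "y"])
    if irnt:
        df["burden"] = inverse_rank_normal(df["burden"])

    sex_num = (df["sex"].astype(str) == "M").astype(float)
    age = df["age"].astype(float)
    X = pd.DataFrame(
        {
            "burden": df["burden"].to_numpy(),
            "age": age.to_numpy(),
            "sex": sex_num.to_numpy(),
            "age_sex": (age * sex_num).to_numpy(),
            "age2": (age**2).to_numpy(),
            "age2_sex": (age**2 * sex_num).to_numpy(),
        },
        index=df.index,
    )
    for col in (ancestry_col, haplogroup_col):
        if col in df.columns and df[col].nunique() > 1:
            X = pd.concat(
                [X, pd.get_dummies(df[col], prefix=col, drop_first=True, dtype=float)], axis=1
            )
    X = sm.add_constant(X)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("error", category=sm.tools.sm_exceptions.PerfectSeparationWarning)
            fit = sm.Logit(df["y"].to_numpy(), X.to_numpy(float)).fit(disp=0, maxiter=200)
        if not fit.mle_retvals.get("converged", True):
            raise RuntimeError("did not converge")
    except Exception as exc:  # separation / convergence failure
        return {"flagged": True, "reason": str(exc), "n": int(len(df)),
                "odds_ratio": np.nan, "ci_low": np.nan, "ci_high": np.nan, "p": np.nan}
    j = list(X.columns).index("burden")
    beta, se = fit.params[j], fit.bse[j]
    return {
        "flagged": False,
        "reason": None,
        "n": int(len(df)),
        "odds_ratio": float(np.exp(beta)),
        "ci_low": float(np.exp(beta - 1.959963984540054 * se)),
        "ci_high": float(np.exp(beta + 1.959963984540054 * se)),
        "p": float(fit.pvalues[j]),
    }


def mean_positional_score(
    callset: pd.DataFrame,
    scores: pd.Series,
    groups: dict[str, np.ndarray],
) -> pd.DataFrame:
    """Per-group mean of a positional score over each group's variant records.

    ``scores`` maps position -> score (e.g. a local-constraint metric);
    variants at unscored positions are dropped and counted.  ``groups``
    maps group name -> sample ids.  SE is SD/sqrt(n) over variant records.
    """
    rows = []
    for name, ids in groups.items():
        sub = callset[callset["sample_id"].isin(ids)]
        vals = sub["pos"].map(scores)
        missing = int(vals.isna().sum())
        vals = vals.dropna().to_numpy(float)
        rows.append(
            {
                "group": name,
                "n_variants": int(vals.size),
                "n_unscored": missing,
                "mean": vals.mean() if vals.size else np.nan,
                "se": vals.std(ddof=1) / np.sqrt(vals.size) if vals.size > 1 else np.nan,
            }
        )
    return pd.DataFrame(rows)
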