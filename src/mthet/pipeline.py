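"""End-to-end driver steps composing the QC and comparison stages.

These are the canonical orderings used by the analysis scripts: sample
filters first, then genotype recoding, then the per-individual Poisson
allele-depth threshold, then the recurrent-artifact blacklist.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .clonal import match_controls, matched_difference_test
from .cohort import CohortConfig, simulate_cohort
from .qc import (
    QcReport,
    apply_blacklist,
    apply_hl_filter,
    filter_samples,
    poisson_detection_threshold,
    recode_genotypes,
)
from .reference import ReferenceGenome


@dataclass
class BurdenQcResult:
    samples: pd.DataFrame  # QC-pass samples
    callset: pd.DataFrame  # burden-QC'd SNV heteroplasmies
    thresholds: pd.Series  # per-sample allele-depth threshold
    sample_report: QcReport
    n_blacklisted: int


def burden_qc(
    callset: pd.DataFrame,
    samples: pd.DataFrame,
    quantile: float = 0.95,
    threshold_basis: str = "nuclear",
    blacklist: pd.DataFrame | None = None,
) -> BurdenQcResult:
    """The full burden-mode QC chain.

    Sample-level filters (variants mode), genotype recoding, the Poisson
    detection threshold at ``quantile`` on each sample's mean nuclear
    coverage (``threshold_basis="mito"`` switches the threshold to mean
    mtDNA coverage), the allele-depth heteroplasmy filter, and the
    recurrent-artifact blacklist (packaged default when None).
    """
    kept, report = filter_samples(samples, "variants")
    cs = callset[callset["sample_id"].isin(set(kept["sample_id"]))]
    cs = recode_genotypes(cs)
    basis_col = {"nuclear": "mean_nuclear_coverage", "mito": "mean_mt_coverage"}[threshold_basis]
    thresholds = pd.Series(
        poisson_detection_threshold(kept[basis_col].to_numpy(float), quantile),
        index=pd.Index(kept["sample_id"], name="sample_id"),
    )
    cs = apply_hl_filter(cs, "burden", thresholds=thresholds)
    cs, n_black = apply_blacklist(cs, blacklist)
    return BurdenQcResult(kept, cs.reset_index(drop=True), thresholds, report, n_black)


def ch_matched_burden_test(
    samples: pd.DataFrame,
    burden: pd.Series,
    n_sets: int = 500,
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """Mean-burden difference between CH carriers and matched controls."""
    matched = match_controls(samples, n_sets=n_sets, seed=seed)
    values = burden.reindex(samples["sample_id"]).to_numpy(float)
    pos = {sid: i for i, sid in enumerate(samples["sample_id"])}

    def stat(ids):
        return np.array([values[[pos[i] for i in ids]].mean()])

    return matched_difference_test(stat, matched, categories=["mean_burden"])


def null_matched_test_size(
    reference: ReferenceGenome,
    n_reps: int = 1000,
    seed: int = 0,
    n_samples: int = 2000,
    n_sets: int = 150,
    alpha: float = 0.05,
) -> float:
    """Empirical size of the matched burden test when CH does nothing.

    Each repetition simulates a fresh cohort in which the CH flag exists but
    clonal expansion is disabled (``p_clonal_mutation=0``), runs the burden
    QC chain, and tests CH vs matched controls at level ``alpha``.  CH
    prevalence is kept low so the control pool dwarfs the carrier group, as
    in a biobank.  Returns the rejection rate.
    """
    root = np.random.default_rng(seed)
    config = CohortConfig(
        n_samples=n_samples,
        age_range=(40, 70),
        rates_per_year={},
        rates_constant={("C>T", "heavy"): 2.0, ("A>G", "light"): 1.0},
        ch_logistic=(-4.6, 0.0),  # ~1% carriers, no age dependence
        p_clonal_mutation=0.0,
        ori=None,
    )
    rejections = 0
    done = 0
    while done < n_reps:
        cohort = simulate_cohort(reference, None, config, seed=root)
        if cohort.samples["ch"].sum() < 2:
            continue
        qc = burden_qc(cohort.callset, cohort.samples)
        counts = qc.callset.groupby("sample_id").size()
        burden = counts.reindex(qc.samples["sample_id"], fill_value=0).astype(float)
        try:
            res = ch_matched_burden_test(qc.samples, burden, n_sets=n_sets, seed=root)
        except ValueError:  # a stratum with no eligible controls; rare draw
            continue
        if res["p"].iloc[0] < alpha:
            rejections += 1
        done += 1
    return rejections / n_reps
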