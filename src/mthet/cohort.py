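"""Synthetic blood mtDNA heteroplasmy cohorts.

The generator embodies a two-step mechanism for age-related heteroplasmy:

1. *Cryptic mutation.*  Replication errors seed low-cell-fraction somatic
   mtDNA mutations.  Per substitution class (and strand), the expected
   number of cryptic mutations a person carries grows linearly with age
   (optionally, an age-independent "embryonic" timing is available), with
   the strand bias of the real spectrum (C>T on the heavy strand and A>G
   on both strands dominate the age-dependent component).
2. *Clonal expansion.*  Carriers of clonal hematopoiesis (CH) — whose
   prevalence rises logistically with age — have one expanded blood clone;
   each of their cryptic mutations rides that clone with some probability,
   lifting its cell fraction (hence bulk heteroplasmy) from near zero to
   the clonal fraction, which carries it above the detection limit.

Bulk heteroplasmy equals the mutation's cell fraction.  Sequencing is
emulated by Poisson site depth at the sample's mean mtDNA coverage and
binomial alternate-read sampling; a call is emitted only when at least one
alternate read is observed, and the *observed* HL is AD/DP, so detection
interacts with coverage exactly as in real callsets.

Optional sibling pairs share "transmitted" (inherited) variants at
identical true heteroplasmy in both siblings, on top of independent
private somatic variants.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genes import GeneModel
from .reference import ReferenceGenome
from .spectrum import ORI_INTERVAL, all_possible_snvs

SUBSTITUTION_CLASSES = [
    (sub, strand) for sub in ("C>A", "C>G", "C>T", "A>C", "A>G", "A>T")
    for strand in ("light", "heavy")
]

#: Age-dependent per-year cryptic mutation rates for the age-accumulating
#: classes (A>G both strands, C>T heavy), and flat rates for the rest.
DEFAULT_RATES_PER_YEAR = {
    ("C>T", "heavy"): 0.10,
    ("A>G", "heavy"): 0.05,
    ("A>G", "light"): 0.05,
}
DEFAULT_RATES_CONSTANT = {
    ("C>T", "light"): 1.2,
    ("C>A", "light"): 0.5,
    ("C>A", "heavy"): 0.5,
    ("C>G", "light"): 0.25,
    ("C>G", "heavy"): 0.25,
    ("A>C", "light"): 0.25,
    ("A>C", "heavy"): 0.25,
    ("A>T", "light"): 0.25,
    ("A>T", "heavy"): 0.25,
}


def logistic(x):
    return 1.0 / (1.0 + np.exp(-np.asarray(x, dtype=float)))


@dataclass
class CohortConfig:
    """Study conditions for one simulated cohort."""

    n_samples: int = 1000
    age_range: tuple[int, int] = (18, 90)
    rates_per_year: dict = field(default_factory=lambda: dict(DEFAULT_RATES_PER_YEAR))
    rates_constant: dict = field(default_factory=lambda: dict(DEFAULT_RATES_CONSTANT))
    #: "aging": cryptic count ~ Poisson(age * rate); "embryonic": mutations
    #: arise during development, count ~ Poisson(embryonic_years * rate)
    #: independent of age.  The data cannot distinguish the two; both are
    #: carried to detection by clonal expansion.
    mutation_timing: str = "aging"
    embryonic_years: float = 70.0
    #: Beta(a, b) for cryptic-mutation cell fractions (concentrated near 0).
    cell_fraction_beta: tuple[float, float] = (0.7, 60.0)
    #: CH prevalence = logistic(intercept + slope * age).
    ch_logistic: tuple[float, float] = (-6.0, 0.06)
    #: Beta(a, b) for a CH carrier's clonal fraction.
    clonal_fraction_beta: tuple[float, float] = (2.0, 8.0)
    #: Probability a carrier's cryptic mutation rides the expanded clone.
    p_clonal_mutation: float = 0.5
    mt_coverage_mean: float = 2000.0
    mt_coverage_sd: float = 250.0
    nuclear_coverage_mean: float = 30.0
    nuclear_coverage_sd: float = 3.0
    n_sibling_pairs: int = 0
    transmitted_rate: float = 1.0
    transmitted_hl_beta: tuple[float, float] = (1.2, 6.0)
    #: Rates of sample-QC pathologies.
    p_overlapping_homoplasmies: float = 0.001
    p_haplogroup_conflict: float = 0.002
    p_pilot: float = 0.01
    contamination_beta: tuple[float, float] = (1.0, 400.0)
    p_smoker: float = 0.45
    ancestry_groups: tuple = ("EUR", "AFR", "AMR", "EAS", "SAS")
    ancestry_probs: tuple = (0.55, 0.2, 0.12, 0.08, 0.05)
    haplogroups: tuple = ("H", "U", "K", "T", "J", "V")
    haplogroup_probs: tuple = (0.45, 0.2, 0.1, 0.1, 0.1, 0.05)
    ori: tuple[int, int] | None = ORI_INTERVAL

    def validate(self) -> None:
        if self.n_samples < 1:
            raise ValueError("n_samples must be positive")
        lo, hi = self.age_range
        if not lo <= hi:
            raise ValueError("invalid age range")
        for rates in (self.rates_per_year, self.rates_constant):
            for key, r in rates.items():
                if r < 0:
                    raise ValueError(f"negative mutation rate for class {key}")
                if key not in SUBSTITUTION_CLASSES:
                    raise ValueError(f"unknown substitution class {key}")
        if self.mutation_timing not in ("aging", "embryonic"):
            raise ValueError("mutation_timing must be 'aging' or 'embryonic'")
        if not 0 <= self.p_clonal_mutation <= 1:
            raise ValueError("p_clonal_mutation must be in [0, 1]")
        if 2 * self.n_sibling_pairs > self.n_samples:
            raise ValueError("too many sibling pairs for cohort size")


@dataclass
class SimulatedCohort:
    """Sample table, emitted callset, and the ground-truth mutation table."""

    samples: pd.DataFrame
    callset: pd.DataFrame
    truth: pd.DataFrame


def _class_pools(reference: ReferenceGenome, ori) -> dict:
    """(substitution, strand) -> array of (pos, ref, alt) rows."""
    table = all_possible_snvs(reference, ori)
    return {
        key: grp[["pos", "ref", "alt"]].reset_index(drop=True)
        for key, grp in table.groupby(["substitution", "strand"])
    }


def simulate_cohort(
    reference: ReferenceGenome,
    gene_model: GeneModel | None,
    config: CohortConfig,
    seed: int | np.random.Generator = 0,
) -> SimulatedCohort:
    """Simulate a cohort under the two-step cryptic-mutation/expansion model.

    Deterministic under ``seed``.  The gene model is accepted for interface
    symmetry with the downstream consequence analyses; mutations fall
    uniformly over each class's possible sites regardless of genes.
    """
    config.validate()
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    n = config.n_samples
    lo, hi = config.age_range

    sample_ids = np.array([f"S{i:06d}" for i in range(n)])
    ages = rng.integers(lo, hi + 1, size=n)
    sexes = rng.choice(["F", "M"], size=n)
    a0, a1 = config.ch_logistic
    ch = rng.random(n) < logistic(a0 + a1 * ages)
    clonal_fraction = np.where(
        ch, rng.beta(*config.clonal_fraction_beta, size=n), np.nan
    )
    mt_cov = np.clip(rng.normal(config.mt_coverage_mean, config.mt_coverage_sd, n), 50, None)
    nuc_cov = np.clip(
        rng.normal(config.nuclear_coverage_mean, config.nuclear_coverage_sd, n), 5, None
    )

    sibling_pair = np.full(n, -1)
    for k in range(config.n_sibling_pairs):
        sibling_pair[2 * k] = sibling_pair[2 * k + 1] = k
    # siblings share age (drawn once per pair) to mimic family structure
    for k in range(config.n_sibling_pairs):
        ages[2 * k + 1] = ages[2 * k]

    pools = _class_pools(reference, config.ori)
    eff_age = ages if config.mutation_timing == "aging" else np.full(n, config.embryonic_years)

    truth_rows = []
    for key in SUBSTITUTION_CLASSES:
        rate = config.rates_per_year.get(key, 0.0)
        const = config.rates_constant.get(key, 0.0)
        lam = eff_age * rate + const
        counts = rng.poisson(lam)
        total = int(counts.sum())
        if total == 0 or key not in pools:
            continue
        pool = pools[key]
        site_idx = rng.integers(len(pool), size=total)
        owner = np.repeat(np.arange(n), counts)
        sites = pool.iloc[site_idx]
        truth_rows.append(
            pd.DataFrame(
                {
                    "sample_idx": owner,
                    "pos": sites["pos"].to_numpy(),
                    "ref": sites["ref"].to_numpy(),
                    "alt": sites["alt"].to_numpy(),
                    "substitution": key[0],
                    "strand": key[1],
                    "transmitted": False,
                }
            )
        )

    if truth_rows:
        truth = pd.concat(truth_rows, ignore_index=True)
    else:
        truth = pd.DataFrame(
            columns=["sample_idx", "pos", "ref", "alt", "substitution", "strand", "transmitted"]
        )

    # cell fractions: Beta near zero, lifted to the clonal fraction when the
    # mutation rides a CH carrier's expanded clone
    m = len(truth)
    cf = rng.beta(*config.cell_fraction_beta, size=m) if m else np.array([])
    if m:
        owner_idx = truth["sample_idx"].to_numpy()
        on_clone = ch[owner_idx] & (rng.random(m) < config.p_clonal_mutation)
        cf = np.where(on_clone, clonal_fraction[owner_idx], cf)
        truth["on_clone"] = on_clone
    else:
        truth["on_clone"] = pd.Series(dtype=bool)
    truth["hl_true"] = np.clip(cf, 1e-12, 1.0)

    # transmitted variants for sibling pairs: identical true HL in both sibs
    if config.n_sibling_pairs and config.transmitted_rate > 0:
        all_sites = all_possible_snvs(reference, config.ori)
        trans_rows = []
        for k in range(config.n_sibling_pairs):
            n_t = rng.poisson(config.transmitted_rate)
            if n_t == 0:
                continue
            idx = rng.choice(len(all_sites), size=n_t, replace=False)
            hls = rng.beta(*config.transmitted_hl_beta, size=n_t)
            for j, h in zip(idx, hls):
                row = all_sites.iloc[j]
                for sib in (2 * k, 2 * k + 1):
                    trans_rows.append(
                        {
                            "sample_idx": sib,
                            "pos": int(row["pos"]),
                            "ref": row["ref"],
                            "alt": row["alt"],
                            "substitution": row["substitution"],
                            "strand": row["strand"],
                            "transmitted": True,
                            "on_clone": False,
                            "hl_true": float(h),
                        }
                    )
        if trans_rows:
            truth = pd.concat([truth, pd.DataFrame(trans_rows)], ignore_index=True)

    # collapse duplicate (sample, site) hits, keeping the largest cell fraction
    truth = truth.sort_values("hl_true", ascending=False)
    emit = truth.drop_duplicates(subset=["sample_idx", "pos", "alt"]).copy()
    truth = truth.sort_index().reset_index(drop=True)
    truth["sample_id"] = sample_ids[truth["sample_idx"].to_numpy(int)]

    # read sampling: Poisson depth, binomial alternate reads, emit if AD >= 1
    dp = rng.poisson(mt_cov[emit["sample_idx"].to_numpy(int)])
    ad = rng.binomial(dp, emit["hl_true"].to_numpy())
    detected = ad >= 1
    callset = pd.DataFrame(
        {
            "sample_id": sample_ids[emit["sample_idx"].to_numpy(int)[detected]],
            "pos": emit["pos"].to_numpy(int)[detected],
            "ref": emit["ref"].to_numpy()[detected],
            "alt": emit["alt"].to_numpy()[detected],
            "HL": ad[detected] / dp[detected],
            "AD": ad[detected],
            "DP": dp[detected],
            "filter": "PASS",
        }
    ).sort_values(["sample_id", "pos", "alt"]).reset_index(drop=True)

    samples = pd.DataFrame(
        {
            "sample_id": sample_ids,
            "age": ages,
            "sex": sexes,
            "smoking": rng.random(n) < config.p_smoker,
            "ancestry": rng.choice(config.ancestry_groups, size=n, p=config.ancestry_probs),
            "haplogroup": rng.choice(config.haplogroups, size=n, p=config.haplogroup_probs),
            "ch": ch,
            "clonal_fraction": clonal_fraction,
            "mt_contamination": rng.beta(*config.contamination_beta, size=n),
            "nuc_contamination": rng.beta(*config.contamination_beta, size=n),
            "overlapping_homoplasmies": rng.random(n) < config.p_overlapping_homoplasmies,
            "haplogroup_conflict": rng.random(n) < config.p_haplogroup_conflict,
            "pilot": rng.random(n) < config.p_pilot,
            "mean_mt_coverage": mt_cov,
            "mean_nuclear_coverage": nuc_cov,
            "sibling_pair": sibling_pair,
        }
    )
    samples["mtcn"] = 2.0 * samples["mean_mt_coverage"] / samples["mean_nuclear_coverage"]
    return SimulatedCohort(samples=samples, callset=callset, truth=truth)


def simulate_phenotypes(
    samples: pd.DataFrame,
    burden: pd.Series,
    intercept: float,
    beta: float,
    seed: int | np.random.Generator = 0,
    covariate_betas: dict[str, float] | None = None,
) -> pd.Series:
    """Binary phenotype ~ Bernoulli(logistic(intercept + beta * burden + ...)).

    ``burden`` is indexed by sample_id; ``covariate_betas`` maps sample-table
    columns to additional linear terms.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    b = burden.reindex(samples["sample_id"]).to_numpy(float)
    eta = intercept + beta * b
    for col, coef in (covariate_betas or {}).items():
        eta = eta + coef * samples[col].to_numpy(float)
    y = rng.random(len(samples)) < logistic(eta)
    return pd.Series(y.astype(int), index=pd.Index(samples["sample_id"], name="sample_id"),
                     name="phenotype")
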