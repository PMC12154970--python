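"""Sample- and variant-level QC for mtDNA heteroplasmy callsets.

Two QC tracks exist because low-heteroplasmy calls trade sensitivity
against NUMT (nuclear-mitochondrial segment) contamination:

* **common** mode keeps variants with 0.05 <= HL <= 0.95 — conservative,
  for analyses of individual common heteroplasmies;
* **burden** mode keeps low-HL SNVs provided their alternate-allele read
  depth clears a per-individual Poisson detection threshold: the smallest
  depth ``t`` such that 95% of *nuclear* genomic sites would be expected to
  have fewer than ``t`` reads under a Poisson(mean nuclear coverage) model.
  Reads misassigned from NUMTs scale with nuclear coverage, so requiring
  more mtDNA reads than nearly any nuclear site can supply suppresses them.

A small fixed blacklist of recurrent suspicious variants (sites whose
detection count inflated by more than 500% when moving from the common to
the burden filter, with more than 30 detections) ships as a packaged
default; :func:`derive_blacklist` re-implements the rule for any pair of
callsets.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .spectrum import ORI_INTERVAL, classify_callset

GENOTYPE_STATES = ("heteroplasmic", "homoplasmic_alt", "homoplasmic_ref", "missing")

SAMPLE_FILTER_COLUMNS = {
    "overlapping_homoplasmies": "overlapping_homoplasmies",
    "mt_contamination": "mt_contamination",
    "nuc_contamination": "nuc_contamination",
    "haplogroup_conflict": "haplogroup_conflict",
    "pilot": "pilot",
}


def poisson_detection_threshold(lam, q: float = 0.95):
    """Smallest integer t with P(X < t) >= q for X ~ Poisson(lam).

    ``lam`` is the per-individual mean nuclear coverage (a scalar or array).
    Monotone nondecreasing in both ``lam`` and ``q``.
    """
    lam_arr = np.asarray(lam, dtype=float)
    if np.any(lam_arr <= 0):
        raise ValueError("mean coverage must be positive")
    if not 0 < q < 1:
        raise ValueError("quantile must lie in (0, 1)")
    # ppf gives the smallest k with P(X <= k) >= q; P(X < t) = P(X <= t-1).
    t = stats.poisson.ppf(q, lam_arr).astype(int) + 1
    return int(t) if np.isscalar(lam) else t


@dataclass
class QcReport:
    """Per-record exclusion log; every removed record has one primary reason."""

    n_input: int
    removed: pd.DataFrame  # columns: sample_id, reason
    counts: dict[str, int] = field(default_factory=dict)

    @property
    def n_kept(self) -> int:
        return self.n_input - len(self.removed)

    def summary(self) -> dict:
        return {"n_input": self.n_input, "n_kept": self.n_kept, "removed": dict(self.counts)}


def filter_samples(
    samples: pd.DataFrame,
    analysis_mode: str = "variants",
    contamination_max: float = 0.02,
    mtcn_min: float = 50.0,
) -> tuple[pd.DataFrame, QcReport]:
    """Sample-level QC.

    Removes samples flagged for abnormally overlapping homoplasmies, either
    contamination estimate above ``contamination_max``, multiple
    haplogroup-defining variants at low heteroplasmy, or pilot-era
    collection.  In ``variants`` mode additionally removes samples with
    mtDNA copy number below ``mtcn_min`` (low-mtCN samples show inflated
    variant counts, suspicious of NUMT contamination); ``copy_number`` mode
    keeps them.
    """
    if analysis_mode not in ("variants", "copy_number"):
        raise ValueError(f"unknown analysis_mode {analysis_mode!r}")
    required = list(SAMPLE_FILTER_COLUMNS.values()) + (
        ["mtcn"] if analysis_mode == "variants" else []
    )
    for col in ["sample_id", *required]:
        if col not in samples.columns:
            raise KeyError(f"sample table missing required field {col!r}")

    reason = pd.Series(pd.NA, index=samples.index, dtype="object")

    def _mark(mask, label):
        reason[mask & reason.isna()] = label

    _mark(samples["overlapping_homoplasmies"].astype(bool), "overlapping_homoplasmies")
    _mark(samples["mt_contamination"] > contamination_max, "contamination")
    _mark(samples["nuc_contamination"] > contamination_max, "contamination")
    _mark(samples["haplogroup_conflict"].astype(bool), "haplogroup_conflict")
    _mark(samples["pilot"].astype(bool), "pilot")
    if analysis_mode == "variants":
        _mark(samples["mtcn"] < mtcn_min, "low_mtcn")

    removed_mask = reason.notna()
    removed = pd.DataFrame(
        {"sample_id": samples.loc[removed_mask, "sample_id"], "reason": reason[removed_mask]}
    ).reset_index(drop=True)
    report = QcReport(
        n_input=len(samples),
        removed=removed,
        counts=removed["reason"].value_counts().to_dict(),
    )
    return samples[~removed_mask].reset_index(drop=True), report


def recode_genotypes(
    callset: pd.DataFrame,
    hl_floor: float = 0.01,
    homoplasmy_min: float = 0.95,
    missing_min_coverage: int = 100,
) -> pd.DataFrame:
    """Drop filter-flagged genotypes and assign genotype states.

    Records with any non-PASS caller filter are removed.  HL below
    ``hl_floor`` is recoded homoplasmic for the reference allele (the
    variant is treated as absent).  A missing genotype (HL is NA) becomes
    homoplasmic-reference when site coverage is at least
    ``missing_min_coverage`` and stays missing otherwise.
    """
    flt = callset.get("filter", pd.Series("PASS", index=callset.index))
    out = callset[flt.fillna("PASS").isin(["PASS", "", "."])].copy()
    hl = out["HL"]
    genotype = np.select(
        [hl.isna() & (out["DP"] >= missing_min_coverage), hl.isna(),
         hl < hl_floor, hl > homoplasmy_min],
        ["homoplasmic_ref", "missing", "homoplasmic_ref", "homoplasmic_alt"],
        default="heteroplasmic",
    )
    out["genotype"] = genotype
    return out


def is_snv(callset: pd.DataFrame) -> pd.Series:
    return (callset["ref"].str.len() == 1) & (callset["alt"].str.len() == 1)


def apply_hl_filter(
    callset: pd.DataFrame,
    mode: str,
    thresholds: pd.Series | None = None,
    hl_min: float = 0.05,
    hl_max: float = 0.95,
) -> pd.DataFrame:
    """Heteroplasmy-level variant filter.

    ``common`` keeps heteroplasmies with ``hl_min <= HL <= hl_max`` (both
    ends inclusive).  ``burden`` keeps SNVs with ``HL <= hl_max`` whose
    alternate allele depth reaches the per-sample Poisson detection
    threshold ``thresholds[sample_id]`` (indels are excluded: the burden
    phenotype counts SNVs only).  Only heteroplasmic genotypes survive when
    a ``genotype`` column is present.
    """
    df = callset
    if "genotype" in df.columns:
        df = df[df["genotype"] == "heteroplasmic"]
    if mode == "common":
        return df[(df["HL"] >= hl_min) & (df["HL"] <= hl_max)].copy()
    if mode == "burden":
        if thresholds is None:
            raise ValueError("burden mode requires per-sample detection thresholds")
        missing = set(df["sample_id"].unique()) - set(thresholds.index)
        if missing:
            raise KeyError(f"no detection threshold for samples: {sorted(missing)[:5]}")
        t = df["sample_id"].map(thresholds)
        return df[is_snv(df) & (df["HL"] <= hl_max) & (df["AD"] >= t)].copy()
    raise ValueError(f"unknown HL-filter mode {mode!r}")


def default_blacklist() -> pd.DataFrame:
    """The packaged 5-variant burden-QC blacklist (pos, ref, alt)."""
    with resources.files("mthet.data").joinpath("blacklist.tsv").open() as fh:
        return pd.read_csv(fh, sep="\t")


def apply_blacklist(
    callset: pd.DataFrame, blacklist: pd.DataFrame | None = None
) -> tuple[pd.DataFrame, int]:
    """Remove exact (pos, ref, alt) blacklist matches across all samples.

    Returns the filtered callset (order preserved) and the removed count.
    """
    if blacklist is None:
        blacklist = default_blacklist()
    for col in ("pos", "ref", "alt"):
        if col not in blacklist.columns:
            raise ValueError(f"blacklist missing column {col!r}")
    if blacklist[["pos", "ref", "alt"]].isna().any().any():
        raise ValueError("malformed blacklist entry (missing field)")
    keys = set(zip(blacklist["pos"].astype(int), blacklist["ref"], blacklist["alt"]))
    mask = [
        (int(p), r, a) in keys
        for p, r, a in zip(callset["pos"], callset["ref"], callset["alt"])
    ]
    mask = np.asarray(mask, dtype=bool)
    return callset[~mask].copy(), int(mask.sum())


def derive_blacklist(
    strict_callset: pd.DataFrame,
    lenient_callset: pd.DataFrame,
    fold_increase: float = 5.0,
    min_detections: int = 30,
) -> pd.DataFrame:
    """Variants whose detection count inflates suspiciously under the lenient filter.

    A variant is flagged when its count in the lenient (allele-depth
    filtered) callset exceeds its count under the strict HL > 0.05 filter
    by more than ``fold_increase`` x 100% (i.e. lenient > (1+fold) x strict,
    or any detections where the strict count is zero) and it is detected
    more than ``min_detections`` times.
    """
    strict = strict_callset.groupby(["pos", "ref", "alt"]).size()
    lenient = lenient_callset.groupby(["pos", "ref", "alt"]).size()
    both = pd.concat([strict.rename("n_strict"), lenient.rename("n_lenient")], axis=1).fillna(0)
    inflated = (both["n_lenient"] > (1 + fold_increase) * both["n_strict"]) & (
        both["n_lenient"] > min_detections
    )
    return both[inflated].reset_index()[["pos", "ref", "alt"]]


def compute_snv_burden(
    callset: pd.DataFrame,
    samples: pd.DataFrame,
    class_filter: str = "all",
    reference=None,
    ori=ORI_INTERVAL,
) -> pd.Series:
    """Per-person QC-pass heteroplasmic SNV count.

    Every sample in ``samples`` appears in the output, zero-count samples
    included.  ``class_filter='age_accumulating'`` counts only the
    age-accumulating classes (A>G either strand, C>T heavy strand, outside
    Ori); it uses an ``age_accumulating`` column if present, otherwise
    classifies against ``reference``.
    """
    df = callset[is_snv(callset)]
    unknown = set(df["sample_id"].unique()) - set(samples["sample_id"])
    if unknown:
        raise KeyError(f"callset samples absent from sample table: {sorted(unknown)[:5]}")
    if class_filter == "age_accumulating":
        if "age_accumulating" not in df.columns:
            if reference is None:
                raise ValueError("need a reference to classify age-accumulating variants")
            df = classify_callset(df, reference, ori)
        df = df[df["age_accumulating"]]
    elif class_filter != "all":
        raise ValueError(f"unknown class_filter {class_filter!r}")
    counts = df.groupby("sample_id").size()
    out = counts.reindex(samples["sample_id"], fill_value=0).astype(int)
    out.name = "snv_burden"
    return out
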