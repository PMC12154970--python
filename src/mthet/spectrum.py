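"""Strand- and region-aware mutational spectrum statistics.

The mtDNA reference sequence is the light strand.  A substitution whose
reference allele is C or A is therefore taken as a light-strand event as
written; one whose reference allele is G or T is complemented and assigned
to the heavy strand.  After strand resolution every SNV falls into one of
six substitution classes (C>A, C>G, C>T, A>C, A>G, A>T), on one of two
strands, with a strand-resolved trinucleotide context (16 flank pairs per
class), giving the 6 x 16 x 2 = 192 context categories; collapsing strands
yields the standard pyrimidine-referenced 96.

Region: positions 16172..210 (wrapping the circular origin) form the
replication-origin "Ori" control region with its own mutational spectrum;
everything else is "Other".  The *age-accumulating* classes — the ones
whose per-person burden rises with age — are A>G on either strand plus C>T
on the heavy strand, outside Ori.

Mean counts per person are normalised by the number of *possible* variants
in each category, so classes with different base abundance are comparable.
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache

import numpy as np
import pandas as pd
from scipy import stats

from .reference import COMPLEMENT, ReferenceGenome, revcomp

#: Ori interval of the rCRS-like genome, 1-based inclusive on both ends,
#: wrapping the origin (16172..length then 1..210).
ORI_INTERVAL = (16172, 210)

PYRIMIDINE_SUBS = ["C>A", "C>G", "C>T", "T>A", "T>C", "T>G"]
_SUB_TO_PYR = {"A>C": "T>G", "A>G": "T>C", "A>T": "T>A"}


@dataclass(frozen=True)
class VariantClass:
    """Strand-resolved classification of one SNV."""

    strand: str  # "heavy" | "light"
    region: str  # "Ori" | "Other"
    substitution: str  # resolved class, reference allele C or A
    context: str | None  # strand-resolved 3-mer; None if a flank is N
    age_accumulating: bool


def in_ori(position: int, ori: tuple[int, int] | None = ORI_INTERVAL) -> bool:
    """Whether a position lies in the (origin-wrapping) Ori interval."""
    if ori is None:
        return False
    start, end = ori
    if start <= end:
        return start <= position <= end
    return position >= start or position <= end


def classify_variant(
    position: int,
    ref: str,
    alt: str,
    reference: ReferenceGenome,
    ori: tuple[int, int] | None = ORI_INTERVAL,
) -> VariantClass:
    """Classify one SNV by strand, region, substitution class, and context."""
    if ref == alt or len(ref) != 1 or len(alt) != 1 or alt not in "ACGT":
        raise ValueError(f"not an SNV: {ref}>{alt}")
    base = reference.base(position)
    if base == "N":
        raise ValueError(f"position {position} is a placeholder")
    if base != ref:
        raise ValueError(f"ref mismatch at {position}: given {ref}, reference has {base}")
    if ref in "CA":
        strand, sub = "light", f"{ref}>{alt}"
    else:
        strand, sub = "heavy", f"{COMPLEMENT[ref]}>{COMPLEMENT[alt]}"
    light_ctx = reference.context(position)
    ctx = light_ctx if strand == "light" else revcomp(light_ctx)
    if "N" in ctx:
        ctx = None
    region = "Ori" if in_ori(position, ori) else "Other"
    age_acc = region == "Other" and (sub == "A>G" or (sub == "C>T" and strand == "heavy"))
    return VariantClass(strand, region, sub, ctx, age_acc)


def classify_callset(
    callset: pd.DataFrame,
    reference: ReferenceGenome,
    ori: tuple[int, int] | None = ORI_INTERVAL,
) -> pd.DataFrame:
    """Vectorised :func:`classify_variant` over a callset.

    Returns a copy with columns ``strand``, ``region``, ``substitution``,
    ``context`` (NaN where a flank is a placeholder) and
    ``age_accumulating`` appended.  Rows must be SNVs whose ref matches the
    reference.
    """
    out = callset.copy()
    cls = [
        classify_variant(int(p), r, a, reference, ori)
        for p, r, a in zip(out["pos"], out["ref"], out["alt"])
    ]
    out["strand"] = [c.strand for c in cls]
    out["region"] = [c.region for c in cls]
    out["substitution"] = [c.substitution for c in cls]
    out["context"] = [c.context for c in cls]
    out["age_accumulating"] = [c.age_accumulating for c in cls]
    return out


def all_possible_snvs(
    reference: ReferenceGenome,
    ori: tuple[int, int] | None = ORI_INTERVAL,
) -> pd.DataFrame:
    """Every possible SNV at every informative position, classified.

    Three alternate alleles per non-placeholder position, ordered by
    (position, alt); 3 x 16,568 = 49,704 rows for an rCRS-like genome.
    """
    return _all_possible_snvs_cached(reference, ori).copy()


@lru_cache(maxsize=8)
def _all_possible_snvs_cached(
    reference: ReferenceGenome, ori: tuple[int, int] | None
) -> pd.DataFrame:
    rows = []
    for pos in reference.informative_positions():
        pos = int(pos)
        ref = reference.base(pos)
        for alt in "ACGT":
            if alt == ref:
                continue
            c = classify_variant(pos, ref, alt, reference, ori)
            rows.append(
                (pos, ref, alt, c.strand, c.region, c.substitution, c.context, c.age_accumulating)
            )
    return pd.DataFrame(
        rows,
        columns=[
            "pos", "ref", "alt", "strand", "region",
            "substitution", "context", "age_accumulating",
        ],
    )


def count_possible(
    reference: ReferenceGenome,
    region: str | None = None,
    strand: str | None = None,
    substitution: str | None = None,
    context: str | None = None,
    ori: tuple[int, int] | None = ORI_INTERVAL,
) -> int:
    """Number of possible SNVs in a category (any ``None`` field is unrestricted).

    When ``context`` is given, positions whose context contains a
    placeholder are excluded.
    """
    table = all_possible_snvs(reference, ori)
    mask = np.ones(len(table), dtype=bool)
    if region is not None:
        mask &= (table["region"] == region).to_numpy()
    if strand is not None:
        mask &= (table["strand"] == strand).to_numpy()
    if substitution is not None:
        mask &= (table["substitution"] == substitution).to_numpy()
    if context is not None:
        mask &= (table["context"] == context).to_numpy()
    return int(mask.sum())


def context_categories() -> pd.DataFrame:
    """The 192 strand-resolved context categories (6 classes x 16 flanks x 2)."""
    rows = [
        (strand, sub, five + sub[0] + three)
        for strand in ("light", "heavy")
        for sub in ("C>A", "C>G", "C>T", "A>C", "A>G", "A>T")
        for five in "ACGT"
        for three in "ACGT"
    ]
    return pd.DataFrame(rows, columns=["strand", "substitution", "context"])


def per_sample_counts(
    classified: pd.DataFrame,
    sample_ids: pd.Series | list,
    variant_by: tuple[str, ...],
) -> pd.DataFrame:
    """Per-sample variant counts in each category, zero-filled.

    Every QC-pass sample appears for every observed category; categories
    with no variants anywhere are absent (their mean is identically 0).
    """
    counts = (
        classified.groupby(["sample_id", *variant_by], observed=True)
        .size()
        .rename("count")
        .reset_index()
    )
    cats = counts[list(variant_by)].drop_duplicates()
    full = (
        pd.MultiIndex.from_product(
            [pd.Index(sample_ids, name="sample_id"), range(len(cats))],
            names=["sample_id", "_cat"],
        )
        .to_frame(index=False)
        .merge(cats.reset_index(drop=True).rename_axis("_cat").reset_index(), on="_cat")
        .drop(columns="_cat")
    )
    out = full.merge(counts, on=["sample_id", *variant_by], how="left")
    out["count"] = out["count"].fillna(0).astype(int)
    return out


def normalized_mean_counts(
    callset: pd.DataFrame,
    samples: pd.DataFrame,
    reference: ReferenceGenome,
    variant_by: tuple[str, ...] = ("strand", "substitution", "region"),
    sample_by: tuple[str, ...] = (),
    ori: tuple[int, int] | None = ORI_INTERVAL,
    age_range: tuple[int, int] | None = None,
    age_bin_width: int = 5,
) -> pd.DataFrame:
    """Possible-variant-normalised mean SNV counts per person.

    ``variant_by`` are classification columns (strand / substitution /
    region / context / age_accumulating); ``sample_by`` are sample-table
    columns, with the derived column ``age_bin`` available when an
    ``age_range`` is set.  Means are over *all* QC-pass samples in the
    stratum, zero-count samples included; SE is sample SD / sqrt(n);
    the normalised mean divides by the category's possible-variant count.
    """
    samples = samples.copy()
    if age_range is not None:
        lo, hi = age_range
        samples = samples[(samples["age"] >= lo) & (samples["age"] <= hi)].copy()
        edges = np.arange(lo, hi + age_bin_width, age_bin_width)
        samples["age_bin"] = pd.cut(samples["age"], edges, right=False, include_lowest=True)
    callset = callset[callset["sample_id"].isin(samples["sample_id"])]
    classified = classify_callset(callset, reference, ori)

    possible = all_possible_snvs(reference, ori)
    denom = possible.groupby(list(variant_by), observed=True).size().rename("n_possible")

    counts = per_sample_counts(classified, samples["sample_id"], variant_by)
    counts = counts.merge(samples, on="sample_id")

    def _summarise(g: pd.DataFrame) -> pd.Series:
        n = len(g)
        mean = g["count"].mean()
        se = g["count"].std(ddof=1) / np.sqrt(n) if n > 1 else np.nan
        return pd.Series({"n_samples": n, "mean_count": mean, "se": se})

    grouped = (
        counts.groupby([*variant_by, *sample_by], observed=True)
        .apply(_summarise, include_groups=False)
        .reset_index()
    )
    grouped = grouped.merge(denom.reset_index(), on=list(variant_by), how="left")
    grouped["normalized_mean"] = grouped["mean_count"] / grouped["n_possible"]
    grouped["normalized_se"] = grouped["se"] / grouped["n_possible"]
    grouped["n_samples"] = grouped["n_samples"].astype(int)
    return grouped


# -- COSMIC-style single-base-substitution signatures ------------------------

def _pyrimidine_label(substitution: str, context: str) -> str:
    """COSMIC label ``A[C>T]G`` for a strand-resolved category."""
    if substitution.startswith("A"):
        substitution = _SUB_TO_PYR[substitution]
        context = revcomp(context)
    return f"{context[0]}[{substitution}]{context[2]}"


def cosmic_labels() -> list[str]:
    """The 96 pyrimidine-referenced context labels in COSMIC order."""
    return [
        f"{five}[{sub}]{three}"
        for sub in PYRIMIDINE_SUBS
        for five in "ACGT"
        for three in "ACGT"
    ]


def spectrum_96(classified: pd.DataFrame, strand: str | None = None) -> pd.Series:
    """Pyrimidine-referenced 96-vector of variant counts.

    ``strand`` restricts to one strand's variants (the strand-resolved A>*
    classes are complemented into the pyrimidine frame); ``None`` pools
    both strands.  Context-less variants (placeholder flank) are dropped.
    """
    df = classified.dropna(subset=["context"])
    if strand is not None:
        df = df[df["strand"] == strand]
    labels = [_pyrimidine_label(s, c) for s, c in zip(df["substitution"], df["context"])]
    vec = pd.Series(labels).value_counts().reindex(cosmic_labels(), fill_value=0)
    vec.index.name = "category"
    return vec.astype(float)


def read_cosmic_signatures(path) -> pd.DataFrame:
    """Read a COSMIC-style signature TSV into a 96 x S matrix.

    Accepts either a ``Type``/``SubType`` pair of columns (e.g. ``C>A`` /
    ``ACA``) or a single ``Type`` column already in ``A[C>A]A`` form.
    """
    df = pd.read_csv(path, sep="\t")
    if "SubType" in df.columns:
        idx = [f"{st[0]}[{t}]{st[2]}" for t, st in zip(df["Type"], df["SubType"])]
        df = df.drop(columns=["Type", "SubType"])
        df.index = pd.Index(idx, name="category")
    else:
        df = df.set_index(df.columns[0])
        df.index.name = "category"
    return df


def sbs_correlation(observed: pd.Series, signatures: pd.DataFrame) -> pd.DataFrame:
    """Per-signature linear fit of the observed spectrum on each signature.

    One simple regression per signature (observed ~ intercept + signature);
    two-sided p for the slope, Bonferroni-adjusted by the number of
    signatures supplied.
    """
    if set(observed.index) != set(signatures.index):
        raise ValueError("signature categories do not match the observed spectrum")
    signatures = signatures.loc[observed.index]
    n_sig = signatures.shape[1]
    rows = []
    for name in signatures.columns:
        fit = stats.linregress(signatures[name].to_numpy(), observed.to_numpy())
        rows.append(
            {
                "signature": name,
                "slope": fit.slope,
                "p": fit.pvalue,
                "p_bonferroni": min(1.0, fit.pvalue * n_sig),
            }
        )
    return pd.DataFrame(rows)
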