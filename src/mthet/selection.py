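"""Nonparametric somatic dN/dS with a per-individual sampling null.

For a gene (and heteroplasmy bin, and mutation-class subset — by default
the age-accumulating classes, since that is the mutational process under
study), dN is the number of observed nonsynonymous variant records divided
by the number of *possible* nonsynonymous variants in the gene, dS the
analogous synonymous quantity, and dN/dS their ratio; values below 1
indicate purifying selection.  Observed records are (sample, variant)
pairs: a variant recurring in several people counts once per person,
matching the null, which resamples per-person counts.

The neutral null: for each individual i and mutation class c, redraw that
individual's N_ic observed variants uniformly without replacement from the
gene's possible variants of class c, recompute dN/dS, and repeat (1000
replicates by default).  Only consequence *counts* enter dN/dS, so each
per-individual draw is realised exactly as a multivariate hypergeometric
sample over consequence categories — distributionally identical to
explicit site sampling, at a fraction of the cost.  An explicit
site-sampling draw is also provided for callset-level checks.

Consequences use the vertebrate mitochondrial genetic code: identical
amino acid (stop included) is synonymous, gain of stop is pLoF, any other
amino-acid change (missense, stop-lost, start-lost) is nonsynonymous;
positions outside coding genes are noncoding.  pLoF is excluded from both
numerator and denominator by default, with an option to fold it into
nonsynonymous.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio.Data import CodonTable
from scipy import stats

from .genes import GeneModel
from .reference import COMPLEMENT, ReferenceGenome
from .spectrum import ORI_INTERVAL, all_possible_snvs

MITO_CODE = CodonTable.unambiguous_dna_by_id[2]  # vertebrate mitochondrial

CLASS_COLUMNS = ["substitution", "strand"]


def translate_codon(codon: str) -> str:
    """One-letter amino acid under the vertebrate mitochondrial code; '*' = stop."""
    if codon in MITO_CODE.stop_codons:
        return "*"
    return MITO_CODE.forward_table[codon]


def enumerate_possible_snvs(
    reference: ReferenceGenome, ori: tuple[int, int] | None = ORI_INTERVAL
) -> pd.DataFrame:
    """All possible SNVs (3 per informative position), classified, ordered
    by (position, alt)."""
    table = all_possible_snvs(reference, ori)
    return table.sort_values(["pos", "alt"], kind="stable").reset_index(drop=True)


def _codon_lookup(gene_model: GeneModel, reference: ReferenceGenome) -> dict:
    """position -> (gene name, codon positions on coding strand, index in codon,
    gene strand)."""
    lookup: dict[int, tuple[str, tuple[int, int, int], int, str]] = {}
    for gene in gene_model:
        if not gene.coding:
            continue
        pos = gene.positions(reference.length)
        coding = pos[gene.frame :] if gene.strand == "heavy" else pos[: len(pos) - gene.frame][::-1]
        for i in range(0, len(coding) - 2, 3):
            triplet = (int(coding[i]), int(coding[i + 1]), int(coding[i + 2]))
            for j, p in enumerate(triplet):
                lookup[p] = (gene.name, triplet, j, gene.strand)
    return lookup


def annotate_consequence(
    snvs: pd.DataFrame, gene_model: GeneModel, reference: ReferenceGenome
) -> pd.DataFrame:
    """Assign gene and coding consequence to each SNV row.

    Adds ``gene`` (NaN outside genes) and ``consequence`` in
    {synonymous, nonsynonymous, pLoF, noncoding}.
    """
    lookup = _codon_lookup(gene_model, reference)
    genes, consequences = [], []
    for pos, ref, alt in zip(snvs["pos"], snvs["ref"], snvs["alt"]):
        pos = int(pos)
        if reference.base(pos) != ref:
            raise ValueError(f"ref mismatch at {pos}")
        hit = lookup.get(pos)
        if hit is None:
            genes.append(pd.NA)
            consequences.append("noncoding")
            continue
        name, triplet, j, strand = hit
        if strand == "heavy":
            codon = "".join(reference.base(p) for p in triplet)
            new = codon[:j] + alt + codon[j + 1 :]
        else:
            codon = "".join(COMPLEMENT[reference.base(p)] for p in triplet)
            new = codon[:j] + COMPLEMENT[alt] + codon[j + 1 :]
        aa_ref, aa_alt = translate_codon(codon), translate_codon(new)
        genes.append(name)
        if aa_ref == aa_alt:
            consequences.append("synonymous")
        elif aa_alt == "*":
            consequences.append("pLoF")
        else:
            consequences.append("nonsynonymous")
    out = snvs.copy()
    out["gene"] = genes
    out["consequence"] = consequences
    return out


@dataclass
class DnDsResult:
    gene: str | None
    hl_bin: tuple[float, float] | None
    n_obs_nonsyn: int
    n_obs_syn: int
    n_poss_nonsyn: int
    n_poss_syn: int
    dn: float
    ds: float
    ratio: float  # NaN when dS == 0 (undefined, flagged)
    null_ratios: np.ndarray | None = None
    null_median: float = np.nan
    null_lo: float = np.nan
    null_hi: float = np.nan
    observed_percentile: float = np.nan

    @property
    def defined(self) -> bool:
        return self.ds > 0


DEFAULT_HL_BINS = [(0.0, 0.05), (0.05, 0.2), (0.2, 0.5), (0.5, 0.95)]


def _restrict(
    df: pd.DataFrame,
    gene: str | None,
    class_subset,
    hl_bin: tuple[float, float] | None = None,
) -> pd.DataFrame:
    if gene is not None:
        df = df[df["gene"] == gene]
    if class_subset == "age_accumulating":
        df = df[df["age_accumulating"]]
    elif class_subset is not None:
        keys = set(class_subset)
        df = df[[tuple(t) in keys for t in df[CLASS_COLUMNS].itertuples(index=False)]]
    if hl_bin is not None:
        lo, hi = hl_bin
        df = df[(df["HL"] >= lo) & (df["HL"] < hi)] if hi < 0.95 else df[
            (df["HL"] >= lo) & (df["HL"] <= hi)
        ]
    return df


def _counts(df: pd.DataFrame, include_plof: bool) -> tuple[int, int]:
    cons = df["consequence"]
    nonsyn = int((cons == "nonsynonymous").sum())
    if include_plof:
        nonsyn += int((cons == "pLoF").sum())
    return nonsyn, int((cons == "synonymous").sum())


def compute_dnds(
    observed: pd.DataFrame,
    possible: pd.DataFrame,
    gene: str | None = None,
    hl_bin: tuple[float, float] | None = None,
    class_subset="age_accumulating",
    include_plof: bool = False,
) -> DnDsResult:
    """Observed/possible dN/dS for one gene, heteroplasmy bin, and class subset.

    ``observed`` is an annotated, classified callset (one row per (sample,
    variant) record); ``possible`` the annotated all-possible-SNV table.
    The same class restriction applies to numerators and denominators.
    """
    obs = _restrict(observed, gene, class_subset, hl_bin)
    poss = _restrict(possible, gene, class_subset)
    on, os_ = _counts(obs, include_plof)
    pn, ps = _counts(poss, include_plof)
    dn = on / pn if pn else np.nan
    ds = os_ / ps if ps else np.nan
    ratio = dn / ds if ds and ds > 0 else np.nan
    return DnDsResult(gene, hl_bin, on, os_, pn, ps, dn, ds, ratio)


def _class_pools(poss: pd.DataFrame, include_plof: bool) -> dict:
    """class key -> (n_nonsyn, n_syn, n_other) in the possible pool."""
    pools = {}
    for key, grp in poss.groupby(CLASS_COLUMNS):
        nonsyn, syn = _counts(grp, include_plof)
        pools[key] = np.array([nonsyn, syn, len(grp) - nonsyn - syn])
    return pools


def sampling_null_dnds(
    observed: pd.DataFrame,
    possible: pd.DataFrame,
    gene: str | None = None,
    hl_bin: tuple[float, float] | None = None,
    class_subset="age_accumulating",
    n_reps: int = 1000,
    seed: int | np.random.Generator = 0,
    include_plof: bool = False,
    randomize_percentile: bool = False,
) -> DnDsResult:
    """dN/dS with its neutral sampling-null envelope.

    Each replicate redraws every individual's per-class variant count
    N_ic uniformly without replacement from the gene's possible variants of
    that class and recomputes dN/dS exactly as for the observed data.
    Reports all null ratios, their median and 2.5/97.5 percentiles, and the
    observed ratio's percentile within the null (mid-rank by default;
    ``randomize_percentile`` breaks ties uniformly, giving an exactly
    uniform percentile under the null).
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    result = compute_dnds(observed, possible, gene, hl_bin, class_subset, include_plof)
    obs = _restrict(observed, gene, class_subset, hl_bin)
    poss = _restrict(possible, gene, class_subset)
    pools = _class_pools(poss, include_plof)

    n_ic = obs.groupby(["sample_id", *CLASS_COLUMNS], observed=True).size()
    nonsyn = np.zeros(n_reps, dtype=int)
    syn = np.zeros(n_reps, dtype=int)
    for (sample, *key), count in n_ic.items():
        key = tuple(key)
        pool = pools.get(key)
        if pool is None or count > pool.sum():
            raise ValueError(
                f"individual {sample}: {count} observed class-{key} variants exceed "
                f"the possible pool in gene {gene!r}"
            )
        draws = rng.multivariate_hypergeometric(pool, count, size=n_reps)
        nonsyn += draws[:, 0]
        syn += draws[:, 1]

    pn, ps = result.n_poss_nonsyn, result.n_poss_syn
    with np.errstate(divide="ignore", invalid="ignore"):
        dn = nonsyn / pn if pn else np.full(n_reps, np.nan)
        ds = syn / ps if ps else np.full(n_reps, np.nan)
        ratios = np.where(ds > 0, dn / np.where(ds > 0, ds, 1), np.nan)

    finite = ratios[np.isfinite(ratios)]
    result.null_ratios = ratios
    if finite.size:
        result.null_median = float(np.median(finite))
        result.null_lo, result.null_hi = np.percentile(finite, [2.5, 97.5])
    if result.defined and finite.size:
        less = int((finite < result.ratio).sum())
        equal = int((finite == result.ratio).sum())
        if randomize_percentile:
            u = rng.random()
            result.observed_percentile = (less + u * (equal + 1)) / (finite.size + 1)
        else:
            result.observed_percentile = (less + 0.5 * equal) / finite.size
    return result


def draw_null_callset(
    observed: pd.DataFrame,
    possible: pd.DataFrame,
    gene: str | None = None,
    class_subset="age_accumulating",
    seed: int | np.random.Generator = 0,
) -> pd.DataFrame:
    """One explicit draw from the sampling null, as a callset.

    Preserves every individual's per-class count; each individual's draw is
    without replacement from the gene's possible variants of that class.
    """
    rng = np.random.default_rng(seed) if not isinstance(seed, np.random.Generator) else seed
    obs = _restrict(observed, gene, class_subset)
    poss = _restrict(possible, gene, class_subset)
    n_ic = obs.groupby(["sample_id", *CLASS_COLUMNS], observed=True).size()
    rows = []
    for (sample, *key), count in n_ic.items():
        pool = poss[(poss["substitution"] == key[0]) & (poss["strand"] == key[1])]
        if count > len(pool):
            raise ValueError(f"individual {sample}: class {tuple(key)} pool too small")
        take = pool.iloc[rng.choice(len(pool), size=count, replace=False)].copy()
        take.insert(0, "sample_id", sample)
        rows.append(take)
    if not rows:
        return obs.iloc[0:0].copy()
    return pd.concat(rows, ignore_index=True)


def heteroplasmy_shift(
    observed: pd.DataFrame,
    gene: str | None = None,
    consequence_a: str = "nonsynonymous",
    consequence_b: str = "synonymous",
) -> dict:
    """Rank-based comparison of HL distributions between consequence groups.

    Negative direction means group a (missense by default) sits at lower
    heteroplasmy than group b.  Returns the rank-biserial correlation as
    the location statistic, a two-sided Mann-Whitney p, and both empirical
    CDFs; ``None`` estimate when either arm is empty.
    """
    df = observed if gene is None else observed[observed["gene"] == gene]
    a = df.loc[df["consequence"] == consequence_a, "HL"].to_numpy(float)
    b = df.loc[df["consequence"] == consequence_b, "HL"].to_numpy(float)
    if a.size == 0 or b.size == 0:
        return {"n_a": a.size, "n_b": b.size, "statistic": None, "p": None,
                "direction": None, "ecdf_a": None, "ecdf_b": None}
    u, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    rank_biserial = 2.0 * u / (a.size * b.size) - 1.0
    return {
        "n_a": int(a.size),
        "n_b": int(b.size),
        "statistic": float(rank_biserial),
        "p": float(p),
        "direction": int(np.sign(rank_biserial)),
        "ecdf_a": stats.ecdf(a).cdf,
        "ecdf_b": stats.ecdf(b).cdf,
    }
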