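"""Reading and writing the standard interchange formats.

The callset travels either as a single long-format TSV (sample_id, pos,
ref, alt, HL, AD, DP, filter) or as minimal one-sample-per-file VCFs with
FORMAT fields HL/AD/DP, written and read through pysam.  The reference is
FASTA, the gene model a BED-like 1-based inclusive TSV, the sample table a
plain TSV.
"""

from __future__ import annotations

from pathlib import Path

import pandas as pd
import pysam

from .reference import ReferenceGenome

CALLSET_COLUMNS = ["sample_id", "pos", "ref", "alt", "HL", "AD", "DP", "filter"]


def write_callset_tsv(callset: pd.DataFrame, path) -> None:
    callset[CALLSET_COLUMNS].to_csv(path, sep="\t", index=False)


def read_callset_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "ref": str, "alt": str})
    missing = set(CALLSET_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"callset TSV missing columns: {sorted(missing)}")
    return df


def write_sample_table(samples: pd.DataFrame, path) -> None:
    samples.to_csv(path, sep="\t", index=False)


def read_sample_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"sample_id": str})


def _vcf_header(reference: ReferenceGenome, sample_id: str, filters) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    header.add_line(f"##contig=<ID={reference.name},length={reference.length}>")
    header.formats.add("HL", 1, "Float", "Heteroplasmy fraction (alt depth / site depth)")
    header.formats.add("AD", 1, "Integer", "Alternate allele read depth")
    header.formats.add("DP", 1, "Integer", "Site read depth")
    for f in filters:
        if f not in ("PASS", ".", ""):
            header.filters.add(f, None, None, "caller filter")
    header.add_sample(sample_id)
    return header


def write_sample_vcf(
    callset: pd.DataFrame, sample_id: str, reference: ReferenceGenome, path
) -> None:
    """Write one sample's calls as an uncompressed single-sample VCF."""
    calls = callset[callset["sample_id"] == sample_id].sort_values(["pos", "alt"])
    header = _vcf_header(reference, sample_id, calls["filter"].unique())
    with pysam.VariantFile(str(path), "w", header=header) as vcf:
        for _, row in calls.iterrows():
            rec = vcf.new_record(
                contig=reference.name,
                start=int(row["pos"]) - 1,
                alleles=(row["ref"], row["alt"]),
            )
            flt = row["filter"]
            rec.filter.add("PASS" if flt in (".", "", None) else str(flt))
            fmt = rec.samples[sample_id]
            fmt["HL"] = float(row["HL"])
            fmt["AD"] = int(row["AD"])
            fmt["DP"] = int(row["DP"])
            vcf.write(rec)


def read_sample_vcf(path) -> pd.DataFrame:
    """Read a single-sample VCF back into long callset form."""
    rows = []
    with pysam.VariantFile(str(path)) as vcf:
        (sample_id,) = list(vcf.header.samples)
        for rec in vcf:
            fmt = rec.samples[sample_id]
            filters = list(rec.filter.keys()) or ["PASS"]
            rows.append(
                {
                    "sample_id": sample_id,
                    "pos": rec.pos,
                    "ref": rec.ref,
                    "alt": rec.alts[0],
                    "HL": float(fmt["HL"]),
                    "AD": int(fmt["AD"]),
                    "DP": int(fmt["DP"]),
                    "filter": ";".join(filters),
                }
            )
    return pd.DataFrame(rows, columns=CALLSET_COLUMNS)


def write_cohort(outdir, cohort, reference: ReferenceGenome, gene_model=None) -> dict:
    """Write a simulated cohort's artefacts (FASTA, TSVs) under ``outdir``."""
    from .reference import write_fasta

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "reference": outdir / "reference.fa",
        "samples": outdir / "samples.tsv",
        "callset": outdir / "callset.tsv",
    }
    write_fasta(reference, paths["reference"])
    write_sample_table(cohort.samples, paths["samples"])
    write_callset_tsv(cohort.callset, paths["callset"])
    if gene_model is not None:
        paths["genes"] = outdir / "genes.tsv"
        gene_model.to_tsv(paths["genes"])
    return paths
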