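#!/usr/bin/env python
"""Generate the working synthetic cohort.

Builds an rCRS-like reference (16,569 bp, placeholder at 3107), a six-gene
model with one light-strand (ND6-analogue) gene, and a 5,000-person cohort
under the two-step mechanism defaults: age-linear cryptic mutation rates
for the age-accumulating classes, flat rates elsewhere, logistic-in-age CH
prevalence, and binomial read sampling against Poisson coverage.  Also
writes 100 sibling pairs carrying transmitted variants.

Outputs under results/cohort/: reference.fa, genes.tsv, samples.tsv,
callset.tsv.
"""

from pathlib import Path

from mthet import CohortConfig, generate_gene_model, generate_reference, simulate_cohort
from mthet.io import write_cohort

OUT = Path(__file__).resolve().parent.parent / "results" / "cohort"
SEED = 2024


def main() -> None:
    reference = generate_reference(16569, {3107}, seed=SEED)
    genes = generate_gene_model(
        reference, 6, {"heavy": 5, "light": 1}, seed=SEED, min_length=300, max_length=900
    )
    config = CohortConfig(n_samples=5000, age_range=(40, 70), n_sibling_pairs=100)
    cohort = simulate_cohort(reference, genes, config, seed=SEED)
    paths = write_cohort(OUT, cohort, reference, genes)
    print(f"cohort: {len(cohort.samples)} samples, {len(cohort.callset)} raw calls")
    print(f"CH carriers: {int(cohort.samples['ch'].sum())}")
    for name, p in paths.items():
        print(f"  wrote {name}: {p}")


if __name__ == "__main__":
    main()
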