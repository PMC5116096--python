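#!/usr/bin/env python
"""Polygenic scoring of the cohort.

Builds a per-allele weight table from the scan's estimated additive
effects at the causal variants (the stand-in for externally adjusted GWAS
weights), scores every sample, and reports the fraction of variance the
score explains in the adult-height analogue and in the birth-length
analogue — the birth trait shares the causal variants at rescaled
effects, so the height-trained score should explain a smaller but clearly
non-zero share of it.

Writes results/pgs_summary.tsv.
"""

from pathlib import Path

import pandas as pd

from poegwas import genio
from poegwas.pgs import score_samples, variance_explained_by_score
from poegwas.phenotype import adjust_and_standardize

COHORT = Path("scratch/cohort")
RESULTS = Path("results")


def main() -> None:
    geno = genio.read_phased_vcf(str(COHORT / "cohort.vcf"))
    phen = genio.read_phenotypes(str(COHORT / "phenotypes.tsv"))
    truth = pd.read_csv(COHORT / "truth.tsv", sep="\t")
    scan = genio.read_results("scratch/association_scan_full.tsv")

    add = scan.loc[scan["model"] == "additive"].set_index("variant")
    weights = pd.DataFrame(
        {
            "id": truth["variant"],
            "allele": "C",
            "weight": [add.loc[v, "beta"] for v in truth["variant"]],
        }
    )
    score = score_samples(geno, weights)

    rows = []
    for trait in ("height", "birth_length"):
        y = adjust_and_standardize(phen.loc[phen["trait"] == trait]).set_index("iid")["y"]
        r2 = variance_explained_by_score(score, y)
        rows.append({"trait": trait, "r2": r2, "n": int(y.notna().sum())})
    out = pd.DataFrame(rows)
    out.to_csv(RESULTS / "pgs_summary.tsv", sep="\t", index=False)
    print("variance explained by the additive polygenic score:")
    print(out.to_string(index=False))


if __name__ == "__main__":
    main()
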