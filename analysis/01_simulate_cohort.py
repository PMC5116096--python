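#!/usr/bin/env python
"""Build the synthetic study cohort.

Generates a three-generation pedigree (~6,000 individuals), phased
LD-structured genotypes with known parental origin, and two traits (an
adult-height analogue, s.d. 6.6 cm, and a birth-length analogue, s.d.
2.5 cm sharing the causal variants at rescaled effects).  The architecture
mirrors the signal types of a parent-of-origin height scan: an
opposing-parental-effect variant and a paternal-only variant inside an
"imprinted" region, plus common additive, rare additive and recessive
variants elsewhere.  Effects are sized so the signals are detectable at
this cohort size.

Writes the cohort as standard files under scratch/cohort/ (VCF, FAM,
phenotype TSV, truth TSV, impact-class annotation, imprinted-region BED)
for the downstream numbered scripts.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from poegwas import genio
from poegwas.synthetic import (
    ArchitectureSpec,
    CausalVariant,
    SimulatedCohort,
    simulate_haplotypes,
    simulate_pedigree,
    simulate_phenotypes,
    truth_table,
)

SEED = 20161116
OUT = Path("scratch/cohort")


def pick_variant(freq, lo, hi, taken):
    """First variant whose minor allele frequency falls in [lo, hi]."""
    maf = np.minimum(freq, 1 - freq)
    for j in np.argsort(maf):
        if lo <= maf[j] <= hi and j not in taken:
            taken.add(int(j))
            return int(j)
    raise RuntimeError(f"no free variant with MAF in [{lo}, {hi}]")


def main() -> None:
    OUT.mkdir(parents=True, exist_ok=True)
    ped = simulate_pedigree(3000, 3, mating_rate=0.6, seed=SEED)
    geno = simulate_haplotypes(
        ped, 900, ld_block_size=(1, 2, 5, 8, 4), maf_range=(0.03, 0.5),
        target_r2=0.6, spacing=50_000, seed=SEED + 1,
    )
    freq = geno.allele_frequency()
    ids = geno.variants["id"]

    taken: set[int] = set()
    j_opposing = pick_variant(freq, 0.04, 0.08, taken)
    j_paternal = pick_variant(freq, 0.12, 0.25, taken)
    j_add_common = pick_variant(freq, 0.25, 0.5, taken)
    j_add_rare = pick_variant(freq, 0.03, 0.06, taken)
    j_recessive = pick_variant(freq, 0.35, 0.5, taken)

    causal = (
        CausalVariant(ids[j_opposing], "opposing", a_p=-0.45, a_m=0.25),
        CausalVariant(ids[j_paternal], "paternal", a_p=-0.35),
        CausalVariant(ids[j_add_common], "additive", a=0.25),
        CausalVariant(ids[j_add_rare], "additive", a=0.55),
        CausalVariant(ids[j_recessive], "recessive", a_r=0.55),
    )
    height = ArchitectureSpec(causal=causal, trait_sd=6.6, trait="height",
                              year_effect=0.05)
    birth = height.scaled(0.6, trait_sd=2.5, trait="birth_length")

    cohort = SimulatedCohort(ped, geno)
    phen_height = simulate_phenotypes(cohort, height, seed=SEED + 2)
    phen_birth = simulate_phenotypes(cohort, birth, seed=SEED + 3)
    truth = truth_table(height, geno)

    # impact classes: the rare additive causal plays a missense analogue
    rng = np.random.default_rng(SEED + 4)
    impact = pd.Series("low", index=ids)
    moderate = rng.choice(ids, size=60, replace=False)
    impact[moderate] = "moderate"
    impact[ids[j_add_rare]] = "moderate"
    impact[rng.choice(ids, size=9, replace=False)] = "high"

    # "imprinted" regions: +/- 100 kb around the two PoE variants
    pos = geno.variants["pos"]
    rows = [
        ("1", max(int(pos[j]) - 100_000, 0), int(pos[j]) + 100_000)
        for j in (j_opposing, j_paternal)
    ]
    regions = genio.RegionSet(
        pd.DataFrame(rows, columns=["chrom", "start", "end"]), label="imprinted"
    ).merge()

    genio.write_phased_vcf(geno, str(OUT / "cohort.vcf"))
    genio.write_pedigree(ped, str(OUT / "cohort.fam"))
    genio.write_phenotypes(
        pd.concat([phen_height, phen_birth], ignore_index=True),
        str(OUT / "phenotypes.tsv"),
    )
    truth.to_csv(OUT / "truth.tsv", sep="\t", index=False)
    genio.write_annotation(dict(impact), str(OUT / "annotation.tsv"))
    genio.write_regions(regions, str(OUT / "imprinted_regions.bed"))

    print(f"cohort: {len(ped)} individuals ({len(ped.founders())} founders), "
          f"{geno.n_variants} variants")
    print("causal truth:")
    print(truth.to_string(index=False))
    print(f"files written under {OUT}/")


if __name__ == "__main__":
    main()
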