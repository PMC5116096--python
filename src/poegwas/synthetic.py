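"""Synthetic pedigreed cohorts with known parental origin of every allele.

The generator emulates the features of a founder-population cohort that the
association pipeline depends on: a multi-generation pedigree, phased
LD-structured haplotypes whose parental origin is known exactly, and
quantitative phenotypes generated under configurable genetic architectures
(additive, recessive, paternal-only, maternal-only, opposing parental
effects, and optional non-transmitted maternal-genotype effects) on top of a
kinship-correlated polygenic background.

LD is produced by a blockwise ancestor-copying scheme: all variants in a
block share an allele frequency, and each founder haplotype copies a latent
block ancestor allele with per-site "mutation" probability mu, giving a
tunable within-block correlation r^2 = (1 - mu)^4.  Meiosis applies one
crossover per parent at a uniform position.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .core import (
    FEMALE,
    MALE,
    MISSING_PARENT,
    OrderedGenotypeMatrix,
    Pedigree,
    PedigreeError,
)

MODELS = ("additive", "recessive", "paternal", "maternal", "opposing")


@dataclass(frozen=True)
class CausalVariant:
    """One causal variant of the simulated architecture.

    Effect sizes are on the standardized (s.d.) scale of the trait.  Which
    of them is used depends on ``model``; ``opposing`` uses both ``a_p``
    and ``a_m`` (typically with opposite signs).  ``maternal_genotype``
    is the effect of the mother's full genotype on the child irrespective
    of transmission (an in-utero style effect).
    """

    variant_id: str
    model: str
    a: float = 0.0
    a_r: float = 0.0
    a_p: float = 0.0
    a_m: float = 0.0
    maternal_genotype: float = 0.0

    def __post_init__(self) -> None:
        if self.model not in MODELS:
            raise ValueError(f"unknown model {self.model!r}")


@dataclass(frozen=True)
class ArchitectureSpec:
    """Genetic architecture of a simulated trait.

    Parameters
    ----------
    causal :
        The causal variants and their effects (s.d. units).
    trait_sd :
        Phenotypic standard deviation in physical units (cm); used only
        to place raw values on a measurement scale.  Defaults to the
        adult-height value of 6.6 cm.
    background_h2 :
        Variance of the kinship-correlated polygenic background on the
        standardized scale (full sibs correlate by half of this).  The
        default 0.8 matches the narrow-sense heritability commonly
        estimated for adult height.
    sex_means :
        Mean raw value per sex (cm).
    year_effect :
        Linear secular trend in cm per year of birth, to give the
        year-of-birth correction something to remove.
    trait :
        Trait label carried into the phenotype table.
    """

    causal: tuple[CausalVariant, ...] = ()
    trait_sd: float = 6.6
    background_h2: float = 0.8
    sex_means: tuple[float, float] = (178.8, 165.6)  # (male, female)
    year_effect: float = 0.0
    self_report_fraction: float = 0.3
    trait: str = "height"

    def __post_init__(self) -> None:
        if self.trait_sd <= 0:
            raise ValueError("trait_sd must be positive")
        if not 0 <= self.background_h2 < 1:
            raise ValueError("background_h2 must be in [0, 1)")

    def scaled(self, factor: float, trait_sd: float, trait: str) -> "ArchitectureSpec":
        """Second-trait architecture sharing the causal variants with all
        standardized effects scaled by ``factor`` (e.g. a birth-length
        analogue of an adult-height architecture)."""
        causal = tuple(
            replace(
                c,
                a=c.a * factor,
                a_r=c.a_r * factor,
                a_p=c.a_p * factor,
                a_m=c.a_m * factor,
                maternal_genotype=c.maternal_genotype * factor,
            )
            for c in self.causal
        )
        return replace(self, causal=causal, trait_sd=trait_sd, trait=trait)


@dataclass
class SimulatedCohort:
    """A pedigree, its ordered genotypes, phenotypes and the ground truth."""

    pedigree: Pedigree
    genotypes: OrderedGenotypeMatrix
    phenotypes: dict[str, pd.DataFrame] = field(default_factory=dict)
    truth: pd.DataFrame | None = None


# ---------------------------------------------------------------------------
# pedigree


def simulate_pedigree(
    n_founders: int,
    n_generations: int,
    mating_rate: float = 0.8,
    seed: int = 0,
    mean_children: float = 2.0,
) -> Pedigree:
    """Simulate a multi-generation pedigree.

    Generation 1 is ``n_founders`` founders with alternating sexes.  Each
    later generation pairs the previous generation's males and females at
    random (avoiding full-sib matings when possible); a fraction
    ``mating_rate`` of the possible couples mate and each has at least one
    child, with extra children Poisson-distributed around
    ``mean_children``.

    Raises :class:`PedigreeError` if offspring are requested but the
    previous generation has no possible couple.
    """
    if n_founders < 2:
        raise PedigreeError("need at least 2 founders")
    if n_generations < 1:
        raise PedigreeError("need at least 1 generation")
    if not 0 < mating_rate <= 1:
        raise PedigreeError("mating_rate must be in (0, 1]")
    rng = np.random.default_rng(seed)

    rows: list[tuple[str, str, str, int]] = []  # iid, father, mother, sex
    current: list[tuple[str, int, frozenset]] = []  # iid, sex, parent set
    for i in range(n_founders):
        sex = MALE if i % 2 == 0 else FEMALE
        iid = f"F{i + 1}"
        rows.append((iid, MISSING_PARENT, MISSING_PARENT, sex))
        current.append((iid, sex, frozenset()))

    counter = 0
    for gen in range(2, n_generations + 1):
        males = [p for p in current if p[1] == MALE]
        females = [p for p in current if p[1] == FEMALE]
        if not males or not females:
            raise PedigreeError(
                f"generation {gen - 1} has no possible couple (all one sex)"
            )
        rng.shuffle(males)
        rng.shuffle(females)
        n_couples = max(1, round(mating_rate * min(len(males), len(females))))
        couples: list[tuple[str, str]] = []
        used: set[str] = set()
        for m_iid, _, m_par in males:
            if len(couples) == n_couples:
                break
            # prefer a non-sib partner; fall back to any free female
            pick = None
            for f_iid, _, f_par in females:
                if f_iid in used:
                    continue
                if m_par and m_par == f_par:
                    continue
                pick = f_iid
                break
            if pick is None:
                for f_iid, _, _ in females:
                    if f_iid not in used:
                        pick = f_iid
                        break
            if pick is None:
                break
            used.add(pick)
            couples.append((m_iid, pick))
        if not couples:
            raise PedigreeError(f"no mating possible at generation {gen}")

        nxt: list[tuple[str, int, frozenset]] = []
        child_idx = 0
        for father, mother in couples:
            n_children = 1 + rng.poisson(max(mean_children - 1, 0))
            parent_set = frozenset((father, mother))
            for _ in range(n_children):
                counter += 1
                iid = f"G{gen}_{counter}"
                sex = MALE if child_idx % 2 == 0 else FEMALE
                child_idx += 1
                rows.append((iid, father, mother, sex))
                nxt.append((iid, sex, parent_set))
        current = nxt

    table = pd.DataFrame(rows, columns=["iid", "father", "mother", "sex"])
    table.insert(0, "fam", "FAM1")
    return Pedigree(table)


def founder_pedigree(n: int, seed: int = 0) -> Pedigree:
    """``n`` unrelated individuals with alternating sexes."""
    table = pd.DataFrame(
        {
            "fam": [f"FAM{i + 1}" for i in range(n)],
            "iid": [f"F{i + 1}" for i in range(n)],
            "father": MISSING_PARENT,
            "mother": MISSING_PARENT,
            "sex": [MALE if i % 2 == 0 else FEMALE for i in range(n)],
        }
    )
    return Pedigree(table)


def trio_pedigree(n_trios: int) -> Pedigree:
    """``n_trios`` independent father-mother-child families."""
    rows = []
    for i in range(n_trios):
        fam = f"T{i + 1}"
        rows.append((fam, f"{fam}_dad", MISSING_PARENT, MISSING_PARENT, MALE))
        rows.append((fam, f"{fam}_mum", MISSING_PARENT, MISSING_PARENT, FEMALE))
        sex = MALE if i % 2 == 0 else FEMALE
        rows.append((fam, f"{fam}_kid", f"{fam}_dad", f"{fam}_mum", sex))
    return Pedigree(pd.DataFrame(rows, columns=["fam", "iid", "father", "mother", "sex"]))


# ---------------------------------------------------------------------------
# haplotypes


def simulate_haplotypes(
    pedigree: Pedigree,
    n_variants: int,
    ld_block_size: int | tuple[int, ...] = 1,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
    target_r2: float = 0.5,
    chrom: str = "1",
    spacing: int = 1000,
    frequencies: np.ndarray | None = None,
) -> OrderedGenotypeMatrix:
    """Phased founder haplotypes with blockwise LD, dropped through the
    pedigree with one crossover per meiosis.

    Variants in the same block share an allele frequency (drawn uniformly
    from ``maf_range`` unless ``frequencies`` is given) and correlate at
    roughly ``target_r2``; blocks are independent.  ``ld_block_size`` may
    be a single size or a repeating pattern of sizes (mixed block lengths
    give LD scores a realistic spread).  The child's paternal
    haplotype is the father's recombined gamete, so parental origin is
    exact by construction.  Imputation info is set to 1.0.
    """
    lo, hi = maf_range
    if not (0 < lo <= hi <= 0.5):
        raise ValueError("maf_range must be within (0, 0.5]")
    pattern = (
        (ld_block_size,) if np.isscalar(ld_block_size) else tuple(ld_block_size)
    )
    if any(b < 1 for b in pattern):
        raise ValueError("ld_block_size must be >= 1")
    rng = np.random.default_rng(seed)
    order = pedigree.topological_order()
    n = len(order)

    variants = pd.DataFrame(
        {
            "chrom": chrom,
            "pos": (np.arange(n_variants) + 1) * spacing,
            "id": [f"var{j + 1}" for j in range(n_variants)],
            "ref": "A",
            "alt": "C",
            "info": 1.0,
        }
    )
    if n_variants == 0:
        empty = np.zeros((n, 0))
        return OrderedGenotypeMatrix(order, variants, empty.copy(), empty.copy())

    sizes: list[int] = []
    while sum(sizes) < n_variants:
        sizes.extend(pattern)
    n_blocks = len(sizes)
    block_of = np.repeat(np.arange(n_blocks), sizes)[:n_variants]
    if frequencies is None:
        block_freq = rng.uniform(lo, hi, size=n_blocks)
        freqs = block_freq[block_of]
    else:
        freqs = np.asarray(frequencies, dtype=float)
        if freqs.shape != (n_variants,):
            raise ValueError("frequencies must have length n_variants")
    mu = 1.0 - float(np.clip(target_r2, 0.0, 1.0)) ** 0.25

    founders = set(pedigree.founders())
    idx = {iid: i for i, iid in enumerate(order)}
    pat = np.empty((n, n_variants), dtype=float)
    mat = np.empty((n, n_variants), dtype=float)
    parent_of = {
        r.iid: (r.father, r.mother) for r in pedigree.table.itertuples()
    }

    def founder_haplotype() -> np.ndarray:
        anc = rng.uniform(size=n_blocks)[block_of]  # block-level latent
        hap = (anc < freqs).astype(float)
        mut = rng.uniform(size=n_variants) < mu
        hap[mut] = (rng.uniform(size=mut.sum()) < freqs[mut]).astype(float)
        return hap

    def gamete(i: int) -> np.ndarray:
        cut = rng.integers(0, n_variants + 1)
        first_pat = rng.uniform() < 0.5
        a, b = (pat[i], mat[i]) if first_pat else (mat[i], pat[i])
        g = a.copy()
        g[cut:] = b[cut:]
        return g

    for iid in order:
        i = idx[iid]
        if iid in founders:
            pat[i] = founder_haplotype()
            mat[i] = founder_haplotype()
        else:
            father, mother = parent_of[iid]
            pat[i] = gamete(idx[father]) if father in idx else founder_haplotype()
            mat[i] = gamete(idx[mother]) if mother in idx else founder_haplotype()

    return OrderedGenotypeMatrix(order, variants, pat, mat)


# ---------------------------------------------------------------------------
# phenotypes


def _polygenic_background(
    pedigree: Pedigree, h2: float, rng: np.random.Generator
) -> pd.Series:
    """Gaussian polygenic value transmitted as allele-like halves.

    Each founder carries two independent N(0, h2/2) half-values; a child
    receives one randomly chosen half from each parent.  The resulting
    values have variance h2 and covariance h2 * 2*phi between relatives,
    which is exactly the covariance structure the kinship model absorbs.
    """
    order = pedigree.topological_order()
    founders = set(pedigree.founders())
    parent_of = {r.iid: (r.father, r.mother) for r in pedigree.table.itertuples()}
    halves: dict[str, np.ndarray] = {}
    sd = np.sqrt(h2 / 2.0) if h2 > 0 else 0.0
    for iid in order:
        if iid in founders:
            halves[iid] = rng.normal(0.0, sd, size=2) if h2 > 0 else np.zeros(2)
        else:
            father, mother = parent_of[iid]
            hp = halves[father][rng.integers(2)] if father in halves else rng.normal(0.0, sd)
            hm = halves[mother][rng.integers(2)] if mother in halves else rng.normal(0.0, sd)
            halves[iid] = np.array([hp, hm])
    return pd.Series({iid: halves[iid].sum() for iid in order})


def genetic_values(
    genotypes: OrderedGenotypeMatrix,
    pedigree: Pedigree,
    causal: tuple[CausalVariant, ...],
) -> np.ndarray:
    """Standardized-scale genetic value of each sample under the stated
    causal architecture.  Raises on a monomorphic causal variant."""
    g = np.zeros(genotypes.n_samples)
    freq = genotypes.allele_frequency()
    sample_pos = {s: i for i, s in enumerate(genotypes.samples)}
    mother_of = dict(zip(pedigree.table["iid"], pedigree.table["mother"]))
    for cv in causal:
        j = genotypes.variant_index(cv.variant_id)
        f = freq[j]
        if not 0.0 < f < 1.0:
            raise ValueError(
                f"causal variant {cv.variant_id!r} is monomorphic (f={f})"
            )
        p, m = genotypes.paternal[:, j], genotypes.maternal[:, j]
        if cv.model == "additive":
            g += cv.a * (p + m)
        elif cv.model == "recessive":
            g += cv.a_r * ((p >= 1) & (m >= 1)).astype(float)
        elif cv.model == "paternal":
            g += cv.a_p * p
        elif cv.model == "maternal":
            g += cv.a_m * m
        elif cv.model == "opposing":
            g += cv.a_p * p + cv.a_m * m
        if cv.maternal_genotype != 0.0:
            add = p + m
            mg = np.full(genotypes.n_samples, 2.0 * f)  # founders: expectation
            for iid, i in sample_pos.items():
                mo = mother_of.get(iid, MISSING_PARENT)
                if mo in sample_pos:
                    mg[i] = add[sample_pos[mo]]
            g += cv.maternal_genotype * mg
    return g


def simulate_phenotypes(
    cohort: SimulatedCohort,
    spec: ArchitectureSpec,
    seed: int = 0,
) -> pd.DataFrame:
    """Raw phenotype table for one trait under ``spec``.

    The standardized-scale signal (causal effects + polygenic background +
    unit-completing Gaussian noise) is mapped to physical units through
    ``trait_sd`` and per-sex means, with an optional secular year-of-birth
    trend, yielding columns ``iid, trait, value, sex, year_of_birth,
    source`` ready for :func:`poegwas.phenotype.adjust_and_standardize`.
    """
    rng = np.random.default_rng(seed)
    ped, geno = cohort.pedigree, cohort.genotypes
    g = genetic_values(geno, ped, spec.causal)
    bg = _polygenic_background(ped, spec.background_h2, rng)
    bg = bg.reindex(geno.samples).to_numpy()
    resid_sd = np.sqrt(max(1.0 - spec.background_h2, 1e-8))
    y_std = g + bg + rng.normal(0.0, resid_sd, size=geno.n_samples)

    sex = (
        ped.table.set_index("iid")["sex"].reindex(geno.samples).to_numpy()
    )
    year = rng.integers(1920, 1981, size=geno.n_samples)
    means = np.where(sex == MALE, spec.sex_means[0], spec.sex_means[1])
    value = means + spec.year_effect * (year - 1950) + spec.trait_sd * y_std
    source = np.where(
        rng.uniform(size=geno.n_samples) < spec.self_report_fraction,
        "self-reported",
        "measured",
    )
    return pd.DataFrame(
        {
            "iid": geno.samples,
            "trait": spec.trait,
            "value": value,
            "sex": sex,
            "year_of_birth": year,
            "source": source,
        }
    )


def truth_table(spec: ArchitectureSpec, genotypes: OrderedGenotypeMatrix) -> pd.DataFrame:
    """Ground-truth causal table (variant, model, effects, frequency)."""
    freq = genotypes.allele_frequency()
    rows = []
    for cv in spec.causal:
        j = genotypes.variant_index(cv.variant_id)
        rows.append(
            {
                "variant": cv.variant_id,
                "model": cv.model,
                "a": cv.a,
                "a_r": cv.a_r,
                "a_p": cv.a_p,
                "a_m": cv.a_m,
                "maternal_genotype": cv.maternal_genotype,
                "maf": min(freq[j], 1 - freq[j]),
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "variant", "model", "a", "a_r", "a_p", "a_m",
            "maternal_genotype", "maf",
        ],
    )


def simulate_cohort(
    pedigree: Pedigree,
    spec: ArchitectureSpec,
    n_variants: int,
    ld_block_size: int = 1,
    maf_range: tuple[float, float] = (0.05, 0.5),
    seed: int = 0,
    target_r2: float = 0.5,
    frequencies: np.ndarray | None = None,
) -> SimulatedCohort:
    """Convenience wrapper: haplotypes + one phenotype + truth table."""
    geno = simulate_haplotypes(
        pedigree,
        n_variants,
        ld_block_size=ld_block_size,
        maf_range=maf_range,
        seed=seed,
        target_r2=target_r2,
        frequencies=frequencies,
    )
    cohort = SimulatedCohort(pedigree=pedigree, genotypes=geno)
    cohort.phenotypes[spec.trait] = simulate_phenotypes(cohort, spec, seed=seed + 1)
    cohort.truth = truth_table(spec, geno)
    return cohort
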