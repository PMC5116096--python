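"""Kinship-aware association testing under four genetic models.

The quantitative trait y is modelled within each family cluster as
N(alpha + beta * g, sigma^2 * V), where g is the expected allele count
under the genetic model being tested (additive, recessive, paternal or
maternal), V = theta*K + (1-theta)*I and K = 2*Phi is the scaled pedigree
kinship matrix.  theta = 1 gives the covariance-proportional-to-kinship
model; in practice traits carry a non-genetic variance share, and theta is
estimated once per trait by profile maximum likelihood under the
intercept-only model (see :meth:`Whitener.estimate_theta`) so that the
per-variant tests stay calibrated.  Maximum-likelihood estimates of
(alpha, beta, sigma^2) are then obtained by whitening each cluster in the
eigenbasis of its K block, pooling, and solving ordinary least squares;
the association test is the Wald chi-squared (beta/se)^2 with a
chi-squared(1) two-sided P-value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import sparse
from scipy.stats import chi2

from .core import OrderedGenotypeMatrix
from .kinship import ClusterPartition, KinshipMatrix, PSD_JITTER

MODEL_TAGS = ("additive", "recessive", "paternal", "maternal")

INFO_MIN = 0.8
COLLINEARITY_R2 = 0.999


@dataclass
class ModelDosage:
    """Per-sample expected allele count under one genetic model.

    Ranges: additive in [0, 2]; recessive (expected homozygosity) and the
    parental dosages in [0, 1].  NaN marks a sample missing for this
    variant x model.
    """

    model: str
    variant: str
    values: np.ndarray
    samples: list[str]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.samples),):
            raise ValueError("dosage length does not match samples")


@dataclass
class AssociationResult:
    """One variant x model test: effect in trait s.d. units, its standard
    error, the Wald chi-squared and two-sided P, plus the ML nuisance
    estimates (intercept alpha, residual scale sigma2)."""

    variant: str
    model: str
    beta: float = np.nan
    se: float = np.nan
    chi2: float = np.nan
    p: float = np.nan
    n: int = 0
    sigma2: float = np.nan
    alpha: float = np.nan
    untestable: bool = False
    note: str = ""


def build_dosage(
    genotypes: OrderedGenotypeMatrix, variant: str, model: str
) -> ModelDosage:
    """Model dosage for one variant from ordered genotypes.

    additive = paternal + maternal dosage; recessive = product of the two
    haplotype dosages (the homozygote indicator for hard calls);
    paternal / maternal = that haplotype's dosage alone.  Alt-allele
    orientation follows the genotype matrix.
    """
    if model not in MODEL_TAGS:
        raise ValueError(f"unknown model {model!r}")
    j = genotypes.variant_index(variant)
    p, m = genotypes.paternal[:, j], genotypes.maternal[:, j]
    if model == "additive":
        vals = p + m
    elif model == "recessive":
        vals = p * m
    else:
        vals = p if model == "paternal" else m
        if np.all(np.isnan(vals)):
            raise ValueError(
                f"{model} model for {variant!r}: no sample has ordered dosages"
            )
    return ModelDosage(model=model, variant=variant, values=vals, samples=list(genotypes.samples))


class Whitener:
    """Block-diagonal whitening operator for a cluster partition.

    The working covariance is sigma^2 * V with V = theta*K + (1-theta)*I
    restricted to each cluster; ``theta=1`` is the covariance-proportional-
    to-kinship model, while an estimated theta < 1 admits a non-genetic
    (independent) variance share.  Each cluster's K block is
    eigendecomposed once, so whitening any vector for any theta is a
    sparse matvec plus a rescale, and the profile likelihood over theta
    (:meth:`estimate_theta`) is cheap.  ``samples`` gives the row order of
    inputs and outputs (clusters concatenated).
    """

    def __init__(
        self,
        kin: KinshipMatrix,
        partition: ClusterPartition,
        include: set[str] | None = None,
        theta: float = 1.0,
        jitter: float = PSD_JITTER,
    ) -> None:
        samples: list[str] = []
        eigvals = []
        blocks = []
        identity = True
        if kin.is_identity():
            # unrelated cohort: whitening is the identity, skip the blocks
            for iids in partition:
                if include is not None:
                    iids = [i for i in iids if i in include]
                samples.extend(iids)
            self.samples = samples
            self.theta = float(theta)
            self._identity = True
            self._lam = np.ones(len(samples))
            self._ut = None
            return
        for iids in partition:
            if include is not None:
                iids = [i for i in iids if i in include]
            if not iids:
                continue
            k = kin.submatrix(iids)
            samples.extend(iids)
            if identity and np.allclose(k, np.eye(len(iids))):
                continue
            if identity:
                # first non-identity block: backfill identity blocks
                done = len(samples) - len(iids)
                eigvals.append(np.ones(done))
                blocks.append(sparse.identity(done, format="csr"))
                identity = False
            lam, u = np.linalg.eigh(k)
            eigvals.append(np.maximum(lam, jitter))
            blocks.append(sparse.csr_matrix(u.T))
        self.samples = samples
        self.theta = float(theta)
        self._identity = identity
        if identity:
            self._lam = np.ones(len(samples))
            self._ut = None
        else:
            self._lam = np.concatenate(eigvals) if eigvals else np.ones(0)
            self._ut = sparse.csr_matrix(sparse.block_diag(blocks))

    def _scale(self, theta: float) -> np.ndarray:
        d = theta * self._lam + (1.0 - theta)
        return np.sqrt(np.maximum(d, PSD_JITTER))

    def rotate(self, arr: np.ndarray) -> np.ndarray:
        """U' arr (the theta-independent part of whitening)."""
        if self._ut is None:
            return np.asarray(arr, dtype=float)
        return self._ut @ np.asarray(arr, dtype=float)

    def whiten(self, arr: np.ndarray, theta: float | None = None) -> np.ndarray:
        """V^{-1/2} arr with V = theta*K + (1-theta)*I per cluster; rows
        of ``arr`` follow ``self.samples``."""
        theta = self.theta if theta is None else theta
        z = self.rotate(arr)
        if self._identity and theta == 1.0:
            return z
        s = self._scale(theta)
        return z / s if z.ndim == 1 else z / s[:, None]

    def estimate_theta(self, y: np.ndarray, grid: int = 201) -> float:
        """Profile-ML estimate of the kinship variance share theta under
        the intercept-only model y ~ N(alpha, sigma^2 V(theta)).

        The per-cluster eigenbasis makes each profile evaluation O(n); a
        grid search over [0, 1] (open at 1 only through the PSD floor) is
        refined by a golden-section step.  Returns the argmax.
        """
        y = np.asarray(y, dtype=float)
        zy = self.rotate(y)
        zx = self.rotate(np.ones(len(y)))
        n = len(y)

        def nll(theta: float) -> float:
            d = np.maximum(theta * self._lam + (1.0 - theta), PSD_JITTER)
            w = 1.0 / d
            alpha = (zx * zy * w).sum() / (zx * zx * w).sum()
            rss = ((zy - alpha * zx) ** 2 * w).sum()
            return n * np.log(rss / n) + np.log(d).sum()

        thetas = np.linspace(0.0, 1.0, grid)
        vals = [nll(t) for t in thetas]
        best = thetas[int(np.argmin(vals))]
        from scipy.optimize import minimize_scalar

        lo = max(0.0, best - 1.0 / (grid - 1))
        hi = min(1.0, best + 1.0 / (grid - 1))
        res = minimize_scalar(nll, bounds=(lo, hi), method="bounded")
        return float(res.x) if res.fun <= nll(best) else float(best)


def _aligned(values: pd.Series | np.ndarray, samples: list[str]) -> np.ndarray:
    if isinstance(values, pd.Series):
        return values.reindex(samples).to_numpy(dtype=float)
    return np.asarray(values, dtype=float)


def _wald(
    zx: np.ndarray, zy: np.ndarray, contrast: np.ndarray
) -> tuple[np.ndarray, float, float, float]:
    """Whitened least squares plus a Wald test of contrast @ beta = 0."""
    coef, _, rank, _ = np.linalg.lstsq(zx, zy, rcond=None)
    resid = zy - zx @ coef
    n = len(zy)
    sigma2 = float(resid @ resid) / n
    xtx_inv = np.linalg.pinv(zx.T @ zx)
    var = float(contrast @ xtx_inv @ contrast) * sigma2
    est = float(contrast @ coef)
    se = float(np.sqrt(var)) if var > 0 else np.nan
    return coef, sigma2, est, se


def gls_fit(
    y: pd.Series,
    g: ModelDosage,
    kin: KinshipMatrix,
    partition: ClusterPartition,
    whitener: Whitener | None = None,
    covariates: pd.DataFrame | None = None,
    theta: float = 1.0,
) -> AssociationResult:
    """ML fit of y = alpha + beta*g (+ covariates) with Cov = sigma^2*K.

    Samples missing either y or g are dropped for this fit (complete
    case).  A prebuilt :class:`Whitener` may be supplied when no
    missingness filtering is needed (its sample set must match the
    complete cases); otherwise one is built for the complete-case subset.
    Returns an untestable result if the dosage has zero variance.
    """
    yv = _aligned(y, g.samples)
    ok = ~(np.isnan(yv) | np.isnan(g.values))
    if covariates is not None:
        cov = covariates.reindex(g.samples).to_numpy(dtype=float)
        ok &= ~np.isnan(cov).any(axis=1)
    iids = [s for s, keep in zip(g.samples, ok) if keep]
    if whitener is None or set(whitener.samples) != set(iids):
        whitener = Whitener(kin, partition, include=set(iids), theta=theta)
    order = whitener.samples
    pos = {s: i for i, s in enumerate(g.samples)}
    rows = np.array([pos[s] for s in order], dtype=int)
    gv = g.values[rows]
    yv = yv[rows]
    n = len(order)
    if n < 3 or np.nanvar(gv) <= 0:
        return AssociationResult(
            variant=g.variant, model=g.model, n=n,
            untestable=True, note="zero dosage variance",
        )
    x = np.column_stack([np.ones(n), gv])
    if covariates is not None:
        x = np.column_stack([x, cov[rows]])
    zx = whitener.whiten(x)
    zy = whitener.whiten(yv)
    contrast = np.zeros(x.shape[1])
    contrast[1] = 1.0
    coef, sigma2, beta, se = _wald(zx, zy, contrast)
    stat = (beta / se) ** 2 if se and np.isfinite(se) and se > 0 else np.nan
    return AssociationResult(
        variant=g.variant,
        model=g.model,
        beta=beta,
        se=se,
        chi2=stat,
        p=float(chi2.sf(stat, df=1)) if np.isfinite(stat) else np.nan,
        n=n,
        sigma2=sigma2,
        alpha=float(coef[0]),
    )


def test_parent_contrast(
    y: pd.Series,
    paternal: ModelDosage,
    maternal: ModelDosage,
    kin: KinshipMatrix,
    partition: ClusterPartition,
    whitener: Whitener | None = None,
    theta: float = 1.0,
) -> AssociationResult:
    """Wald test of beta_pat = beta_mat in the joint two-dosage model.

    Fits y = alpha + b_p*g_pat + b_m*g_mat with the kinship covariance and
    tests the difference b_p - b_m against chi-squared(1); this is the
    "paternal versus maternal" test used to call opposing parental
    effects.  Near-collinear parental dosages (r^2 > 0.999) are flagged
    untestable.
    """
    if paternal.samples != maternal.samples:
        raise ValueError("parental dosages must share the same sample order")
    yv = _aligned(y, paternal.samples)
    ok = ~(np.isnan(yv) | np.isnan(paternal.values) | np.isnan(maternal.values))
    iids = [s for s, keep in zip(paternal.samples, ok) if keep]
    if whitener is None or set(whitener.samples) != set(iids):
        whitener = Whitener(kin, partition, include=set(iids), theta=theta)
    pos = {s: i for i, s in enumerate(paternal.samples)}
    rows = np.array([pos[s] for s in whitener.samples], dtype=int)
    gp, gm, yv = paternal.values[rows], maternal.values[rows], yv[rows]
    n = len(rows)
    res = AssociationResult(variant=paternal.variant, model="pat_vs_mat", n=n)
    if n < 4 or np.var(gp) <= 0 or np.var(gm) <= 0:
        res.untestable, res.note = True, "degenerate parental dosage"
        return res
    r = np.corrcoef(gp, gm)[0, 1]
    if r * r > COLLINEARITY_R2:
        res.untestable, res.note = True, "collinear parental dosages"
        return res
    x = np.column_stack([np.ones(n), gp, gm])
    zx = whitener.whiten(x)
    zy = whitener.whiten(yv)
    coef, sigma2, diff, se = _wald(zx, zy, np.array([0.0, 1.0, -1.0]))
    stat = (diff / se) ** 2 if se and np.isfinite(se) and se > 0 else np.nan
    res.beta, res.se, res.chi2 = diff, se, stat
    res.p = float(chi2.sf(stat, df=1)) if np.isfinite(stat) else np.nan
    res.sigma2, res.alpha = sigma2, float(coef[0])
    return res


def results_to_frame(results: list[AssociationResult]) -> pd.DataFrame:
    cols = [
        "variant", "model", "beta", "se", "chi2", "p", "n",
        "sigma2", "alpha", "untestable", "note",
    ]
    return pd.DataFrame([vars(r) for r in results], columns=cols)


def genome_scan(
    genotypes: OrderedGenotypeMatrix,
    y: pd.Series,
    kin: KinshipMatrix,
    partition: ClusterPartition,
    models: tuple[str, ...] = MODEL_TAGS,
    info_min: float = INFO_MIN,
    whitener: Whitener | None = None,
    theta: float = 1.0,
) -> pd.DataFrame:
    """Scan all variants under the requested models.

    Filters: variants with imputation info <= ``info_min`` are skipped
    everywhere; the recessive model is fit only when at least one
    minor-allele homozygote is observed.  Skipped variant x model
    combinations are kept as untestable rows with a note.  The returned
    frame carries a ``best`` flag marking, per variant, the model with the
    most significant association.
    """
    bad = [m for m in models if m not in MODEL_TAGS]
    if bad:
        raise ValueError(f"unknown models {bad}")
    if whitener is None:
        have_y = set(y.dropna().index) & set(genotypes.samples)
        whitener = Whitener(kin, partition, include=have_y, theta=theta)
    results: list[AssociationResult] = []
    info = genotypes.variants["info"].to_numpy(dtype=float)
    for j, vid in enumerate(genotypes.variants["id"]):
        if not info[j] > info_min:
            for model in models:
                results.append(
                    AssociationResult(
                        variant=vid, model=model, untestable=True,
                        note=f"info {info[j]:.3g} <= {info_min}",
                    )
                )
            continue
        pat, mat = genotypes.paternal[:, j], genotypes.maternal[:, j]
        add = pat + mat
        f = np.nanmean(add) / 2.0
        for model in models:
            if model == "recessive":
                minor_hom = (
                    np.nansum((pat >= 0.5) & (mat >= 0.5)) if f <= 0.5
                    else np.nansum((pat < 0.5) & (mat < 0.5))
                )
                if minor_hom < 1:
                    results.append(
                        AssociationResult(
                            variant=vid, model=model, untestable=True,
                            note="no minor-allele homozygote",
                        )
                    )
                    continue
            dose = build_dosage(genotypes, vid, model)
            results.append(gls_fit(y, dose, kin, partition, whitener=whitener))
    frame = results_to_frame(results)
    tested = frame.loc[~frame["untestable"] & frame["p"].notna()]
    best_idx = tested.groupby("variant")["p"].idxmin()
    frame["best"] = False
    frame.loc[best_idx, "best"] = True
    return frame
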