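"""PCA for population structure, with two supervised variants.

Supervised PCA (svPCA) fits the axes on a chosen subset of individuals —
typically excluding highly drifted isolates whose large genetic distances
would otherwise dominate the leading components — and projects everyone
onto them.  Geographic svPCA fits only on breeds at the geographic
extremes of a study area so that the leading axis aligns with the
geographic cline.

Standardization follows the variance standardization used by PLINK:
dosages are centered by 2*p and scaled by sqrt(2*p*(1-p)), with p the
allele frequency of the fit subset; missing dosages are imputed to the
fit-subset mean.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, AnnotatedGenotypes, GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass
class PCAModel:
    snp_ids: list[str]
    center: np.ndarray  # per-SNP mean dosage 2*p of the fit subset
    scale: np.ndarray  # per-SNP sqrt(2 p (1-p))
    loadings: np.ndarray  # (n_model_snps, k), orthonormal columns
    eigenvalues: np.ndarray  # (k,)
    fit_samples: list[str]

    @property
    def k(self) -> int:
        return self.loadings.shape[1]

    def to_dict(self) -> dict:
        return {
            "snp_ids": self.snp_ids,
            "center": self.center.tolist(),
            "scale": self.scale.tolist(),
            "loadings": self.loadings.tolist(),
            "eigenvalues": self.eigenvalues.tolist(),
            "fit_samples": self.fit_samples,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PCAModel":
        return cls(
            list(d["snp_ids"]),
            np.asarray(d["center"], dtype=float),
            np.asarray(d["scale"], dtype=float),
            np.asarray(d["loadings"], dtype=float),
            np.asarray(d["eigenvalues"], dtype=float),
            list(d["fit_samples"]),
        )


def _standardize(calls: np.ndarray, center: np.ndarray, scale: np.ndarray) -> np.ndarray:
    x = calls.astype(float)
    x[calls == MISSING] = np.nan
    x = np.where(np.isnan(x), center[None, :], x)
    return (x - center[None, :]) / scale[None, :]


def pca_fit(gm: GenotypeMatrix, fit_subset: list[str] | None = None, k: int = 2) -> PCAModel:
    """Fit a PCA model on ``fit_subset`` (default: all samples).

    Monomorphic SNPs within the fit subset carry no variance and are
    dropped from the model (logged).  Loadings are the top-k right singular
    vectors of the standardized fit matrix; each loading's sign is fixed so
    its largest-magnitude entry is positive.
    """
    fit_subset = list(fit_subset) if fit_subset is not None else list(gm.samples)
    missing_ids = set(fit_subset) - set(gm.samples)
    if missing_ids:
        raise ValueError(f"fit subset not in data: {sorted(missing_ids)}")
    if len(fit_subset) < k + 1:
        raise ValueError("fit subset too small for k components")

    fit_gm = gm.select_samples(fit_subset)
    calls = fit_gm.calls
    nonmiss = (calls != MISSING).sum(axis=0)
    dose = np.where(calls == MISSING, 0, calls).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(nonmiss > 0, dose / (2.0 * nonmiss), np.nan)
    keep = (nonmiss > 0) & (p > 0) & (p < 1)
    dropped = int((~keep).sum())
    if dropped:
        log.info("dropping %d monomorphic/all-missing SNPs from PCA model", dropped)
    p = p[keep]
    center = 2.0 * p
    scale = np.sqrt(2.0 * p * (1.0 - p))

    x = _standardize(calls[:, keep], center, scale)
    # columns have exact zero mean by construction of center
    u, s, vt = np.linalg.svd(x, full_matrices=False)
    loadings = vt[:k].T
    # deterministic sign: largest-magnitude entry of each loading positive
    for c in range(loadings.shape[1]):
        col = loadings[:, c]
        if col[np.argmax(np.abs(col))] < 0:
            loadings[:, c] = -col
    eigenvalues = (s[:k] ** 2) / (len(fit_subset) - 1)
    snp_ids = [gm.snps["snp_id"].iloc[i] for i in np.flatnonzero(keep)]
    return PCAModel(snp_ids, center, scale, loadings, eigenvalues, fit_subset)


def pca_project(model: PCAModel, gm: GenotypeMatrix) -> pd.DataFrame:
    """Project every individual onto the model's axes.

    Each individual is standardized with the MODEL's centering and scaling
    (never its own cohort's), so fit individuals reproduce their fit
    scores.  Individuals missing more than half the model SNPs are scored
    but flagged in the ``flagged`` column.
    """
    sub = gm.select_snps(model.snp_ids)
    x = _standardize(sub.calls, model.center, model.scale)
    scores = x @ model.loadings
    miss_frac = (sub.calls == MISSING).mean(axis=1)
    df = pd.DataFrame(
        scores, index=gm.samples,
        columns=[f"svPC{c + 1}" for c in range(model.k)],
    )
    df["flagged"] = miss_frac > 0.5
    return df


def geographic_svpca(
    ann: AnnotatedGenotypes, extreme_breed_sets: list[list[str]], k: int = 2
) -> tuple[PCAModel, pd.DataFrame]:
    """Fit PCA only on breeds at the geographic extremes; project all.

    ``extreme_breed_sets`` lists at least two sets of breed codes (e.g.
    north, southwest, southeast); the fit subset is the union of their
    individuals.
    """
    if len(extreme_breed_sets) < 2:
        raise ValueError("need >= 2 extreme breed sets")
    breeds = ann.meta["breed"]
    fit_ids: list[str] = []
    for bset in extreme_breed_sets:
        if not bset:
            raise ValueError("empty extreme breed set")
        sel = breeds.isin(bset).to_numpy()
        fit_ids.extend(np.asarray(ann.gm.samples)[sel])
    fit_ids = list(dict.fromkeys(fit_ids))
    model = pca_fit(ann.gm, fit_ids, k=k)
    return model, pca_project(model, ann.gm)


def average_scores_by_group(
    scores: pd.DataFrame, ann: AnnotatedGenotypes, by: str = "breed"
) -> pd.DataFrame:
    """Arithmetic mean of component scores per breed (or other group)."""
    comp_cols = [c for c in scores.columns if c.startswith("svPC")]
    joined = scores[comp_cols].copy()
    joined[by] = ann.meta.set_index(ann.meta["id"]).loc[scores.index, by].to_numpy()
    return joined.groupby(by, sort=True)[comp_cols].mean()
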