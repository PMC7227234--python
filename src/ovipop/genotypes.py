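"""Core genotype containers, metadata joining, and the QC filters every
downstream analysis consumes.

The central object is :class:`GenotypeMatrix`: an individuals x SNPs matrix of
diploid allele-B dosages (0/1/2) with ``-1`` as the missing sentinel, plus a
SNP map (chromosome, bp position, alleles) and ordered sample IDs.  Sample
metadata (breed, region, coordinates, metapopulation tag) lives in a
:class:`SampleTable` and is joined explicitly so that group-by-breed and
group-by-metapopulation queries are always resolvable.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MISSING = -1

SNP_COLUMNS = ["snp_id", "chrom", "pos", "allele_a", "allele_b"]


class ValidationError(ValueError):
    """Raised when a container violates its invariants."""


@dataclass
class GenotypeMatrix:
    """Diploid dosage matrix with SNP map and sample IDs.

    Parameters
    ----------
    samples : list of str
        Ordered individual IDs, unique.
    snps : pandas.DataFrame
        One row per SNP with columns ``snp_id, chrom, pos, allele_a,
        allele_b``; within a chromosome rows are sorted by position.
    calls : ndarray of int8, shape (n_samples, n_snps)
        Dosage of allele B: 0, 1, 2 or ``MISSING`` (-1).
    """

    samples: list[str]
    snps: pd.DataFrame
    calls: np.ndarray

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.snps = self.snps.reset_index(drop=True)
        self.calls = np.asarray(self.calls, dtype=np.int8)
        self.validate()

    def validate(self) -> None:
        if len(set(self.samples)) != len(self.samples):
            raise ValidationError("duplicate sample IDs")
        ids = self.snps["snp_id"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValidationError(f"duplicate SNP ID {dup!r}")
        if self.calls.shape != (len(self.samples), len(self.snps)):
            raise ValidationError(
                f"calls shape {self.calls.shape} does not match "
                f"{len(self.samples)} samples x {len(self.snps)} SNPs"
            )
        pos = self.snps["pos"].to_numpy()
        if len(pos) and (pos < 0).any():
            raise ValidationError("negative SNP position")
        for _, sub in self.snps.groupby("chrom", sort=False):
            p = sub["pos"].to_numpy()
            if (np.diff(p) < 0).any():
                raise ValidationError("SNPs not position-sorted within chromosome")
        bad = ~np.isin(self.calls, (0, 1, 2, MISSING))
        if bad.any():
            raise ValidationError("calls must be 0, 1, 2 or the missing sentinel")

    # -- basic queries -------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_snps(self) -> int:
        return len(self.snps)

    def missing_mask(self) -> np.ndarray:
        return self.calls == MISSING

    def sample_missing_rate(self) -> np.ndarray:
        return self.missing_mask().mean(axis=1)

    def snp_missing_rate(self) -> np.ndarray:
        return self.missing_mask().mean(axis=0)

    def dosages(self) -> np.ndarray:
        """Calls as float with missing as NaN."""
        out = self.calls.astype(float)
        out[self.calls == MISSING] = np.nan
        return out

    # -- subsetting ----------------------------------------------------

    def take_samples(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            [self.samples[i] for i in idx], self.snps.copy(), self.calls[idx]
        )

    def take_snps(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            list(self.samples), self.snps.iloc[idx], self.calls[:, idx]
        )

    def select_samples(self, ids) -> "GenotypeMatrix":
        lookup = {s: i for i, s in enumerate(self.samples)}
        missing = [s for s in ids if s not in lookup]
        if missing:
            raise ValidationError(f"unknown sample IDs: {missing}")
        return self.take_samples([lookup[s] for s in ids])

    def select_snps(self, snp_ids) -> "GenotypeMatrix":
        lookup = {s: i for i, s in enumerate(self.snps["snp_id"])}
        missing = [s for s in snp_ids if s not in lookup]
        if missing:
            raise ValidationError(f"unknown SNP IDs: {missing[:5]}")
        return self.take_snps([lookup[s] for s in snp_ids])

    def copy(self) -> "GenotypeMatrix":
        return GenotypeMatrix(list(self.samples), self.snps.copy(), self.calls.copy())

    def __eq__(self, other) -> bool:
        return (
            isinstance(other, GenotypeMatrix)
            and self.samples == other.samples
            and self.snps[SNP_COLUMNS].astype(str).equals(
                other.snps[SNP_COLUMNS].astype(str)
            )
            and np.array_equal(self.calls, other.calls)
        )


@dataclass
class SampleTable:
    """Individual -> breed -> region assignments with optional coordinates
    and metapopulation tags (e.g. mEMF, PRMS, mMER, nMER)."""

    table: pd.DataFrame  # columns: id, breed, region, lat, lon, metapop

    REQUIRED = ["id", "breed"]
    OPTIONAL = ["region", "lat", "lon", "metapop"]

    def __post_init__(self) -> None:
        t = self.table.copy()
        for col in self.REQUIRED:
            if col not in t.columns:
                raise ValidationError(f"sample table missing column {col!r}")
        for col in self.OPTIONAL:
            if col not in t.columns:
                t[col] = np.nan if col in ("lat", "lon") else None
        if t["id"].duplicated().any():
            raise ValidationError("duplicate individual IDs in sample table")
        if (t["breed"].astype(str).str.len() == 0).any():
            raise ValidationError("empty breed code")
        self.table = t.reset_index(drop=True)

    @classmethod
    def from_records(cls, records) -> "SampleTable":
        return cls(pd.DataFrame.from_records(records))

    @classmethod
    def read_tsv(cls, path) -> "SampleTable":
        return cls(pd.read_csv(path, sep="\t", dtype={"id": str, "breed": str}))

    def write_tsv(self, path) -> None:
        self.table.to_csv(path, sep="\t", index=False)

    def breed_of(self) -> dict[str, str]:
        return dict(zip(self.table["id"], self.table["breed"]))

    def ids_in_metapop(self, tag: str) -> list[str]:
        sel = self.table["metapop"] == tag
        return list(self.table.loc[sel, "id"])

    def ids_in_breed(self, breed: str) -> list[str]:
        return list(self.table.loc[self.table["breed"] == breed, "id"])


@dataclass
class AnnotatedGenotypes:
    """A GenotypeMatrix joined to its metadata, row-aligned."""

    gm: GenotypeMatrix
    meta: pd.DataFrame  # one row per gm sample, gm order

    def breeds(self) -> np.ndarray:
        return self.meta["breed"].to_numpy()

    def groups(self, by: str = "breed") -> dict[str, np.ndarray]:
        """Map group label -> row indices into gm, in gm order."""
        out: dict[str, np.ndarray] = {}
        labels = self.meta[by]
        for lab in pd.unique(labels.dropna()):
            out[lab] = np.flatnonzero((labels == lab).to_numpy())
        return out


def join_metadata(gm: GenotypeMatrix, st: SampleTable) -> AnnotatedGenotypes:
    """Join genotypes to sample metadata, preserving genotype order.

    Raises
    ------
    ValidationError
        If any genotyped individual lacks a metadata row (offenders listed).
    """
    t = st.table.set_index("id")
    absent = [s for s in gm.samples if s not in t.index]
    if absent:
        raise ValidationError(f"samples without metadata: {absent}")
    meta = t.loc[gm.samples].reset_index()
    return AnnotatedGenotypes(gm, meta)


# ---------------------------------------------------------------------------
# QC
# ---------------------------------------------------------------------------


@dataclass
class QCStep:
    name: str
    n_before: int
    n_after: int
    removed: dict[str, float] = field(default_factory=dict)  # id -> rate/stat

    def __post_init__(self) -> None:
        if self.n_before - len(self.removed) != self.n_after:
            raise ValidationError(
                f"QC step {self.name}: {self.n_before} - {len(self.removed)} "
                f"!= {self.n_after}"
            )


@dataclass
class QCReport:
    """Per-step record of what QC removed and why."""

    steps: list[QCStep] = field(default_factory=list)

    def add(self, step: QCStep) -> None:
        self.steps.append(step)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for s in self.steps:
            for ident, rate in s.removed.items():
                rows.append({"step": s.name, "id": ident, "stat": rate})
        return pd.DataFrame(rows, columns=["step", "id", "stat"])

    def summary(self) -> dict:
        return {
            s.name: {"before": s.n_before, "after": s.n_after,
                     "removed": len(s.removed)}
            for s in self.steps
        }


def filter_missingness(
    gm: GenotypeMatrix, max_rate: float = 0.10
) -> tuple[GenotypeMatrix, QCReport]:
    """Remove SNPs, then samples, with missing fraction above ``max_rate``.

    SNPs are filtered first and sample rates recomputed afterwards, matching
    the convention of the PLINK toolchain.  Removing a SNP can only lower a
    sample's missing rate, so the result has no sample or SNP above the
    threshold.
    """
    if not 0 <= max_rate <= 1:
        raise ValueError("max_rate must be in [0, 1]")
    report = QCReport()

    snp_rate = gm.snp_missing_rate()
    keep_snps = np.flatnonzero(snp_rate <= max_rate)
    removed_snps = {
        gm.snps["snp_id"].iloc[i]: float(snp_rate[i])
        for i in np.flatnonzero(snp_rate > max_rate)
    }
    gm2 = gm.take_snps(keep_snps) if len(removed_snps) else gm
    report.add(QCStep("snp_missingness", gm.n_snps, gm2.n_snps, removed_snps))

    samp_rate = gm2.sample_missing_rate() if gm2.n_snps else np.ones(gm2.n_samples)
    keep_samp = np.flatnonzero(samp_rate <= max_rate)
    removed_samp = {
        gm2.samples[i]: float(samp_rate[i])
        for i in np.flatnonzero(samp_rate > max_rate)
    }
    gm3 = gm2.take_samples(keep_samp) if len(removed_samp) else gm2
    report.add(QCStep("sample_missingness", gm2.n_samples, gm3.n_samples,
                      removed_samp))

    if gm3.n_samples == 0 or gm3.n_snps == 0:
        raise ValidationError("no data survive QC")
    return gm3, report


# ---------------------------------------------------------------------------
# LD pruning
# ---------------------------------------------------------------------------


def _pairwise_r2(x: np.ndarray, y: np.ndarray) -> float:
    """Squared Pearson correlation of two dosage vectors over
    pairwise-complete individuals; monomorphic -> 0."""
    ok = (x != MISSING) & (y != MISSING)
    if ok.sum() < 2:
        return 0.0
    xv = x[ok].astype(float)
    yv = y[ok].astype(float)
    sx = xv.std()
    sy = yv.std()
    if sx == 0 or sy == 0:
        return 0.0
    r = ((xv - xv.mean()) * (yv - yv.mean())).mean() / (sx * sy)
    return float(r * r)


def _window_r2_matrix(calls: np.ndarray) -> np.ndarray:
    """r^2 among SNP columns over pairwise-complete rows, vectorized.

    Missing handled by masked moments; monomorphic pairs get r^2 = 0.
    """
    g = calls.astype(float)
    ok = (calls != MISSING).astype(float)
    g0 = np.where(calls == MISSING, 0.0, g)
    n = ok.T @ ok  # pairwise-complete counts
    with np.errstate(divide="ignore", invalid="ignore"):
        s1 = g0.T @ ok  # sum of x over complete pairs
        s2 = ok.T @ g0  # sum of y
        sxy = g0.T @ g0
        sxx = (g0**2).T @ ok
        syy = ok.T @ (g0**2)
        cov = sxy / n - (s1 / n) * (s2 / n)
        vx = sxx / n - (s1 / n) ** 2
        vy = syy / n - (s2 / n) ** 2
        r2 = cov**2 / (vx * vy)
    r2 = np.where((n >= 2) & (vx > 0) & (vy > 0), r2, 0.0)
    np.fill_diagonal(r2, 0.0)
    return r2


def ld_prune(
    gm: GenotypeMatrix,
    window_snps: int = 50,
    step_snps: int = 50,
    r2_threshold: float = 0.03,
) -> tuple[GenotypeMatrix, QCReport]:
    """Greedy within-window LD pruning (PLINK ``--indep-pairwise`` semantics).

    Windows of ``window_snps`` SNPs advance by ``step_snps`` within each
    chromosome.  Within a window, while any retained pair exceeds
    ``r2_threshold``, the member with the higher missing rate is removed
    (tie: the later SNP in map order).  Deterministic for fixed input.
    """
    if window_snps < 2:
        raise ValueError("window_snps must be >= 2")
    miss_rate = gm.snp_missing_rate()
    keep = np.ones(gm.n_snps, dtype=bool)
    chrom = gm.snps["chrom"].to_numpy()

    for c in pd.unique(chrom):
        idx = np.flatnonzero(chrom == c)
        start = 0
        while start < len(idx):
            win = idx[start : start + window_snps]
            if len(win) >= 2:
                _prune_window(gm.calls, win, keep, miss_rate, r2_threshold)
            start += step_snps

    removed = {
        gm.snps["snp_id"].iloc[i]: float(miss_rate[i])
        for i in np.flatnonzero(~keep)
    }
    out = gm.take_snps(np.flatnonzero(keep))
    report = QCReport()
    report.add(QCStep("ld_prune", gm.n_snps, out.n_snps, removed))
    return out, report


def _prune_window(calls, win, keep, miss_rate, thr) -> None:
    active = [i for i in win if keep[i]]
    if len(active) < 2:
        return
    sub = calls[:, active]
    r2 = _window_r2_matrix(sub)
    alive = np.ones(len(active), dtype=bool)
    while True:
        hit = None
        for a in range(len(active)):
            if not alive[a]:
                continue
            for b in range(a + 1, len(active)):
                if alive[b] and r2[a, b] > thr:
                    hit = (a, b)
                    break
            if hit:
                break
        if hit is None:
            break
        a, b = hit
        ia, ib = active[a], active[b]
        # drop the less complete SNP; tie -> the later one in map order
        victim = a if miss_rate[ia] > miss_rate[ib] else b
        alive[victim] = False
        keep[active[victim]] = False


# ---------------------------------------------------------------------------
# Per-group subsampling
# ---------------------------------------------------------------------------


def subsample_per_group(
    ann: AnnotatedGenotypes, max_n: int, seed: int, by: str = "breed"
) -> GenotypeMatrix:
    """Keep at most ``max_n`` individuals per group, sampled reproducibly.

    Groups with ``max_n`` or fewer members pass through whole.
    """
    if max_n < 1:
        raise ValueError("max_n must be >= 1")
    rng = np.random.default_rng(seed)
    chosen: list[int] = []
    for lab in sorted(ann.groups(by)):
        idx = ann.groups(by)[lab]
        if len(idx) <= max_n:
            chosen.extend(idx.tolist())
        else:
            chosen.extend(sorted(rng.choice(idx, size=max_n, replace=False)))
    chosen = sorted(chosen)
    return ann.gm.take_samples(chosen)
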