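"""Observed heterozygosity, runs of homozygosity (ROH), and the genomic
inbreeding coefficient F_ROH.

ROH are called by a deterministic maximal-run scan that enforces the stated
constraints directly: a run must span at least ``min_length_bp``, contain at
least ``min_snps`` markers at an average density above one SNP per
``1/min_density`` bp, never jump more than ``max_gap_bp`` between
consecutive markers, and contain at most ``max_het`` heterozygous and
``max_missing`` missing calls.  F_ROH is the summed ROH length divided by
the total autosome length (2452.06 Mb for the sheep genome).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotypes import MISSING, AnnotatedGenotypes, GenotypeMatrix

#: total length of the sheep autosomes, bp
SHEEP_AUTOSOME_BP = 2_452_060_000


@dataclass
class ROHParams:
    """Constraints a homozygous run must satisfy to be reported."""

    min_length_bp: int = 1_000_000
    min_snps: int = 31  # "more than 30"
    min_density: float = 1.0 / 100_000  # SNPs per bp
    max_gap_bp: int = 250_000
    max_missing: int = 1
    max_het: int = 1

    def __post_init__(self) -> None:
        if min(self.min_length_bp, self.min_snps, self.max_gap_bp) <= 0:
            raise ValueError("length/SNP/gap constraints must be positive")
        if self.min_density <= 0:
            raise ValueError("min_density must be positive")
        if self.max_missing < 0 or self.max_het < 0:
            raise ValueError("max_missing and max_het must be >= 0")


@dataclass
class ROHSegment:
    individual: str
    chrom: str
    start: int  # bp of first SNP, 1-based inclusive
    end: int  # bp of last SNP, 1-based inclusive
    n_snps: int
    n_het: int
    n_missing: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def observed_heterozygosity(ann: AnnotatedGenotypes, by: str = "breed") -> pd.DataFrame:
    """Per-group mean observed heterozygosity.

    Per individual, H_o is the fraction of heterozygous calls among
    non-missing calls; the group value is the mean over its individuals.
    Individuals with no non-missing calls are excluded with a warning.

    Returns a DataFrame with columns ``group, n, ho``.
    """
    calls = ann.gm.calls
    het = (calls == 1).sum(axis=1)
    nonmiss = (calls != MISSING).sum(axis=1)
    valid = nonmiss > 0
    if not valid.all():
        import warnings

        bad = [ann.gm.samples[i] for i in np.flatnonzero(~valid)]
        warnings.warn(f"individuals with all calls missing excluded: {bad}")
    ho = np.full(len(calls), np.nan)
    ho[valid] = het[valid] / nonmiss[valid]

    rows = []
    for lab, idx in sorted(ann.groups(by).items()):
        vals = ho[idx]
        vals = vals[~np.isnan(vals)]
        rows.append({"group": lab, "n": len(vals), "ho": float(vals.mean())})
    return pd.DataFrame(rows)


def individual_heterozygosity(gm: GenotypeMatrix) -> pd.Series:
    calls = gm.calls
    nonmiss = (calls != MISSING).sum(axis=1)
    with np.errstate(invalid="ignore"):
        ho = (calls == 1).sum(axis=1) / np.where(nonmiss > 0, nonmiss, np.nan)
    return pd.Series(ho, index=gm.samples, name="ho")


# ---------------------------------------------------------------------------
# ROH scan
# ---------------------------------------------------------------------------


def detect_roh(
    gm: GenotypeMatrix,
    params: ROHParams | None = None,
    autosomes: set[str] | None = None,
) -> list[ROHSegment]:
    """Scan every individual x chromosome for maximal qualifying runs.

    The scan grows a candidate run SNP by SNP; a gap larger than
    ``max_gap_bp`` or a het/missing call beyond the allowance closes it.
    A closed run is emitted iff the length, SNP-count and density
    constraints all pass; emitted segments are trimmed to start and end on
    a homozygous call and never overlap within an individual-chromosome.
    """
    params = params or ROHParams()
    segments: list[ROHSegment] = []
    chrom_arr = gm.snps["chrom"].to_numpy()
    pos_all = gm.snps["pos"].to_numpy()
    for c in pd.unique(chrom_arr):
        if autosomes is not None and c not in autosomes:
            continue
        snp_idx = np.flatnonzero(chrom_arr == c)
        if len(snp_idx) < params.min_snps:
            continue
        pos = pos_all[snp_idx]
        for i, ind in enumerate(gm.samples):
            calls = gm.calls[i, snp_idx]
            segments.extend(_scan_chromosome(ind, str(c), pos, calls, params))
    return segments


def _scan_chromosome(ind, chrom, pos, calls, params: ROHParams) -> list[ROHSegment]:
    out: list[ROHSegment] = []
    n = len(pos)
    start = 0  # candidate run start index
    het_at: list[int] = []
    miss_at: list[int] = []
    j = 0
    while j < n:
        broke = False
        if j > start and pos[j] - pos[j - 1] > params.max_gap_bp:
            broke = True
            restart = j
        elif calls[j] == 1 and len([h for h in het_at if h >= start]) >= params.max_het:
            broke = True
            offenders = [h for h in het_at if h >= start]
            restart = (offenders[0] + 1) if offenders else j + 1
        elif calls[j] == MISSING and (
            len([m for m in miss_at if m >= start]) >= params.max_missing
        ):
            broke = True
            offenders = [m for m in miss_at if m >= start]
            restart = (offenders[0] + 1) if offenders else j + 1
        if broke:
            seg = _emit(ind, chrom, pos, calls, start, j - 1, params)
            if seg is not None:
                out.append(seg)
                restart = max(restart, _index_after(pos, seg.end, start, j))
            start = restart
            if start > j:
                j = start
            continue
        if calls[j] == 1:
            het_at.append(j)
        elif calls[j] == MISSING:
            miss_at.append(j)
        j += 1
    seg = _emit(ind, chrom, pos, calls, start, n - 1, params)
    if seg is not None:
        out.append(seg)
    return out


def _index_after(pos, end_bp, lo, hi) -> int:
    k = lo
    while k <= hi and pos[k] <= end_bp:
        k += 1
    return k


def _emit(ind, chrom, pos, calls, a, b, params: ROHParams) -> ROHSegment | None:
    # trim so the emitted segment starts and ends on a homozygous call
    while a <= b and calls[a] != 0 and calls[a] != 2:
        a += 1
    while b >= a and calls[b] != 0 and calls[b] != 2:
        b -= 1
    if b < a:
        return None
    n_snps = b - a + 1
    length = int(pos[b] - pos[a] + 1)
    seg_calls = calls[a : b + 1]
    n_het = int((seg_calls == 1).sum())
    n_miss = int((seg_calls == MISSING).sum())
    if n_snps < params.min_snps:
        return None
    if length < params.min_length_bp:
        return None
    if n_snps / length <= params.min_density:
        return None
    return ROHSegment(ind, chrom, int(pos[a]), int(pos[b]), n_snps, n_het, n_miss)


def roh_to_frame(segments: list[ROHSegment]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "id": s.individual,
                "chrom": s.chrom,
                "start": s.start,
                "end": s.end,
                "nsnp": s.n_snps,
                "nhet": s.n_het,
                "nmiss": s.n_missing,
            }
            for s in segments
        ],
        columns=["id", "chrom", "start", "end", "nsnp", "nhet", "nmiss"],
    )


def f_roh(
    segments: list[ROHSegment],
    samples: list[str],
    autosome_length_bp: int = SHEEP_AUTOSOME_BP,
) -> pd.Series:
    """Per-individual F_ROH = summed ROH length / total autosome length."""
    total = {s: 0 for s in samples}
    for seg in segments:
        total[seg.individual] = total.get(seg.individual, 0) + seg.length
    return pd.Series(
        {s: total[s] / autosome_length_bp for s in samples}, name="f_roh"
    )


def diversity_table(
    ann: AnnotatedGenotypes,
    params: ROHParams | None = None,
    autosome_length_bp: int = SHEEP_AUTOSOME_BP,
    by: str = "breed",
) -> pd.DataFrame:
    """Per-breed H_o and mean F_ROH (columns ``group, n, ho, f_roh``)."""
    ho = observed_heterozygosity(ann, by=by)
    segs = detect_roh(ann.gm, params)
    froh = f_roh(segs, ann.gm.samples, autosome_length_bp)
    means = []
    for lab, idx in sorted(ann.groups(by).items()):
        means.append(float(froh.iloc[idx].mean()))
    ho["f_roh"] = means
    return ho
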