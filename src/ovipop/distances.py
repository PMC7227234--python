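"""Genetic distances and trees: allele-sharing distance (ASD) between
individuals, Reynolds' coancestry distance between pooled populations,
neighbor-joining trees, and PHYLIP/NEXUS export (the NEXUS distance block
feeds external neighbor-net drawing, e.g. in SplitsTree).
"""

from __future__ import annotations

import io
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import MISSING, AnnotatedGenotypes, GenotypeMatrix

log = logging.getLogger(__name__)


@dataclass
class DistanceMatrix:
    labels: list[str]
    values: np.ndarray
    kind: str = ""  # "ASD" | "Reynolds" | ...

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        n = len(self.labels)
        if self.values.shape != (n, n):
            raise ValueError("distance matrix shape does not match labels")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("non-finite distances")
        if not np.allclose(self.values, self.values.T):
            raise ValueError("distance matrix not symmetric")
        if not np.allclose(np.diag(self.values), 0):
            raise ValueError("nonzero diagonal")
        if (self.values < -1e-12).any():
            raise ValueError("negative distances")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.labels, columns=self.labels)

    def to_phylip(self) -> str:
        out = [f"{len(self.labels)}"]
        for lab, row in zip(self.labels, self.values):
            out.append(lab + "  " + "  ".join(f"{v:.8f}" for v in row))
        return "\n".join(out) + "\n"


# ---------------------------------------------------------------------------
# Allele-sharing distance
# ---------------------------------------------------------------------------


def asd_matrix(gm: GenotypeMatrix, min_overlap: int = 100) -> DistanceMatrix:
    """Pairwise allele-sharing distance between individuals.

    Over pairwise-complete SNPs, a pair shares ``2 - |g_i - g_j|`` alleles
    at each SNP; ASD = 1 - shared / (2 * n SNPs).  Pairs overlapping at
    fewer than ``min_overlap`` SNPs raise an error naming the pair.
    """
    if gm.n_samples < 2:
        raise ValueError("need >= 2 individuals")
    g = gm.calls.astype(np.float64)
    ok = (gm.calls != MISSING).astype(np.float64)
    g0 = np.where(gm.calls == MISSING, 0.0, g)

    n_pair = ok @ ok.T
    # sum over complete SNPs of |gi - gj| via the identity
    # |a-b| = a + b - 2*min(a,b); dosages in {0,1,2} let us expand by level
    is1 = ((gm.calls == 1).astype(np.float64))
    is2 = ((gm.calls == 2).astype(np.float64))
    # min(a,b) = 1*[a>=1][b>=1] + 1*[a>=2][b>=2]
    ge1 = is1 + is2
    ge2 = is2
    sum_min = ge1 @ ge1.T + ge2 @ ge2.T
    sum_a = g0 @ ok.T
    sum_b = ok @ g0.T
    sum_abs = sum_a + sum_b - 2 * sum_min

    low = (n_pair < min_overlap) & ~np.eye(gm.n_samples, dtype=bool)
    if low.any():
        i, j = np.argwhere(low)[0]
        raise ValueError(
            f"pair ({gm.samples[i]}, {gm.samples[j]}) overlaps at only "
            f"{int(n_pair[i, j])} SNPs (min_overlap={min_overlap})"
        )
    with np.errstate(invalid="ignore", divide="ignore"):
        asd = sum_abs / (2.0 * n_pair)
    np.fill_diagonal(asd, 0.0)
    asd = (asd + asd.T) / 2
    return DistanceMatrix(list(gm.samples), asd, kind="ASD")


# ---------------------------------------------------------------------------
# Population allele frequencies and Reynolds distance
# ---------------------------------------------------------------------------


@dataclass
class FreqTable:
    """Per-population alternate-allele frequencies with non-missing allele
    counts (2 x genotyped individuals); frequency is NaN iff count is 0."""

    pops: list[str]
    snp_ids: list[str]
    freq: np.ndarray  # (n_pops, n_snps), NaN = missing
    count: np.ndarray  # (n_pops, n_snps) int, non-missing allele count

    def __post_init__(self) -> None:
        self.freq = np.asarray(self.freq, dtype=float)
        self.count = np.asarray(self.count, dtype=int)
        if self.freq.shape != (len(self.pops), len(self.snp_ids)):
            raise ValueError("freq shape mismatch")
        if self.count.shape != self.freq.shape:
            raise ValueError("count shape mismatch")
        if (self.count % 2).any() or (self.count < 0).any():
            raise ValueError("allele counts must be even and >= 0")
        if not ((self.count == 0) == np.isnan(self.freq)).all():
            raise ValueError("frequency must be missing iff count is 0")

    def row(self, pop: str) -> tuple[np.ndarray, np.ndarray]:
        i = self.pops.index(pop)
        return self.freq[i], self.count[i]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.freq.T, index=self.snp_ids, columns=self.pops)


def pool_freqs(
    ann: AnnotatedGenotypes, grouping: dict[str, str] | None = None, by: str = "breed"
) -> FreqTable:
    """Alternate-allele frequency per group and SNP.

    ``grouping`` optionally maps each breed (or metapopulation tag) to a
    pooled group label; unmapped breeds keep their own label.  Frequency is
    (sum of dosages) / (2 x non-missing individuals).
    """
    labels = ann.meta[by].astype(str)
    if grouping is not None:
        labels = labels.map(lambda b: grouping.get(b, b))
    pops = sorted(pd.unique(labels.dropna()))
    n_snps = ann.gm.n_snps
    freq = np.full((len(pops), n_snps), np.nan)
    count = np.zeros((len(pops), n_snps), dtype=int)
    calls = ann.gm.calls
    for k, pop in enumerate(pops):
        idx = np.flatnonzero((labels == pop).to_numpy())
        sub = calls[idx]
        nonmiss = (sub != MISSING).sum(axis=0)
        dose = np.where(sub == MISSING, 0, sub).sum(axis=0)
        count[k] = 2 * nonmiss
        with np.errstate(invalid="ignore", divide="ignore"):
            freq[k] = np.where(nonmiss > 0, dose / (2.0 * nonmiss), np.nan)
    return FreqTable(pops, list(ann.gm.snps["snp_id"]), freq, count)


def reynolds_distance(freqs: FreqTable, pop_a: str, pop_b: str) -> float:
    """Reynolds' (1983) coancestry distance, ratio-of-sums form.

    D = sum_l (pA - pB)^2 / sum_l [pA + pB - 2 pA pB] over loci where both
    populations are genotyped.  Both sums are accumulated over loci before
    dividing, which makes monomorphic shared loci harmless.
    """
    fa, _ = freqs.row(pop_a)
    fb, _ = freqs.row(pop_b)
    ok = ~np.isnan(fa) & ~np.isnan(fb)
    if not ok.any():
        raise ValueError(f"no shared genotyped SNPs between {pop_a} and {pop_b}")
    pa, pb = fa[ok], fb[ok]
    num = float(((pa - pb) ** 2).sum())
    den = float((pa + pb - 2 * pa * pb).sum())
    if den == 0:
        log.info("Reynolds denominator 0 for (%s, %s); D = 0 by continuity",
                 pop_a, pop_b)
        return 0.0
    return num / den


def reynolds_matrix(freqs: FreqTable) -> DistanceMatrix:
    n = len(freqs.pops)
    d = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            d[i, j] = d[j, i] = reynolds_distance(freqs, freqs.pops[i], freqs.pops[j])
    return DistanceMatrix(list(freqs.pops), d, kind="Reynolds")


# ---------------------------------------------------------------------------
# Neighbor joining
# ---------------------------------------------------------------------------


@dataclass
class TreeNode:
    """Node of an unrooted tree serialized via its newick string."""

    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.name]
        out = []
        for child, _ in self.children:
            out.extend(child.leaves())
        return out

    def to_newick(self) -> str:
        return self._newick() + ";"

    def _newick(self) -> str:
        if not self.children:
            return self.name
        inner = ",".join(
            f"{c._newick()}:{bl:.10g}" for c, bl in self.children
        )
        return f"({inner})"

    def leaf_distances(self) -> dict[tuple[str, str], float]:
        """Path lengths between all leaf pairs (oracle for additivity)."""
        paths: dict[str, float] = {}

        def walk(node, acc):
            if not node.children:
                paths[node.name] = acc
                return
            for child, bl in node.children:
                walk(child, acc + bl)

        dists: dict[tuple[str, str], float] = {}

        def collect(node):
            below = []
            if not node.children:
                return [(node.name, 0.0)]
            for child, bl in node.children:
                sub = [(n, d + bl) for n, d in collect(child)]
                for (n1, d1) in sub:
                    for (n2, d2) in below:
                        key = tuple(sorted((n1, n2)))
                        dists[key] = d1 + d2
                below.extend(sub)
            return below

        collect(self)
        return dists


def nj_tree(dm: DistanceMatrix) -> TreeNode:
    """Classical Saitou-Nei neighbor joining, deterministic.

    On equal Q-criterion the lexicographically smallest label pair is
    merged; negative branch lengths are clamped to zero (deficit logged).
    """
    n = len(dm.labels)
    if n < 3:
        raise ValueError("need >= 3 labels for NJ")
    if not np.all(np.isfinite(dm.values)):
        raise ValueError("non-finite distances")

    d = dm.values.astype(float).copy()
    nodes: list[TreeNode] = [TreeNode(name=l) for l in dm.labels]
    # label key per active node for the deterministic tie-break: the
    # smallest leaf name under that node
    keys: list[str] = list(dm.labels)
    active = list(range(n))

    while len(active) > 3:
        m = len(active)
        sub = d[np.ix_(active, active)]
        r = sub.sum(axis=1)
        q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(q, np.inf)
        qmin = q.min()
        # candidates within numerical tolerance of the minimum
        cand = np.argwhere(q <= qmin + 1e-12)
        best = min(
            (tuple(sorted((keys[active[a]], keys[active[b]]))), a, b)
            for a, b in cand
            if a < b
        )
        _, a, b = best
        ia, ib = active[a], active[b]
        dij = sub[a, b]
        la = 0.5 * dij + (r[a] - r[b]) / (2 * (m - 2))
        lb = dij - la
        la, lb = _clamp(la), _clamp(lb)
        new = TreeNode(children=[(nodes[ia], la), (nodes[ib], lb)])
        nodes.append(new)
        keys.append(min(keys[ia], keys[ib]))
        # distances from the new node
        newrow = np.zeros(len(nodes))
        for c in active:
            if c in (ia, ib):
                continue
            newrow[: len(nodes) - 1][c] = 0.5 * (d[ia, c] + d[ib, c] - dij)
        d = np.pad(d, ((0, 1), (0, 1)))
        d[-1, : len(newrow)] = newrow
        d[: len(newrow), -1] = newrow
        active = [c for c in active if c not in (ia, ib)] + [len(nodes) - 1]

    # terminal three-star: closed-form branch lengths
    i, j, k = active
    li = _clamp(0.5 * (d[i, j] + d[i, k] - d[j, k]))
    lj = _clamp(0.5 * (d[i, j] + d[j, k] - d[i, k]))
    lk = _clamp(0.5 * (d[i, k] + d[j, k] - d[i, j]))
    return TreeNode(children=[(nodes[i], li), (nodes[j], lj), (nodes[k], lk)])


def _clamp(x: float) -> float:
    if x < 0:
        if x < -1e-9:
            log.info("negative NJ branch length %.3g clamped to 0", x)
        return 0.0
    return float(x)


# ---------------------------------------------------------------------------
# NEXUS export
# ---------------------------------------------------------------------------


def _nexus_label(label: str) -> str:
    if any(ch in label for ch in " \t()[]{}/\\,;:=*'\"`<>-"):
        return "'" + label.replace("'", "''") + "'"
    return label


def export_nexus(dm: DistanceMatrix) -> str:
    """NEXUS TAXA + DISTANCES blocks (for SplitsTree neighbor-net)."""
    n = len(dm.labels)
    lines = ["#NEXUS", "", "BEGIN TAXA;", f"  DIMENSIONS NTAX={n};",
             "  TAXLABELS"]
    lines += [f"    {_nexus_label(l)}" for l in dm.labels]
    lines += ["  ;", "END;", "", "BEGIN DISTANCES;",
              f"  DIMENSIONS NTAX={n};",
              "  FORMAT TRIANGLE=BOTH DIAGONAL LABELS;", "  MATRIX"]
    for lab, row in zip(dm.labels, dm.values):
        lines.append(
            "    " + _nexus_label(lab) + " " + " ".join(f"{v:.8f}" for v in row)
        )
    lines += ["  ;", "END;", ""]
    return "\n".join(lines)


def read_nexus_distances(text: str) -> DistanceMatrix:
    """Parse the DISTANCES block written by :func:`export_nexus`."""
    lines = iter(text.splitlines())
    labels: list[str] = []
    rows: list[list[float]] = []
    in_matrix = False
    for line in lines:
        s = line.strip()
        if s.upper().startswith("MATRIX"):
            in_matrix = True
            continue
        if in_matrix:
            if s == ";" or s.upper().startswith("END"):
                break
            toks = _tokenize_nexus_row(s)
            if not toks:
                continue
            labels.append(toks[0])
            rows.append([float(t) for t in toks[1:]])
    return DistanceMatrix(labels, np.array(rows), kind="parsed")


def _tokenize_nexus_row(s: str) -> list[str]:
    toks, i = [], 0
    while i < len(s):
        if s[i].isspace():
            i += 1
        elif s[i] == "'":
            j = i + 1
            buf = []
            while j < len(s):
                if s[j] == "'" and j + 1 < len(s) and s[j + 1] == "'":
                    buf.append("'")
                    j += 2
                elif s[j] == "'":
                    break
                else:
                    buf.append(s[j])
                    j += 1
            toks.append("".join(buf))
            i = j + 1
        else:
            j = i
            while j < len(s) and not s[j].isspace():
                j += 1
            toks.append(s[i:j])
            i = j
    return toks
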