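"""Synthetic genotype datasets with known truth.

Population structure follows the Balding-Nichols model: each SNP has an
ancestral frequency p drawn from a uniform law, and a population with
drift coefficient F relative to its parent draws its frequency from
Beta(p(1-F)/F, (1-p)(1-F)/F), which has mean p and variance F p(1-p).
Admixture nodes mix their sources' frequencies with known proportions, so
individuals from them have per-SNP success probability sum_c alpha_c p_c.
Genotypes are Binomial(2, .) draws; no linkage disequilibrium is
simulated (LD-dependent tests construct correlation explicitly).

The generator also supports implanting homozygous runs (ROH fixtures),
masking genotypes at a missing rate, and SNP-array ascertainment by a
minor-allele-frequency floor within named discovery populations.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .genotypes import (
    MISSING,
    SNP_COLUMNS,
    AnnotatedGenotypes,
    GenotypeMatrix,
    SampleTable,
    join_metadata,
)


@dataclass
class PopSpec:
    """One node of the population graph.

    A node either drifts from its parent with coefficient ``fst`` (parent
    None means the ancestral pool) or, if ``admix`` is given, mixes the
    named source nodes with the stated proportions (which must sum to 1).
    ``n`` individuals are sampled from the node (0 = unsampled internal
    node).
    """

    name: str
    n: int = 0
    parent: str | None = None
    fst: float = 0.0
    admix: dict[str, float] | None = None
    region: str | None = None
    lat: float | None = None
    lon: float | None = None
    metapop: str | None = None


@dataclass
class SimConfig:
    populations: list[PopSpec]
    n_snps: int = 5000
    chromosomes: list[tuple[str, int]] = field(
        default_factory=lambda: [("1", 100_000_000), ("2", 80_000_000),
                                 ("3", 60_000_000)]
    )
    freq_low: float = 0.05
    freq_high: float = 0.95
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        names = [p.name for p in self.populations]
        if len(set(names)) != len(names):
            raise ValueError("duplicate population names")
        known = set()
        for p in self.populations:
            if not (0 <= p.fst < 1):
                raise ValueError(f"{p.name}: drift F must be in [0, 1)")
            if p.admix is not None:
                if abs(sum(p.admix.values()) - 1) > 1e-9:
                    raise ValueError(f"{p.name}: admixture proportions must sum to 1")
                for s in p.admix:
                    if s not in known:
                        raise ValueError(f"{p.name}: admixture source {s!r} "
                                         "must be declared earlier (acyclic graph)")
            elif p.parent is not None and p.parent not in known:
                raise ValueError(f"{p.name}: parent {p.parent!r} must be "
                                 "declared earlier (acyclic graph)")
            known.add(p.name)
        if not 0 <= self.missing_rate <= 1:
            raise ValueError("missing_rate must be in [0, 1]")


@dataclass
class SimTruth:
    pop_freqs: dict[str, np.ndarray]
    drift_f: dict[str, float]
    ancestry: dict[str, dict[str, float]]  # individual -> {source pop: alpha}
    roh_intervals: list[tuple[str, str, int, int]]  # (id, chrom, start, end)
    seed: int


def _drift(rng: np.random.Generator, p: np.ndarray, f: float) -> np.ndarray:
    if f == 0:
        return p.copy()
    a = p * (1 - f) / f
    b = (1 - p) * (1 - f) / f
    out = rng.beta(a, b)
    # keep frequencies strictly inside (0,1) so downstream estimators behave
    return np.clip(out, 1e-6, 1 - 1e-6)


def simulate(config: SimConfig) -> tuple[GenotypeMatrix, SampleTable, SimTruth]:
    """Draw genotypes, metadata and ground truth from the configured graph."""
    rng = np.random.default_rng(config.seed)

    # SNP map: SNPs split across chromosomes proportional to length,
    # positions uniform then sorted
    lengths = np.array([L for _, L in config.chromosomes], dtype=float)
    n_per = np.floor(config.n_snps * lengths / lengths.sum()).astype(int)
    n_per[0] += config.n_snps - n_per.sum()
    snp_rows = []
    i0 = 0
    for (label, length), m in zip(config.chromosomes, n_per):
        pos = np.sort(rng.integers(1, length + 1, size=m))
        for p_ in pos:
            snp_rows.append((f"snp{i0:06d}", label, int(p_), "A", "B"))
            i0 += 1
    snps = pd.DataFrame(snp_rows, columns=SNP_COLUMNS)

    p_anc = rng.uniform(config.freq_low, config.freq_high, config.n_snps)
    freqs: dict[str, np.ndarray] = {}
    for pop in config.populations:
        if pop.admix is not None:
            f = np.zeros(config.n_snps)
            for src, alpha in pop.admix.items():
                f += alpha * freqs[src]
            freqs[pop.name] = f
        else:
            parent = p_anc if pop.parent is None else freqs[pop.parent]
            freqs[pop.name] = _drift(rng, parent, pop.fst)

    samples: list[str] = []
    meta_rows = []
    call_blocks = []
    ancestry: dict[str, dict[str, float]] = {}
    for pop in config.populations:
        if pop.n == 0:
            continue
        prob = freqs[pop.name]
        block = rng.binomial(2, prob, size=(pop.n, config.n_snps)).astype(np.int8)
        call_blocks.append(block)
        comp = dict(pop.admix) if pop.admix is not None else {pop.name: 1.0}
        for i in range(pop.n):
            sid = f"{pop.name}_{i:03d}"
            samples.append(sid)
            ancestry[sid] = comp
            meta_rows.append(
                {"id": sid, "breed": pop.name, "region": pop.region,
                 "lat": pop.lat, "lon": pop.lon, "metapop": pop.metapop}
            )
    calls = np.vstack(call_blocks) if call_blocks else np.empty((0, config.n_snps), np.int8)

    if config.missing_rate > 0:
        mask = rng.random(calls.shape) < config.missing_rate
        calls[mask] = MISSING

    gm = GenotypeMatrix(samples, snps, calls)
    st = SampleTable(pd.DataFrame(meta_rows))
    truth = SimTruth(
        pop_freqs=freqs,
        drift_f={p.name: p.fst for p in config.populations},
        ancestry=ancestry,
        roh_intervals=[],
        seed=config.seed,
    )
    return gm, st, truth


def implant_roh(
    gm: GenotypeMatrix,
    individual: str,
    chrom: str,
    start: int,
    end: int,
    seed: int = 0,
    truth: SimTruth | None = None,
) -> GenotypeMatrix:
    """Return a copy with all calls of one individual in [start, end] made
    homozygous (a sampled haplotype doubled); the original is untouched."""
    rng = np.random.default_rng(seed)
    out = gm.copy()
    row = out.samples.index(individual)
    sel = (
        (out.snps["chrom"] == chrom)
        & (out.snps["pos"] >= start)
        & (out.snps["pos"] <= end)
    ).to_numpy()
    if sel.sum() < 2:
        import warnings

        warnings.warn(f"ROH interval {chrom}:{start}-{end} covers "
                      f"{int(sel.sum())} SNPs")
    g = out.calls[row, sel]
    hom = np.where(g == 2, 2, 0).astype(np.int8)
    undecided = (g == 1) | (g == MISSING)
    hom[undecided] = 2 * rng.integers(0, 2, size=int(undecided.sum())).astype(np.int8)
    out.calls[row, sel] = hom
    if truth is not None:
        truth.roh_intervals.append((individual, chrom, int(start), int(end)))
    return out


def ascertain_snps(
    ann: AnnotatedGenotypes, panel_pops: list[str], maf_floor: float
) -> GenotypeMatrix:
    """Keep only SNPs whose minor-allele frequency within the pooled
    discovery populations reaches ``maf_floor`` (emulates array design)."""
    if not panel_pops:
        raise ValueError("panel_pops must be non-empty")
    sel = ann.meta["breed"].isin(panel_pops).to_numpy()
    if not sel.any():
        raise ValueError(f"no individuals in discovery populations {panel_pops}")
    calls = ann.gm.calls[sel]
    nonmiss = (calls != MISSING).sum(axis=0)
    dose = np.where(calls == MISSING, 0, calls).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(nonmiss > 0, dose / (2.0 * nonmiss), np.nan)
    maf = np.minimum(p, 1 - p)
    keep = np.flatnonzero(~np.isnan(maf) & (maf >= maf_floor))
    if len(keep) == 0:
        raise ValueError("ascertainment removed every SNP")
    return ann.gm.take_snps(keep)


# ---------------------------------------------------------------------------
# Study-shaped preset
# ---------------------------------------------------------------------------


def paper_like_config(seed: int = 0, n_snps: int = 5000,
                      missing_rate: float = 0.01) -> SimConfig:
    """A study-shaped population graph: two deeply drifted wild-source
    outgroups (Asian- and European-mouflon-like), a reference group at the
    root of the domestic radiation, an 8-population cline of rising
    wild-source ancestry (0 -> 0.20), and two bottlenecked isolates."""
    pops = [
        PopSpec("WILD", parent=None, fst=0.12),
        PopSpec("AMF", parent="WILD", fst=0.15, n=25, region="Asia",
                lat=32.0, lon=53.0, metapop="AMF"),
        PopSpec("EMF", parent="WILD", fst=0.15, n=25, region="Mediterranean",
                lat=40.0, lon=9.0, metapop="mEMF"),
        PopSpec("DOM", parent=None, fst=0.05),
        PopSpec("PRMS", parent="DOM", fst=0.05, n=28, region="Balkan",
                lat=43.0, lon=20.0, metapop="PRMS"),
        PopSpec("BKG", parent="DOM", fst=0.05),
    ]
    # SE -> NW cline: admixture of EMF rising from 0 to 0.20
    alphas = np.linspace(0.0, 0.20, 8)
    lats = np.linspace(38.0, 62.0, 8)
    lons = np.linspace(24.0, 8.0, 8)
    for i, (a, la, lo) in enumerate(zip(alphas, lats, lons), start=1):
        a = float(round(a, 6))
        if a == 0.0:
            pops.append(PopSpec(f"CL{i}", parent="BKG", fst=0.02, n=25,
                                region="cline", lat=la, lon=lo))
        else:
            pops.append(
                PopSpec(f"CL{i}", admix={"BKG": 1.0 - a, "EMF": a}, n=25,
                        region="cline", lat=la, lon=lo)
            )
    pops.append(PopSpec("ISO1", parent="DOM", fst=0.35, n=10, region="isolate"))
    pops.append(PopSpec("ISO2", parent="DOM", fst=0.30, n=10, region="isolate"))
    return SimConfig(populations=pops, n_snps=n_snps,
                     missing_rate=missing_rate, seed=seed)


def two_source_graph_config(
    alpha: float, seed: int = 0, n_snps: int = 5000, n_per_pop: int = 25
) -> SimConfig:
    """Four-population introgression graph for f4/f4n calibration: two
    related wild sources (AMF, EMF), a domestic reference (PRMS), and a
    test population X carrying a known fraction ``alpha`` of EMF ancestry
    on a PRMS-like background (alpha = 0 gives an unadmixed sister)."""
    pops = [
        PopSpec("WILD", fst=0.1),
        PopSpec("AMF", parent="WILD", fst=0.12, n=n_per_pop),
        PopSpec("EMF", parent="WILD", fst=0.12, n=n_per_pop),
        PopSpec("DOM", fst=0.05),
        PopSpec("PRMS", parent="DOM", fst=0.05, n=n_per_pop),
        PopSpec("BKG", parent="DOM", fst=0.05),
    ]
    if alpha == 0:
        pops.append(PopSpec("X", parent="BKG", fst=0.0, n=n_per_pop))
    else:
        pops.append(PopSpec("X", admix={"BKG": 1 - alpha, "EMF": alpha},
                            n=n_per_pop))
    return SimConfig(populations=pops, n_snps=n_snps, seed=seed)


def isolate_contrast_config(seed: int = 0, n_snps: int = 10_000) -> SimConfig:
    """Two tight regional clusters of three breeds each (strong east-west
    axis, breeds within a region nearly undifferentiated) plus a heavily
    bottlenecked isolate whose drift is private.  The isolate dominates
    the second axis of an all-samples PCA, the motivating case for
    fitting components on a subset."""
    pops = [
        PopSpec("ROOT"),
        PopSpec("W", parent="ROOT", fst=0.2),
        PopSpec("E", parent="ROOT", fst=0.2),
    ]
    for i in range(3):
        pops.append(PopSpec(f"W{i}", parent="W", fst=0.001, n=25))
        pops.append(PopSpec(f"E{i}", parent="E", fst=0.001, n=25))
    pops.append(PopSpec("ISO", parent="ROOT", fst=0.3, n=10))
    return SimConfig(populations=pops, n_snps=n_snps, seed=seed)


def simulate_annotated(config: SimConfig):
    """Convenience: simulate and return (AnnotatedGenotypes, SimTruth)."""
    gm, st, truth = simulate(config)
    return join_metadata(gm, st), truth
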