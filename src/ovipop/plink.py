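"""PLINK-format I/O: binary .bed/.bim/.fam (v1.0 SNP-major) and text
.ped/.map.

Dosages count allele B (column 6 of the .bim / the second allele of each
.ped genotype pair), so 0 = homozygous A, 2 = homozygous B.  The bed
two-bit codes are 00 = hom A1, 01 = missing, 10 = het, 11 = hom A2,
packed little-endian four samples per byte in SNP-major order.
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .genotypes import MISSING, SNP_COLUMNS, GenotypeMatrix

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# bed 2-bit code -> allele-B dosage
_CODE_TO_DOSAGE = np.array([0, MISSING, 1, 2], dtype=np.int8)
_DOSAGE_TO_CODE = {0: 0b00, MISSING: 0b01, 1: 0b10, 2: 0b11}


class PlinkFormatError(ValueError):
    """Malformed PLINK file (bad magic bytes, wrong column count, ...)."""


def read_plink(path_prefix: str | Path, dialect: str | None = None) -> GenotypeMatrix:
    """Read ``<prefix>.bed/.bim/.fam`` or ``<prefix>.ped/.map``.

    ``dialect`` is ``"bed"`` or ``"ped"``; if None it is inferred from which
    files exist (bed preferred).
    """
    prefix = Path(path_prefix)
    if dialect is None:
        dialect = "bed" if prefix.with_suffix(".bed").exists() else "ped"
    if dialect == "bed":
        return _read_bed(prefix)
    if dialect == "ped":
        return _read_ped(prefix)
    raise ValueError(f"unknown dialect {dialect!r}")


def write_plink(gm: GenotypeMatrix, path_prefix: str | Path, dialect: str = "bed") -> None:
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    if dialect == "bed":
        _write_bed(gm, prefix)
    elif dialect == "ped":
        _write_ped(gm, prefix)
    else:
        raise ValueError(f"unknown dialect {dialect!r}")


# ---------------------------------------------------------------------------
# bed/bim/fam
# ---------------------------------------------------------------------------


def _read_bim(path: Path) -> pd.DataFrame:
    rows = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 6:
                raise PlinkFormatError(
                    f"{path}:{lineno}: expected 6 columns, got {len(parts)}"
                )
            chrom, snp_id, _cm, pos, a1, a2 = parts
            rows.append((snp_id, chrom, int(pos), a1, a2))
    return pd.DataFrame(rows, columns=SNP_COLUMNS)


def _read_fam(path: Path) -> list[str]:
    ids = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 6:
                raise PlinkFormatError(
                    f"{path}:{lineno}: expected 6 columns, got {len(parts)}"
                )
            ids.append(parts[1])
    return ids


def _read_bed(prefix: Path) -> GenotypeMatrix:
    bim = _read_bim(prefix.with_suffix(".bim"))
    samples = _read_fam(prefix.with_suffix(".fam"))
    bed_path = prefix.with_suffix(".bed")
    raw = bed_path.read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise PlinkFormatError(f"{bed_path}: bad magic bytes {raw[:3]!r}")
    n_samples, n_snps = len(samples), len(bim)
    bytes_per_snp = (n_samples + 3) // 4
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    if body.size != bytes_per_snp * n_snps:
        raise PlinkFormatError(
            f"{bed_path}: payload {body.size} bytes, expected "
            f"{bytes_per_snp * n_snps}"
        )
    body = body.reshape(n_snps, bytes_per_snp)
    # unpack 2-bit codes, sample order within a byte is LSB-first
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (body[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(n_snps, -1)[:, :n_samples]
    calls = _CODE_TO_DOSAGE[codes].T  # samples x snps
    return GenotypeMatrix(samples, bim, calls)


def _write_bed(gm: GenotypeMatrix, prefix: Path) -> None:
    bim = gm.snps
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for r in bim.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.snp_id}\t0\t{r.pos}\t{r.allele_a}\t{r.allele_b}\n")
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for s in gm.samples:
            fh.write(f"{s}\t{s}\t0\t0\t0\t-9\n")
    n_samples = gm.n_samples
    bytes_per_snp = (n_samples + 3) // 4
    code = np.zeros((gm.n_snps, 4 * bytes_per_snp), dtype=np.uint8)
    calls_t = gm.calls.T
    for dosage, c in _DOSAGE_TO_CODE.items():
        code[:, :n_samples][calls_t == dosage] = c
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    packed = (code.reshape(gm.n_snps, bytes_per_snp, 4) << shifts).sum(
        axis=2, dtype=np.uint16
    ).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())


# ---------------------------------------------------------------------------
# ped/map
# ---------------------------------------------------------------------------


def _read_ped(prefix: Path) -> GenotypeMatrix:
    map_path = prefix.with_suffix(".map")
    rows = []
    with open(map_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 4:
                raise PlinkFormatError(
                    f"{map_path}:{lineno}: expected 4 columns, got {len(parts)}"
                )
            chrom, snp_id, _cm, pos = parts
            rows.append((snp_id, chrom, int(pos)))
    n_snps = len(rows)

    ped_path = prefix.with_suffix(".ped")
    samples: list[str] = []
    geno_rows: list[list[str]] = []
    with open(ped_path) as fh:
        for lineno, line in enumerate(fh, 1):
            parts = line.split()
            if len(parts) != 6 + 2 * n_snps:
                raise PlinkFormatError(
                    f"{ped_path}:{lineno}: expected {6 + 2 * n_snps} columns, "
                    f"got {len(parts)}"
                )
            samples.append(parts[1])
            geno_rows.append(parts[6:])

    # infer alleles per SNP: allele_a/allele_b taken in sorted order so that
    # the encoding is deterministic; monomorphic SNPs get a placeholder B
    alleles = np.array(geno_rows, dtype=object).reshape(len(samples), n_snps, 2) \
        if samples else np.empty((0, n_snps, 2), dtype=object)
    snp_records = []
    calls = np.full((len(samples), n_snps), MISSING, dtype=np.int8)
    for j in range(n_snps):
        col = alleles[:, j, :] if len(samples) else np.empty((0, 2), dtype=object)
        observed = sorted({a for pair in col for a in pair if a != "0"})
        if len(observed) > 2:
            raise PlinkFormatError(
                f"{ped_path}: SNP {rows[j][0]} has >2 alleles {observed}"
            )
        a = observed[0] if observed else "A"
        b = observed[1] if len(observed) > 1 else "0"
        snp_records.append((rows[j][0], rows[j][1], rows[j][2], a, b))
        for i in range(len(samples)):
            x, y = col[i]
            if x == "0" or y == "0":
                continue
            calls[i, j] = (x == b) + (y == b)
    snps = pd.DataFrame(snp_records, columns=SNP_COLUMNS)
    return GenotypeMatrix(samples, snps, calls)


def _write_ped(gm: GenotypeMatrix, prefix: Path) -> None:
    with open(prefix.with_suffix(".map"), "w") as fh:
        for r in gm.snps.itertuples(index=False):
            fh.write(f"{r.chrom}\t{r.snp_id}\t0\t{r.pos}\n")
    a = gm.snps["allele_a"].to_numpy()
    b = gm.snps["allele_b"].to_numpy()
    with open(prefix.with_suffix(".ped"), "w") as fh:
        for i, s in enumerate(gm.samples):
            fields = [s, s, "0", "0", "0", "-9"]
            row = gm.calls[i]
            for j in range(gm.n_snps):
                g = row[j]
                if g == MISSING:
                    fields += ["0", "0"]
                elif g == 0:
                    fields += [a[j], a[j]]
                elif g == 1:
                    fields += [a[j], b[j]]
                else:
                    fields += [b[j], b[j]]
            fh.write(" ".join(fields) + "\n")
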