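"""Readers, writers and the orchestrating pipeline.

Text formats: a dosage TSV (individuals as rows, variant ids as header,
entries 0/1/2), a phenotype TSV (individuals as rows, phenotype names as
header), and result TSVs.  PLINK bed/bim/fam (SNP-major) is supported
for genotypes.  Output files carry ``#``-prefixed header comments with
the seed and a config hash so equal runs are byte-identical.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .association import manova_scan
from .clustering import agnes, phenotype_distance_matrix, select_k
from .datatypes import GenotypeMatrix, PhenotypeMatrix, RepresentativeSet
from .evaluation import permutation_threshold
from .representatives import build_representatives

logger = logging.getLogger("agnep")

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major
# 2-bit PLINK codes -> minor (A1) allele count; 0b01 is missing
_BED_DECODE = {0b00: 2, 0b10: 1, 0b11: 0}
_BED_ENCODE = {2: 0b00, 1: 0b10, 0: 0b11}


# ---------------------------------------------------------------------------
# writers

def _comment_header(seed: int | None, extra: dict | None = None) -> str:
    parts = {}
    if seed is not None:
        parts["seed"] = seed
    if extra:
        parts.update(extra)
    if not parts:
        return ""
    return "# " + " ".join(f"{k}={v}" for k, v in parts.items()) + "\n"


def write_dosage_tsv(
    genotypes: GenotypeMatrix, path: str | Path, seed: int | None = None
) -> None:
    """Dosage TSV with the drawn MAF preserved in a comment line."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_comment_header(seed))
        fh.write("#maf\t" + "\t".join(repr(float(p)) for p in genotypes.maf) + "\n")
        fh.write("individual_id\t" + "\t".join(genotypes.variant_ids) + "\n")
        for i, ind in enumerate(genotypes.individual_ids):
            row = genotypes.values[i]
            fh.write(ind + "\t" + "\t".join(str(int(v)) for v in row) + "\n")


def write_phenotype_tsv(
    pheno: PhenotypeMatrix, path: str | Path, seed: int | None = None
) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_comment_header(seed))
        fh.write("individual_id\t" + "\t".join(pheno.phenotype_ids) + "\n")
        for j, ind in enumerate(pheno.individual_ids):
            vals = pheno.values[:, j]
            fh.write(ind + "\t" + "\t".join(repr(float(v)) for v in vals) + "\n")


def write_truth_tsv(truth, path: str | Path, seed: int | None = None) -> None:
    """Truth table: one row per (QTN, affected phenotype) with its effect."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_comment_header(seed))
        fh.write("variant_id\tgroup\teffect\n")
        for q, vid in enumerate(truth.qtn_variant_ids):
            g = int(truth.qtn_group_map[q]) if truth.qtn_group_map is not None else -1
            beta = truth.qtn_effects[q][truth.qtn_effects[q] != 0]
            eff = float(beta[0]) if beta.size else 0.0
            fh.write(f"{vid}\t{g + 1}\t{eff!r}\n")


def write_plink(genotypes: GenotypeMatrix, prefix: str | Path) -> None:
    """Write bed/bim/fam (SNP-major); allele A1 is the minor allele."""
    prefix = Path(prefix)
    n, m = genotypes.values.shape
    with open(prefix.with_suffix(".fam"), "w") as fh:
        for ind in genotypes.individual_ids:
            fh.write(f"{ind} {ind} 0 0 0 -9\n")
    with open(prefix.with_suffix(".bim"), "w") as fh:
        for j, vid in enumerate(genotypes.variant_ids):
            fh.write(f"1\t{vid}\t0\t{j + 1}\tA\tB\n")
    n_bytes = (n + 3) // 4
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(_BED_MAGIC)
        for j in range(m):
            col = genotypes.values[:, j]
            buf = bytearray(n_bytes)
            for i, g in enumerate(col):
                buf[i // 4] |= _BED_ENCODE[int(g)] << (2 * (i % 4))
            fh.write(bytes(buf))


# ---------------------------------------------------------------------------
# readers

def _read_dosage_tsv(path: Path) -> tuple[pd.DataFrame, np.ndarray | None]:
    maf: np.ndarray | None = None
    with open(path) as fh:
        skip = 0
        for line in fh:
            if line.startswith("#maf\t"):
                maf = np.array([float(x) for x in line.rstrip("\n").split("\t")[1:]])
                skip += 1
            elif line.startswith("#"):
                skip += 1
            else:
                break
    df = pd.read_csv(path, sep="\t", skiprows=skip, index_col=0, dtype=str)
    return df, maf


def _read_plink(prefix: Path) -> tuple[np.ndarray, list[str], list[str]]:
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None)
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None)
    individual_ids = fam[1].astype(str).tolist()
    variant_ids = bim[1].astype(str).tolist()
    n, m = len(individual_ids), len(variant_ids)
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:3] != _BED_MAGIC:
        raise ValueError(f"{prefix}.bed is not a SNP-major PLINK bed file")
    n_bytes = (n + 3) // 4
    body = np.frombuffer(raw[3:], dtype=np.uint8)
    if len(body) != n_bytes * m:
        raise ValueError(f"{prefix}.bed has unexpected length")
    codes = body.reshape(m, n_bytes)
    # unpack 2-bit fields, little-endian within each byte
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    expanded = (codes[:, :, None] >> shifts[None, None, :]) & 0b11
    expanded = expanded.reshape(m, n_bytes * 4)[:, :n]
    if np.any(expanded == 0b01):
        raise ValueError("missing genotype calls are not supported")
    lut = np.zeros(4, dtype=np.int8)
    for code, cnt in _BED_DECODE.items():
        lut[code] = cnt
    values = lut[expanded].T  # n x m
    return values, variant_ids, individual_ids


def read_genotypes(
    path: str | Path,
    fmt: str = "dosage",
    maf_filter: float | None = None,
) -> GenotypeMatrix:
    """Read genotypes, orienting every column to the minor allele.

    Columns with allele frequency above 0.5 are flipped (counts 2 - x)
    and logged.  Monomorphic columns are always dropped; when
    ``maf_filter`` is given, variants with MAF strictly below it are
    removed as well.
    """
    path = Path(path)
    stored_maf: np.ndarray | None = None
    if fmt == "dosage":
        if not path.exists():
            raise FileNotFoundError(path)
        df, stored_maf = _read_dosage_tsv(path)
        try:
            values = df.to_numpy(dtype=float)
        except ValueError as exc:
            raise ValueError(f"malformed dosage value in {path}: {exc}") from exc
        if not np.isin(values, (0.0, 1.0, 2.0)).all():
            i, j = np.argwhere(~np.isin(values, (0.0, 1.0, 2.0)))[0]
            raise ValueError(
                f"{path}: entry at row {df.index[i]!r}, column {df.columns[j]!r} "
                "is not an allele count in {0, 1, 2}"
            )
        values = values.astype(np.int8)
        variant_ids = [str(c) for c in df.columns]
        individual_ids = [str(i) for i in df.index]
    elif fmt == "plink":
        values, variant_ids, individual_ids = _read_plink(path)
    else:
        raise ValueError(f"unknown genotype format {fmt!r}; use 'dosage' or 'plink'")

    n = values.shape[0]
    freq = values.mean(axis=0) / 2.0
    # a #maf comment line declares the orientation (written by our writer);
    # trust it and skip empirical flipping so round trips are bit-identical
    trusted = stored_maf is not None and len(stored_maf) == values.shape[1]
    flip = freq > 0.5 if not trusted else np.zeros(values.shape[1], dtype=bool)
    if flip.any():
        flipped = [variant_ids[j] for j in np.flatnonzero(flip)]
        logger.warning(
            "flipped %d variant(s) to minor-allele orientation: %s",
            len(flipped),
            ", ".join(flipped[:10]),
        )
        values = values.copy()
        values[:, flip] = 2 - values[:, flip]
        freq = values.mean(axis=0) / 2.0
    maf = stored_maf if trusted else freq
    keep = maf > 0
    if maf_filter is not None:
        keep &= maf >= maf_filter
    dropped = int((~keep).sum())
    if dropped:
        logger.info("dropped %d variant(s) below the MAF filter", dropped)
    idx = np.flatnonzero(keep)
    return GenotypeMatrix(
        values[:, idx],
        maf[idx],
        [variant_ids[j] for j in idx],
        individual_ids,
    )


def read_phenotypes(path: str | Path) -> PhenotypeMatrix:
    """Read a phenotype TSV; individuals with any missing value are dropped."""
    path = Path(path)
    df = pd.read_csv(
        path, sep="\t", comment="#", index_col=0, float_precision="round_trip"
    )
    for col in df.columns:
        if not pd.api.types.is_numeric_dtype(df[col]):
            coerced = pd.to_numeric(df[col], errors="coerce")
            bad = df.index[coerced.isna() & df[col].notna()]
            if len(bad):
                raise ValueError(
                    f"{path}: non-numeric value at individual {bad[0]!r}, "
                    f"phenotype {col!r}"
                )
            df[col] = coerced
    complete = df.dropna(axis=0, how="any")
    n_dropped = len(df) - len(complete)
    if n_dropped:
        logger.info(
            "dropped %d individual(s) with missing phenotype values", n_dropped
        )
    return PhenotypeMatrix(
        complete.to_numpy(dtype=float).T,
        phenotype_ids=[str(c) for c in complete.columns],
        individual_ids=[str(i) for i in complete.index],
    )


def write_representatives_tsv(
    reps: RepresentativeSet, path: str | Path, seed: int | None = None
) -> None:
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(_comment_header(seed, {"method": reps.method}))
        fh.write("individual_id\t" + "\t".join(reps.row_ids) + "\n")
        for j, ind in enumerate(reps.individual_ids):
            vals = reps.values[:, j]
            fh.write(ind + "\t" + "\t".join(repr(float(v)) for v in vals) + "\n")


def read_representatives(path: str | Path) -> RepresentativeSet:
    path = Path(path)
    method = "mean"
    with open(path) as fh:
        first = fh.readline()
        if first.startswith("#") and "method=" in first:
            method = first.split("method=")[1].split()[0]
    df = pd.read_csv(
        path, sep="\t", comment="#", index_col=0, float_precision="round_trip"
    )
    return RepresentativeSet(
        values=df.to_numpy(dtype=float).T,
        source_cluster=np.arange(1, df.shape[1] + 1),
        method=method if method in ("mean", "median", "pca") else "mean",
        row_ids=[str(c) for c in df.columns],
        individual_ids=[str(i) for i in df.index],
    )


# ---------------------------------------------------------------------------
# pipeline

@dataclass
class RunConfig:
    """Declarative configuration for ``agnep run``."""

    genotype_path: str
    phenotype_path: str
    out_dir: str
    genotype_format: str = "dosage"
    method: str = "pca"
    linkage: str = "single"
    K: int | None = None  # None = auto (max silhouette)
    cum_threshold: float = 0.85
    statistic: str = "wilks"
    alpha: float = 0.05
    n_perm: int = 10
    maf_filter: float | None = None
    seed: int = 0
    extras: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for name in ("cum_threshold", "alpha"):
            v = getattr(self, name)
            if not 0 < v < 1:
                raise ValueError(f"{name} must lie in (0, 1), got {v}")

    def config_hash(self) -> str:
        payload = asdict(self)
        payload.pop("out_dir")  # analysis-irrelevant; keeps reruns comparable
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:12]


def align_individuals(
    genotypes: GenotypeMatrix, pheno: PhenotypeMatrix
) -> tuple[GenotypeMatrix, PhenotypeMatrix]:
    """Intersect and order-normalize the two individual-id axes."""
    common = [i for i in genotypes.individual_ids if i in set(pheno.individual_ids)]
    if not common:
        raise ValueError("no shared individual ids between genotypes and phenotypes")
    n_dropped = (
        len(genotypes.individual_ids) + len(pheno.individual_ids) - 2 * len(common)
    )
    if n_dropped:
        logger.info("dropped %d unmatched individual id(s)", n_dropped)
    gi = {x: k for k, x in enumerate(genotypes.individual_ids)}
    pi = {x: k for k, x in enumerate(pheno.individual_ids)}
    g_idx = [gi[x] for x in common]
    p_idx = [pi[x] for x in common]
    geno = GenotypeMatrix(
        genotypes.values[g_idx],
        genotypes.maf,
        list(genotypes.variant_ids),
        common,
    )
    ph = PhenotypeMatrix(
        pheno.values[:, p_idx], list(pheno.phenotype_ids), common
    )
    return geno, ph


def run_pipeline(config: RunConfig) -> Path:
    """Cluster -> represent -> scan -> permutation threshold, with outputs.

    Writes clusters.tsv, silhouette.tsv, reps.tsv, scan.tsv, threshold.txt
    and manifest.json into the output directory and returns its path.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "read inputs"
    try:
        genotypes = read_genotypes(
            config.genotype_path, config.genotype_format, config.maf_filter
        )
        pheno = read_phenotypes(config.phenotype_path)
        genotypes, pheno = align_individuals(genotypes, pheno)

        stage = "cluster"
        D = phenotype_distance_matrix(pheno)
        s_by_k: dict[int, float] = {}
        if config.K is None:
            K, partition, s_by_k = select_k(D, linkage=config.linkage)
        else:
            K = config.K
            partition = agnes(D, K, linkage=config.linkage)

        stage = "represent"
        reps = build_representatives(
            pheno, partition, config.method, config.cum_threshold
        )

        stage = "scan"
        scan = manova_scan(reps, genotypes, config.statistic)

        stage = "permutation threshold"
        threshold = permutation_threshold(
            reps,
            genotypes,
            n_perm=config.n_perm,
            alpha=config.alpha,
            seed=config.seed,
        )
    except Exception as exc:
        raise RuntimeError(f"pipeline failed at stage '{stage}': {exc}") from exc

    header = _comment_header(
        config.seed, {"config_hash": config.config_hash()}
    )
    with open(out / "clusters.tsv", "w") as fh:
        fh.write(header)
        fh.write("phenotype_id\tcluster_label\n")
        for pid, lab in zip(pheno.phenotype_ids, partition.assignment):
            fh.write(f"{pid}\t{lab}\n")
    with open(out / "silhouette.tsv", "w") as fh:
        fh.write(header)
        fh.write("K\tmean_silhouette\n")
        for k in sorted(s_by_k):
            fh.write(f"{k}\t{s_by_k[k]!r}\n")
    write_representatives_tsv(reps, out / "reps.tsv", config.seed)
    with open(out / "scan.tsv", "w") as fh:
        fh.write(header)
        fh.write("variant_id\tstatistic\tp_value\tneg_log10_p\n")
        for j, vid in enumerate(scan.variant_ids):
            fh.write(
                f"{vid}\t{scan.statistic[j]!r}\t{scan.p_value[j]!r}\t"
                f"{scan.neg_log10_p[j]!r}\n"
            )
    with open(out / "threshold.txt", "w") as fh:
        fh.write(header)
        fh.write(f"{threshold!r}\n")
    manifest = {"config": asdict(config), "K": int(K), "config_hash": config.config_hash()}
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True, default=str)
        fh.write("\n")
    return out
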