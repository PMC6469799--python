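"""File formats: phenotype/covariate TSVs, genotype TSV, a minimal PLINK
bed/bim/fam codec, and JSON model serialization.

The canonical tabular format is a TSV with a header row and the sample ID
in the first column.  Missing values are blank or NA.
"""

from __future__ import annotations

import json
from pathlib import Path
import numpy as np
import pandas as pd

from .mfmr import MFMRParams, params_from_dict, params_to_dict

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])  # SNP-major


def write_table(df: pd.DataFrame, path, id_column: str = "sample_id") -> None:
    out = df.copy()
    if id_column not in out.columns:
        out.index.name = id_column
        out = out.reset_index()
    out.to_csv(path, sep="\t", index=False, na_rep="NA")


def read_table(path, id_column: str = "sample_id") -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t", na_values=["NA", ""])
    if id_column not in df.columns:
        raise ValueError(f"{path}: missing id column {id_column!r}")
    df[id_column] = df[id_column].astype(str)
    return df.set_index(id_column)


def write_genotypes_tsv(genotypes: np.ndarray, path, sample_ids=None, snp_ids=None) -> None:
    n, m = genotypes.shape
    sample_ids = sample_ids or [f"s{i+1}" for i in range(n)]
    snp_ids = snp_ids or [f"snp{j+1}" for j in range(m)]
    df = pd.DataFrame(genotypes, index=pd.Index(sample_ids, name="sample_id"), columns=snp_ids)
    df.to_csv(path, sep="\t")


def read_genotypes_tsv(path):
    df = read_table(path)
    geno = df.to_numpy()
    if not np.isin(geno[~pd.isna(geno)], (0, 1, 2)).all():
        raise ValueError(f"{path}: genotypes must be additive 0/1/2")
    return geno.astype(float), list(df.index), list(df.columns)


# ----------------------------------------------------------------------
# minimal PLINK bed/bim/fam


def write_plink(prefix: str, genotypes: np.ndarray, sample_ids=None, snp_ids=None,
                chrom: int = 1) -> None:
    """Write a .bed/.bim/.fam triple (SNP-major bed; A1 dosage coding)."""
    g = np.asarray(genotypes)
    n, m = g.shape
    sample_ids = sample_ids or [f"s{i+1}" for i in range(n)]
    snp_ids = snp_ids or [f"snp{j+1}" for j in range(m)]
    code = np.empty((m, n), dtype=np.uint8)
    gt = g.T
    code[gt == 2] = 0b00
    code[gt == 1] = 0b10
    code[gt == 0] = 0b11
    code[np.isnan(gt.astype(float))] = 0b01
    n_bytes = (n + 3) // 4
    packed = np.zeros((m, n_bytes), dtype=np.uint8)
    for off in range(4):
        cols = np.arange(off, n, 4)
        packed[:, cols // 4] |= code[:, cols] << (2 * off)
    with open(f"{prefix}.bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())
    with open(f"{prefix}.bim", "w") as fh:
        for j, sid in enumerate(snp_ids):
            fh.write(f"{chrom}\t{sid}\t0\t{j+1}\tA\tB\n")
    with open(f"{prefix}.fam", "w") as fh:
        for sid in sample_ids:
            fh.write(f"{sid}\t{sid}\t0\t0\t0\t-9\n")


def read_plink(prefix: str):
    """Read a .bed/.bim/.fam triple written by :func:`write_plink`.

    Returns ``(genotypes, sample_ids, snp_ids)`` with NaN for missing.
    """
    with open(f"{prefix}.fam") as fh:
        sample_ids = [line.split()[1] for line in fh if line.strip()]
    with open(f"{prefix}.bim") as fh:
        snp_ids = [line.split()[1] for line in fh if line.strip()]
    n, m = len(sample_ids), len(snp_ids)
    with open(f"{prefix}.bed", "rb") as fh:
        magic = fh.read(3)
        if magic != _BED_MAGIC:
            raise ValueError("not a SNP-major PLINK bed file")
        raw = np.frombuffer(fh.read(), dtype=np.uint8)
    n_bytes = (n + 3) // 4
    raw = raw.reshape(m, n_bytes)
    geno = np.empty((n, m), dtype=float)
    for off in range(4):
        cols = np.arange(off, n, 4)
        codes = (raw[:, cols // 4] >> (2 * off)) & 0b11  # (m, len(cols))
        block = np.empty(codes.shape, dtype=float)
        block[codes == 0b00] = 2.0
        block[codes == 0b01] = np.nan
        block[codes == 0b10] = 1.0
        block[codes == 0b11] = 0.0
        geno[cols, :] = block.T
    return geno, sample_ids, snp_ids


# ----------------------------------------------------------------------
# model + posterior serialization


def save_model(params: MFMRParams, schema: dict, path) -> None:
    payload = {"schema": schema, "params": params_to_dict(params)}
    Path(path).write_text(json.dumps(payload, indent=1))


def load_model(path) -> tuple[MFMRParams, dict]:
    payload = json.loads(Path(path).read_text())
    return params_from_dict(payload["params"]), payload.get("schema", {})


def write_posterior(Z: np.ndarray, sample_ids, path) -> None:
    k = Z.shape[1]
    df = pd.DataFrame(Z, index=pd.Index(sample_ids, name="sample_id"),
                      columns=[f"subtype{j+1}" for j in range(k)])
    df.to_csv(path, sep="\t")


def read_posterior(path) -> tuple[np.ndarray, list[str]]:
    df = read_table(path)
    return df.to_numpy(), list(df.index)
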