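"""Minimal PLINK 1 binary (.bed/.bim/.fam) reader and writer.

Implements the standard SNP-major 2-bit encoding: per variant, each
sample occupies two bits — 00 homozygous A1, 10 heterozygous, 11
homozygous A2, 01 missing. Dosages returned here count copies of the
A1 allele (the .bim fifth column), matching PLINK's ``--recode A``
convention.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

_BED_MAGIC = bytes([0x6C, 0x1B, 0x01])

# 2-bit code -> A1-allele count; 01 (=1) is missing
_CODE_TO_DOSAGE = np.array([2.0, np.nan, 1.0, 0.0])

BIM_COLUMNS = ["chrom", "variant_id", "cm", "pos", "a1", "a2"]
FAM_COLUMNS = ["fid", "iid", "father", "mother", "sex", "phenotype"]


def read_bim(path: str) -> pd.DataFrame:
    bim = pd.read_csv(path, sep=r"\s+", header=None, names=BIM_COLUMNS,
                      dtype={"chrom": str, "variant_id": str, "a1": str, "a2": str})
    return bim


def read_fam(path: str) -> pd.DataFrame:
    return pd.read_csv(path, sep=r"\s+", header=None, names=FAM_COLUMNS,
                       dtype={"fid": str, "iid": str})


def read_bed(prefix: str) -> tuple[np.ndarray, pd.DataFrame, pd.DataFrame]:
    """Read ``prefix.bed/.bim/.fam``.

    Returns
    -------
    dosages : (n_individuals, n_snps) float array of A1-allele counts,
        NaN for missing genotypes.
    bim, fam : variant and sample metadata tables.
    """
    bim = read_bim(prefix + ".bim")
    fam = read_fam(prefix + ".fam")
    n, m = len(fam), len(bim)
    with open(prefix + ".bed", "rb") as fh:
        magic = fh.read(3)
        if magic != _BED_MAGIC:
            raise ValueError(f"{prefix}.bed is not a SNP-major PLINK bed file")
        raw = np.frombuffer(fh.read(), dtype=np.uint8)
    bytes_per_snp = (n + 3) // 4
    if raw.size != bytes_per_snp * m:
        raise ValueError(f"bed payload has {raw.size} bytes, expected {bytes_per_snp * m}")
    raw = raw.reshape(m, bytes_per_snp)
    # unpack 2-bit codes, little-endian within each byte
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    codes = (raw[:, :, None] >> shifts) & 0b11  # (m, bytes, 4)
    codes = codes.reshape(m, -1)[:, :n]
    dosages = _CODE_TO_DOSAGE[codes].T.copy()  # (n, m)
    return dosages, bim, fam


def write_bed(prefix: str, dosages: np.ndarray, bim: pd.DataFrame,
              fam: pd.DataFrame | None = None) -> None:
    """Write ``prefix.bed/.bim/.fam`` from an A1-dosage matrix."""
    dosages = np.asarray(dosages, dtype=float)
    n, m = dosages.shape
    if len(bim) != m:
        raise ValueError("bim rows must match dosage columns")
    if fam is None:
        fam = pd.DataFrame({
            "fid": [f"F{i}" for i in range(n)],
            "iid": [f"I{i}" for i in range(n)],
            "father": 0, "mother": 0, "sex": 0, "phenotype": -9,
        })
    # dosage -> 2-bit code
    codes = np.full((m, n), 1, dtype=np.uint8)  # default missing (01)
    dT = dosages.T
    codes[dT == 2] = 0b00
    codes[dT == 1] = 0b10
    codes[dT == 0] = 0b11
    pad = (-n) % 4
    if pad:
        codes = np.concatenate([codes, np.zeros((m, pad), dtype=np.uint8)], axis=1)
    grouped = codes.reshape(m, -1, 4)
    shifts = np.array([0, 2, 4, 6], dtype=np.uint8)
    packed = (grouped << shifts).sum(axis=2).astype(np.uint8)
    os.makedirs(os.path.dirname(os.path.abspath(prefix)), exist_ok=True)
    with open(prefix + ".bed", "wb") as fh:
        fh.write(_BED_MAGIC)
        fh.write(packed.tobytes())
    bim.to_csv(prefix + ".bim", sep="\t", header=False, index=False,
               columns=BIM_COLUMNS)
    fam.to_csv(prefix + ".fam", sep="\t", header=False, index=False,
               columns=FAM_COLUMNS)
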