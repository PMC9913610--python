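"""Minimal PLINK-1 binary (bed/bim/fam) reader and writer.

SNP-major layout only (third magic byte 0x01).  Genotypes are returned as
float dosages counting the A1 allele of the .bim file: 2-bit codes
00 -> 2.0 (A1 homozygote), 10 -> 1.0 (heterozygote), 11 -> 0.0
(A2 homozygote), 01 -> NaN (missing).
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

MAGIC = bytes([0x6C, 0x1B, 0x01])
# index = 2-bit code
_CODE_TO_DOSE = np.array([2.0, np.nan, 1.0, 0.0])

BIM_COLS = ["chrom", "snp", "cm", "pos", "a1", "a2"]
FAM_COLS = ["fid", "iid", "father", "mother", "sex", "phenotype"]


@dataclass
class GenotypeMatrix:
    """Samples x markers dosage matrix with marker and sample metadata."""

    dosages: np.ndarray          # (n_samples, n_markers) float, NaN = missing
    bim: pd.DataFrame            # per-marker chrom, snp, cm, pos, a1, a2
    fam: pd.DataFrame            # per-sample ids

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_markers(self) -> int:
        return self.dosages.shape[1]

    def subset_markers(self, keep) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(self.dosages[:, keep],
                              self.bim.iloc[keep].reset_index(drop=True),
                              self.fam)


class PlinkFormatError(ValueError):
    pass


def read_plink1(prefix) -> GenotypeMatrix:
    """Read a bed/bim/fam triplet given its common path prefix."""
    prefix = Path(prefix)
    bim = pd.read_csv(prefix.with_suffix(".bim"), sep=r"\s+", header=None,
                      names=BIM_COLS, dtype={"chrom": str, "snp": str})
    fam = pd.read_csv(prefix.with_suffix(".fam"), sep=r"\s+", header=None,
                      names=FAM_COLS, dtype={"fid": str, "iid": str})
    n, m = len(fam), len(bim)
    raw = Path(prefix.with_suffix(".bed")).read_bytes()
    if raw[:2] != MAGIC[:2]:
        raise PlinkFormatError(f"bad bed magic bytes {raw[:2]!r}")
    if raw[2:3] != MAGIC[2:3]:
        raise PlinkFormatError("only SNP-major bed files are supported")
    bpm = (n + 3) // 4                     # bytes per marker
    expected = 3 + bpm * m
    if len(raw) != expected:
        raise PlinkFormatError(
            f"truncated bed: expected {expected} bytes, got {len(raw)} "
            f"(offset {len(raw)})")
    data = np.frombuffer(raw, dtype=np.uint8, offset=3).reshape(m, bpm)
    # unpack 2-bit codes, sample-within-byte little-endian
    shifts = np.arange(4) * 2
    codes = (data[:, :, None] >> shifts[None, None, :]) & 0b11
    codes = codes.reshape(m, bpm * 4)[:, :n]
    return GenotypeMatrix(_CODE_TO_DOSE[codes].T.copy(), bim, fam)


def write_plink1(prefix, geno: GenotypeMatrix) -> None:
    """Write a GenotypeMatrix as a SNP-major bed/bim/fam triplet."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    geno.bim[BIM_COLS].to_csv(prefix.with_suffix(".bim"), sep="\t",
                              header=False, index=False)
    geno.fam[FAM_COLS].to_csv(prefix.with_suffix(".fam"), sep="\t",
                              header=False, index=False)
    n, m = geno.n_samples, geno.n_markers
    dose = geno.dosages.T                  # marker-major
    codes = np.full(dose.shape, 1, dtype=np.uint8)   # missing
    codes[dose == 2.0] = 0b00
    codes[dose == 1.0] = 0b10
    codes[dose == 0.0] = 0b11
    bpm = (n + 3) // 4
    padded = np.ones((m, bpm * 4), dtype=np.uint8) * 0b11  # pad with hom A2
    padded[:, :n] = codes
    padded = padded.reshape(m, bpm, 4)
    shifts = np.arange(4) * 2
    packed = (padded << shifts[None, None, :]).astype(np.uint16).sum(axis=2).astype(np.uint8)
    with open(prefix.with_suffix(".bed"), "wb") as fh:
        fh.write(MAGIC)
        fh.write(packed.tobytes())
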