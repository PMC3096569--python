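"""File input/output: VCF SNP pairs, TSV genotype matrices, study configs.

Genotypes are coded as allele-copy dosages.  In VCF mode the counted
allele is ALT; in the TSV matrix it is whatever allele the matrix was
written with.  All LD measures are invariant to which allele is
counted, so the coding choice is cosmetic.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
import yaml

from cyvcf2 import VCF

from .em import MISSING
from .experiments import StudyConfig

__all__ = [
    "GenotypeMatrix",
    "read_vcf_pair",
    "read_tsv_matrix",
    "write_tsv_matrix",
    "genotype_matrix_from_pair",
    "load_study_config",
]

_VALID_CELLS = {"0", "1", "2", "NA"}


@dataclass(frozen=True)
class GenotypeMatrix:
    """Individuals × SNPs dosage matrix with ``MISSING`` (-1) for NA."""

    sample_ids: tuple
    snp_ids: tuple
    calls: np.ndarray  # (n_samples, n_snps) int8
    source: str = ""

    def __post_init__(self) -> None:
        calls = np.asarray(self.calls, dtype=np.int8)
        if calls.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise ValueError(
                f"calls shape {calls.shape} inconsistent with "
                f"{len(self.sample_ids)} samples x {len(self.snp_ids)} SNPs"
            )
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise ValueError("SNP ids must be unique")
        calls.setflags(write=False)
        object.__setattr__(self, "calls", calls)
        object.__setattr__(self, "sample_ids", tuple(self.sample_ids))
        object.__setattr__(self, "snp_ids", tuple(self.snp_ids))

    def pair(self, snp_1: str, snp_2: str) -> tuple[np.ndarray, np.ndarray]:
        """Genotype sequences for two named SNPs."""
        for s in (snp_1, snp_2):
            if s not in self.snp_ids:
                raise KeyError(f"SNP id {s!r} not in matrix")
        i, j = self.snp_ids.index(snp_1), self.snp_ids.index(snp_2)
        return self.calls[:, i].copy(), self.calls[:, j].copy()


def read_vcf_pair(path, snp_id_1: str, snp_id_2: str) -> tuple[np.ndarray, np.ndarray]:
    """Extract ALT-dosage genotype sequences for two SNP ids from a VCF.

    Phase separators are accepted but phase is discarded (the Monte
    Carlo test assumes unphased data); ``./.`` becomes missing.  Both
    records must be bi-allelic.
    """
    wanted = {snp_id_1: None, snp_id_2: None}
    vcf = VCF(str(path), gts012=False)
    try:
        for variant in vcf:
            if variant.ID in wanted and wanted[variant.ID] is None:
                if len(variant.ALT) != 1:
                    raise ValueError(
                        f"site {variant.ID} at {variant.CHROM}:{variant.POS} "
                        "is not bi-allelic"
                    )
                calls = []
                for gt in variant.genotypes:
                    alleles = gt[:-1]  # last element is the phased flag
                    if any(a < 0 for a in alleles):
                        calls.append(MISSING)
                    else:
                        calls.append(int(sum(alleles)))
                wanted[variant.ID] = np.array(calls, dtype=np.int8)
                if all(v is not None for v in wanted.values()):
                    break
    finally:
        vcf.close()
    for snp_id, calls in wanted.items():
        if calls is None:
            raise KeyError(f"SNP id {snp_id!r} not found in {path}")
    return wanted[snp_id_1], wanted[snp_id_2]


def read_tsv_matrix(path) -> GenotypeMatrix:
    """Read a TSV genotype matrix (header: SNP ids; first column: sample id).

    Cells must be 0, 1, 2 or NA; anything else is reported with its
    line number (1-based, header is line 1).
    """
    df = pd.read_csv(path, sep="\t", dtype=str, index_col=0)
    if df.shape[1] == 0:
        raise ValueError(f"{path}: no SNP columns found")
    calls = np.empty(df.shape, dtype=np.int8)
    values = df.to_numpy()
    for r in range(df.shape[0]):
        for c in range(df.shape[1]):
            cell = values[r, c]
            cell = "NA" if cell is None or cell != cell else str(cell).strip()
            if cell not in _VALID_CELLS:
                raise ValueError(
                    f"{path}, line {r + 2}, column {df.columns[c]!r}: "
                    f"invalid genotype {cell!r} (expected 0/1/2/NA)"
                )
            calls[r, c] = MISSING if cell == "NA" else int(cell)
    return GenotypeMatrix(
        sample_ids=tuple(str(s) for s in df.index),
        snp_ids=tuple(str(s) for s in df.columns),
        calls=calls,
        source=f"{path} (tsv)",
    )


def write_tsv_matrix(path, matrix: GenotypeMatrix) -> None:
    """Write the matrix in the TSV format `read_tsv_matrix` accepts."""
    out = pd.DataFrame(
        np.where(matrix.calls == MISSING, "NA", matrix.calls.astype(object)),
        index=list(matrix.sample_ids),
        columns=list(matrix.snp_ids),
    )
    out.index.name = "sample"
    out.to_csv(path, sep="\t")


def genotype_matrix_from_pair(
    g_a, g_b, snp_ids=("snpA", "snpB"), sample_prefix: str = "ind"
) -> GenotypeMatrix:
    """Wrap two simulated genotype sequences as a writable matrix."""
    g_a = np.asarray(g_a, dtype=np.int8)
    g_b = np.asarray(g_b, dtype=np.int8)
    if g_a.size != g_b.size:
        raise ValueError("genotype sequences differ in length")
    calls = np.stack([g_a, g_b], axis=1)
    samples = tuple(f"{sample_prefix}{i + 1}" for i in range(g_a.size))
    return GenotypeMatrix(samples, tuple(snp_ids), calls, source="simulated")


_CONFIG_KEYS = {"p1", "q1", "d_h", "n", "reps", "dprime_grid", "alphas", "seed", "B"}


def load_study_config(path) -> StudyConfig:
    """Load a StudyConfig from a flat YAML key-value file.

    Recognised keys: p1, q1, d_h, n, reps, dprime_grid, alphas, seed, B.
    Missing keys fall back to the defaults of :class:`StudyConfig`.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"{path}: expected flat key-value pairs")
    unknown = set(raw) - _CONFIG_KEYS
    if unknown:
        raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
    for key in ("dprime_grid", "alphas"):
        if key in raw:
            raw[key] = tuple(raw[key])
    return replace(StudyConfig(), **raw)
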