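"""Containers and readers for longitudinal phenotypes and SNP genotypes.

Phenotypes live in long format (one row per measurement: id, time, value);
genotypes as an additive-coded matrix (0/1/2 counts of the coded allele, or
dosages in [0, 2]).  Plain TSV is the native exchange format; VCF genotypes
are read through cyvcf2 when available.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .basis import TimeDomain

__all__ = ["LongitudinalData", "GenotypeMatrix", "read_phenotypes", "read_genotypes_tsv"]


@dataclass
class LongitudinalData:
    """Long-format repeated records: parallel arrays of id, time, value."""

    ids: np.ndarray      # individual id per record (object)
    times: np.ndarray    # recording time per record (float)
    values: np.ndarray   # phenotype per record (float)

    def __post_init__(self) -> None:
        self.ids = np.asarray(self.ids, dtype=object)
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if not (len(self.ids) == len(self.times) == len(self.values)):
            raise ValueError("ids, times, values must have equal length")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("phenotype values must be finite")

    @property
    def n_records(self) -> int:
        return len(self.values)

    @property
    def individuals(self) -> np.ndarray:
        """Unique individual ids in order of first appearance."""
        return pd.unique(pd.Series(self.ids))

    @property
    def n_individuals(self) -> int:
        return len(self.individuals)

    def record_counts(self) -> pd.Series:
        return pd.Series(self.ids).value_counts()

    def domain(self) -> TimeDomain:
        return TimeDomain.from_times(self.times)

    def is_balanced(self) -> bool:
        """True when every individual is recorded at the same set of times."""
        df = pd.DataFrame({"id": self.ids, "t": self.times})
        counts = df.groupby("id", sort=False)["t"].apply(tuple)
        return counts.nunique() == 1

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"id": self.ids, "time": self.times, "value": self.values})

    @classmethod
    def from_frame(cls, df: pd.DataFrame) -> "LongitudinalData":
        return cls(df["id"].to_numpy(dtype=object), df["time"].to_numpy(), df["value"].to_numpy())


def read_phenotypes(path) -> LongitudinalData:
    """Read a phenotype TSV with header columns id, time, value."""
    df = pd.read_csv(path, sep="\t", comment="#", dtype={"id": str})
    for c in ("id", "time", "value"):
        if c not in df.columns:
            raise ValueError(f"phenotype file {path} lacks column {c!r}")
    return LongitudinalData.from_frame(df)


@dataclass
class GenotypeMatrix:
    """Additive-coded genotypes: one row per SNP, one column per individual.

    ``values`` may be hard calls (0/1/2) or dosages in [0, 2].  The coded
    allele is the ALT/second allele of the source file; its sample frequency
    is ``freq``.
    """

    snp_ids: np.ndarray
    individual_ids: np.ndarray
    values: np.ndarray
    chrom: np.ndarray | None = None
    pos: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        self.individual_ids = np.asarray(self.individual_ids, dtype=object)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.snp_ids), len(self.individual_ids)):
            raise ValueError("genotype matrix shape mismatch")
        with np.errstate(invalid="ignore"):
            bad = (self.values < 0) | (self.values > 2)
        if np.any(bad & ~np.isnan(self.values)):
            raise ValueError("genotype values must lie in [0, 2] (or NaN for missing)")

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    @property
    def freq(self) -> np.ndarray:
        """Sample frequency of the coded allele per SNP (missing ignored)."""
        return np.nanmean(self.values, axis=1) / 2.0

    def is_hard_calls(self) -> bool:
        v = self.values[~np.isnan(self.values)]
        return bool(np.all(np.isin(v, (0.0, 1.0, 2.0))))

    def subset_individuals(self, ids) -> "GenotypeMatrix":
        lookup = {v: i for i, v in enumerate(self.individual_ids)}
        idx = np.array([lookup[v] for v in ids], dtype=int)
        return GenotypeMatrix(
            self.snp_ids, np.asarray(ids, dtype=object), self.values[:, idx],
            self.chrom, self.pos,
        )

    def to_frame(self) -> pd.DataFrame:
        df = pd.DataFrame(self.values, index=self.snp_ids, columns=self.individual_ids)
        df.index.name = "snp"
        return df


def read_genotypes_tsv(path) -> GenotypeMatrix:
    """Read a genotype TSV: rows = SNPs, columns = individuals.

    The first column holds SNP ids; optional columns ``chrom`` and ``pos``
    (when present, immediately after the id column) carry positions.
    """
    df = pd.read_csv(path, sep="\t", comment="#", index_col=0)
    chrom = pos = None
    if "chrom" in df.columns and "pos" in df.columns:
        chrom = df.pop("chrom").to_numpy()
        pos = df.pop("pos").to_numpy()
    return GenotypeMatrix(
        df.index.to_numpy(dtype=object),
        df.columns.to_numpy(dtype=object),
        df.to_numpy(dtype=float),
        chrom,
        pos,
    )


def read_genotypes_vcf(path, use_dosage: bool = False) -> GenotypeMatrix:
    """Read genotypes from a VCF via cyvcf2 (GT field; DS when requested)."""
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = np.asarray(vcf.samples, dtype=object)
    snp_ids, chroms, poss, rows = [], [], [], []
    for var in vcf:
        snp_ids.append(var.ID or f"{var.CHROM}:{var.POS}")
        chroms.append(var.CHROM)
        poss.append(var.POS)
        ds = var.format("DS") if use_dosage else None
        if ds is not None:
            rows.append(np.asarray(ds).ravel().astype(float))
        else:
            gt = np.asarray(var.gt_types, dtype=float)  # 0 hom-ref,1 het,2 unknown,3 hom-alt
            gt[gt == 2] = np.nan
            gt[gt == 3] = 2.0
            rows.append(gt)
    return GenotypeMatrix(
        np.asarray(snp_ids, dtype=object), samples, np.vstack(rows),
        np.asarray(chroms, dtype=object), np.asarray(poss),
    )
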