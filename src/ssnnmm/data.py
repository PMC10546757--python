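"""In-memory containers and CSV I/O for genotypes, phenotypes and truth."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "GenotypeMatrix",
    "PhenotypeTable",
    "TrueValues",
    "read_genotypes",
    "write_genotypes",
    "read_phenotypes",
    "write_phenotypes",
]


@dataclass
class GenotypeMatrix:
    """Individuals x markers dosage matrix with a cellwise observed mask.

    ``Z`` holds dosages of the counted allele (0/1/2 where observed; the
    value at masked cells is arbitrary and must not be read).  Allele
    frequencies are computed from observed cells only.
    """

    ids: tuple[str, ...]
    markers: tuple[str, ...]
    Z: np.ndarray  # (n, m) float64
    observed_mask: np.ndarray  # (n, m) bool

    def __post_init__(self) -> None:
        n, m = len(self.ids), len(self.markers)
        if self.Z.shape != (n, m) or self.observed_mask.shape != (n, m):
            raise ValueError("Z / observed_mask shape must be (n_ids, n_markers)")
        obs = self.Z[self.observed_mask]
        if obs.size and not np.isin(obs, (0.0, 1.0, 2.0)).all():
            raise ValueError("observed dosages must be 0, 1 or 2")

    @property
    def n(self) -> int:
        return len(self.ids)

    @property
    def m(self) -> int:
        return len(self.markers)

    @property
    def allele_freq(self) -> np.ndarray:
        """Frequency of the counted allele per marker, from observed cells."""
        cnt = self.observed_mask.sum(axis=0)
        with np.errstate(invalid="ignore"):
            return np.where(
                cnt > 0, np.where(self.observed_mask, self.Z, 0.0).sum(axis=0) / (2.0 * cnt), np.nan
            )

    def genotyped_ids(self) -> list[str]:
        """Ids with at least one observed cell."""
        any_obs = self.observed_mask.any(axis=1)
        return [i for i, o in zip(self.ids, any_obs) if o]

    def fully_observed_ids(self) -> list[str]:
        full = self.observed_mask.all(axis=1)
        return [i for i, o in zip(self.ids, full) if o]

    def subset(self, ids) -> "GenotypeMatrix":
        lookup = {i: k for k, i in enumerate(self.ids)}
        idx = np.array([lookup[i] for i in ids], dtype=np.int64)
        return GenotypeMatrix(
            tuple(ids), self.markers, self.Z[idx].copy(), self.observed_mask[idx].copy()
        )


@dataclass
class PhenotypeTable:
    """Per-individual trait values with train/test roles.

    Test individuals carry a phenotype (for accuracy evaluation) but it is
    never used in model fitting.
    """

    ids: tuple[str, ...]
    y: np.ndarray
    role: tuple[str, ...]  # 'train' | 'test'

    def __post_init__(self) -> None:
        if len(self.ids) != len(self.y) or len(self.ids) != len(self.role):
            raise ValueError("ids, y and role must have equal length")
        bad = set(self.role) - {"train", "test"}
        if bad:
            raise ValueError(f"unknown roles {bad}")

    def train_ids(self) -> list[str]:
        return [i for i, r in zip(self.ids, self.role) if r == "train"]

    def test_ids(self) -> list[str]:
        return [i for i, r in zip(self.ids, self.role) if r == "test"]

    def y_of(self, ids) -> np.ndarray:
        lookup = {i: k for k, i in enumerate(self.ids)}
        return self.y[[lookup[i] for i in ids]]


@dataclass
class TrueValues:
    """Simulator ground truth: QTL positions/effects and true breeding values."""

    qtl_indices: np.ndarray
    qtl_effects: np.ndarray
    ids: tuple[str, ...]
    true_bv: np.ndarray
    h2_target: float
    varp_target: float

    def bv_of(self, ids) -> np.ndarray:
        lookup = {i: k for k, i in enumerate(self.ids)}
        return self.true_bv[[lookup[i] for i in ids]]


def read_genotypes(path) -> GenotypeMatrix:
    """Genotype CSV: ``id`` column then one column per marker, NA = missing."""
    df = pd.read_csv(path, dtype={0: str})
    ids = tuple(df.iloc[:, 0].astype(str))
    markers = tuple(df.columns[1:])
    Z = df.iloc[:, 1:].to_numpy(dtype=float)
    mask = ~np.isnan(Z)
    Z = np.where(mask, Z, 0.0)
    return GenotypeMatrix(ids, markers, Z, mask)


def write_genotypes(geno: GenotypeMatrix, path) -> None:
    Z = np.where(geno.observed_mask, geno.Z, np.nan)
    df = pd.DataFrame(Z, columns=list(geno.markers))
    df.insert(0, "id", list(geno.ids))
    df.to_csv(path, index=False, na_rep="NA")


def read_phenotypes(path) -> PhenotypeTable:
    """Phenotype CSV with header ``id,y,role`` (role optional, default train)."""
    df = pd.read_csv(path, dtype={"id": str})
    role = tuple(df["role"]) if "role" in df else tuple(["train"] * len(df))
    return PhenotypeTable(tuple(df["id"]), df["y"].to_numpy(dtype=float), role)


def write_phenotypes(pheno: PhenotypeTable, path) -> None:
    pd.DataFrame({"id": list(pheno.ids), "y": pheno.y, "role": list(pheno.role)}).to_csv(
        path, index=False
    )
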