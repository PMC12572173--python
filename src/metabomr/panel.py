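"""Reference panel of genotype dosages for LD computation.

The panel plays the role of an external haplotype reference (e.g. a
1000-Genomes-style European panel): it supplies pairwise r² between
variants for clumping, proxy search and overlap checks, and allele
orientation signs for mapping a proxy's effect allele onto a target's.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

VARIANT_COLUMNS = ["snp_id", "chrom", "pos", "ref_allele", "alt_allele", "block"]


@dataclass
class ReferencePanel:
    """Genotype dosages (individuals x variants) plus a variant table.

    variants : DataFrame with columns snp_id, chrom, pos, ref_allele,
        alt_allele, block (LD-block index). Positions are 1-based GRCh37
        and strictly increasing within a chromosome.
    dosages : float array of shape (n_individuals, n_variants) with
        values in [0, 2] counting alt (minor) alleles.
    """

    variants: pd.DataFrame
    dosages: np.ndarray
    _index: dict = field(init=False, repr=False)

    def __post_init__(self) -> None:
        self.variants = self.variants.reset_index(drop=True)
        if self.dosages.shape[1] != len(self.variants):
            raise ValueError("dosage matrix width does not match variant table")
        if np.isnan(self.dosages).any():
            raise ValueError("dosage matrix contains missing entries")
        if self.dosages.min() < 0 or self.dosages.max() > 2:
            raise ValueError("dosages must lie in [0, 2]")
        for _, grp in self.variants.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing or grp["pos"].duplicated().any():
                raise ValueError("positions must be strictly increasing per chromosome")
        self._index = {s: i for i, s in enumerate(self.variants["snp_id"])}

    # -- basic lookups -------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def column(self, snp_id: str) -> int:
        try:
            return self._index[snp_id]
        except KeyError:
            raise KeyError(f"variant {snp_id!r} not in reference panel") from None

    def __contains__(self, snp_id: str) -> bool:
        return snp_id in self._index

    def maf(self) -> np.ndarray:
        """Per-variant minor-allele frequency from the dosages."""
        f = self.dosages.mean(axis=0) / 2.0
        return np.minimum(f, 1.0 - f)

    # -- LD ------------------------------------------------------------
    def correlation(self, i: int, j: int) -> float:
        """Pearson dosage correlation between two variant columns."""
        x, y = self.dosages[:, i], self.dosages[:, j]
        sx, sy = x.std(), y.std()
        if sx == 0 or sy == 0:
            return 0.0
        return float(((x - x.mean()) * (y - y.mean())).mean() / (sx * sy))

    def r2(self, a: str, b: str) -> float:
        return self.correlation(self.column(a), self.column(b)) ** 2

    def r_with(self, snp_id: str, others: list[str]) -> np.ndarray:
        """Signed correlation of one target variant with many others."""
        i = self.column(snp_id)
        x = self.dosages[:, i]
        x = x - x.mean()
        sx = x.std()
        out = np.empty(len(others))
        for k, o in enumerate(others):
            y = self.dosages[:, self.column(o)]
            y = y - y.mean()
            sy = y.std()
            out[k] = 0.0 if sx == 0 or sy == 0 else (x * y).mean() / (sx * sy)
        return out

    def ld_matrix(self, snp_ids: list[str]) -> np.ndarray:
        """Signed correlation matrix for a list of variants."""
        cols = [self.column(s) for s in snp_ids]
        g = self.dosages[:, cols]
        g = g - g.mean(axis=0)
        sd = g.std(axis=0)
        sd[sd == 0] = 1.0
        return np.corrcoef((g / sd).T) if len(cols) > 1 else np.ones((1, 1))

    # -- persistence (plain text) ---------------------------------------
    def write(self, variants_path, dosages_path) -> None:
        self.variants[VARIANT_COLUMNS].to_csv(variants_path, sep="\t", index=False)
        np.savetxt(dosages_path, self.dosages, fmt="%.4f", delimiter="\t")

    @classmethod
    def read(cls, variants_path, dosages_path) -> "ReferencePanel":
        variants = pd.read_csv(variants_path, sep="\t")
        dosages = np.loadtxt(dosages_path, delimiter="\t", ndmin=2)
        return cls(variants=variants, dosages=dosages)
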