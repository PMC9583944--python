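"""Core containers shared across the package.

Genotypes live in a :class:`GenotypePanel` (individuals x loci allele-dosage
matrix with map positions and population labels); relationship matrices in a
:class:`GRM` tagged by effect kind and locus scope.  Phenotypes are plain
pandas DataFrames with columns ``individual, trial, season, cell, value``
(``cell`` is the trial-by-season label, e.g. ``"F1"``).
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Sequence

import numpy as np
import pandas as pd

#: required columns of a phenotype table
PHENO_COLUMNS = ("individual", "trial", "season", "cell", "value")


def make_cell(trial: str, season: str) -> str:
    """Trial-by-season cell label, e.g. ``make_cell("F", "2011") == "F:2011"``."""
    return f"{trial}:{season}"


@dataclass
class GenotypePanel:
    """Allele-dosage matrix with locus map and individual metadata.

    dosage
        float array, shape (n_individuals, n_loci); entries 0/1/2 or NaN for
        missing.
    loci
        DataFrame with columns ``chrom, pos, ref, alt`` (pos 1-based bp),
        strictly increasing within chromosome.
    individuals
        DataFrame with columns ``id, population``.
    haplotypes
        optional (n_individuals, n_loci, 2) phased 0/1 array kept by the
        simulator so that offspring gametes can be dropped from the panel.
    """

    dosage: np.ndarray
    loci: pd.DataFrame
    individuals: pd.DataFrame
    haplotypes: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.dosage = np.asarray(self.dosage, dtype=float)
        if self.dosage.ndim != 2:
            raise ValueError("dosage must be 2-D (individuals x loci)")
        if self.dosage.shape != (len(self.individuals), len(self.loci)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} does not match "
                f"{len(self.individuals)} individuals x {len(self.loci)} loci"
            )
        ids = self.individuals["id"]
        if ids.duplicated().any():
            dups = ids[ids.duplicated()].tolist()
            raise ValueError(f"duplicate individual ids: {dups}")
        # fractional values in [0, 2] are allowed (mean-imputed dosages)
        with np.errstate(invalid="ignore"):
            valid = np.isnan(self.dosage) | (
                (self.dosage >= 0.0) & (self.dosage <= 2.0))
        if not valid.all():
            raise ValueError("dosages must lie in [0, 2] or be missing")
        for _, grp in self.loci.groupby("chrom", sort=False):
            if not grp["pos"].is_monotonic_increasing:
                raise ValueError("locus positions must increase within chromosome")

    # -- convenience -------------------------------------------------------
    @property
    def n_individuals(self) -> int:
        return self.dosage.shape[0]

    @property
    def n_loci(self) -> int:
        return self.dosage.shape[1]

    @property
    def ids(self) -> list[str]:
        return self.individuals["id"].tolist()

    @property
    def populations(self) -> np.ndarray:
        return self.individuals["population"].to_numpy()

    def allele_frequencies(self) -> np.ndarray:
        """Alternate-allele frequency per locus, ignoring missing calls."""
        with np.errstate(invalid="ignore"):
            return np.nanmean(self.dosage, axis=0) / 2.0

    def subset(
        self,
        individuals: Sequence[str] | np.ndarray | None = None,
        locus_mask: np.ndarray | None = None,
    ) -> "GenotypePanel":
        """Return a panel restricted to the given individuals and/or loci."""
        dosage = self.dosage
        indiv = self.individuals
        haps = self.haplotypes
        if individuals is not None:
            pos = indiv.reset_index(drop=True)
            idx = pos.set_index("id").index.get_indexer(list(individuals))
            if (idx < 0).any():
                missing = [i for i, j in zip(individuals, idx) if j < 0]
                raise KeyError(f"unknown individual ids: {missing}")
            dosage = dosage[idx]
            indiv = pos.iloc[idx].reset_index(drop=True)
            haps = None if haps is None else haps[idx]
        loci = self.loci
        if locus_mask is not None:
            locus_mask = np.asarray(locus_mask, dtype=bool)
            dosage = dosage[:, locus_mask]
            loci = loci.loc[locus_mask].reset_index(drop=True)
            haps = None if haps is None else haps[:, locus_mask]
        return GenotypePanel(dosage, loci, indiv, haplotypes=haps)

    def interval_mask(self, chrom, start_bp: int, end_bp: int) -> np.ndarray:
        """Boolean mask of loci inside [start_bp, end_bp] on ``chrom``."""
        loci = self.loci
        return (
            (loci["chrom"].to_numpy() == chrom)
            & (loci["pos"].to_numpy() >= start_bp)
            & (loci["pos"].to_numpy() <= end_bp)
        )


@dataclass
class GRM:
    """Genomic relationship matrix with provenance tags.

    ``matrix`` is symmetric, aligned with ``ids``.  ``effect_kind`` is
    ``"additive"`` or ``"dominance"``; ``locus_scope`` one of ``"genome-wide"``,
    ``"qtl"``, ``"background"``.
    """

    matrix: np.ndarray
    ids: list[str]
    effect_kind: str
    locus_scope: str = "genome-wide"
    allele_freqs_used: np.ndarray | None = None
    n_loci: int | None = None
    bent: bool = False
    bend_epsilon: float | None = None

    def __post_init__(self) -> None:
        self.matrix = np.asarray(self.matrix, dtype=float)
        n = len(self.ids)
        if self.matrix.shape != (n, n):
            raise ValueError("GRM matrix shape does not match id count")
        if not np.allclose(self.matrix, self.matrix.T, atol=1e-8):
            raise ValueError("GRM must be symmetric")

    def indexer(self, ids: Sequence[str]) -> np.ndarray:
        lookup = {v: i for i, v in enumerate(self.ids)}
        try:
            return np.array([lookup[i] for i in ids], dtype=int)
        except KeyError as exc:  # pragma: no cover - message path
            raise KeyError(f"individual {exc.args[0]!r} not in GRM") from exc

    def align(self, ids: Sequence[str]) -> np.ndarray:
        idx = self.indexer(ids)
        return self.matrix[np.ix_(idx, idx)]

    def with_matrix(self, matrix: np.ndarray, **changes) -> "GRM":
        return replace(self, matrix=matrix, **changes)


def validate_phenotypes(pheno: pd.DataFrame) -> pd.DataFrame:
    """Check required columns and add ``cell`` when absent."""
    pheno = pheno.copy()
    if "cell" not in pheno.columns:
        pheno["cell"] = [
            make_cell(t, s) for t, s in zip(pheno["trial"], pheno["season"])
        ]
    missing = [c for c in PHENO_COLUMNS if c not in pheno.columns]
    if missing:
        raise ValueError(f"phenotype table missing columns: {missing}")
    return pheno
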