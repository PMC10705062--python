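"""Core domain containers for diploid SNP data.

The central object is :class:`GenotypeMatrix`: a samples x variants matrix of
alternate-allele dosages (0, 1, 2, or :data:`MISSING`) together with variant
coordinates and a population label per sample.  Every downstream stage (QC,
structure analysis, sweep scanning, gene profiling) consumes this container.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

#: Sentinel dosage for a missing genotype (``./.`` in VCF).
MISSING: int = -1

VARIANT_COLUMNS = ("chrom", "pos", "ref", "alt", "id")


@dataclass(frozen=True)
class VariantRecord:
    """One biallelic variant locus.

    ``pos`` is 1-based, as in VCF.  ``ref`` and ``alt`` are the two allele
    strings; exactly one alternate allele is carried (multi-allelic records
    are split or dropped upstream).
    """

    chrom: str
    pos: int
    ref: str
    alt: str
    id: str | None = None

    def __post_init__(self) -> None:
        if self.pos < 1:
            raise ValueError(f"variant position must be >= 1, got {self.pos}")
        if not self.ref or not self.alt:
            raise ValueError("ref and alt alleles must be non-empty")
        if self.ref == self.alt:
            raise ValueError(f"ref == alt ({self.ref}) at {self.chrom}:{self.pos}")

    @property
    def is_snp(self) -> bool:
        return len(self.ref) == 1 and len(self.alt) == 1


@dataclass(frozen=True)
class GeneModel:
    """A named gene interval (1-based inclusive coordinates, GTF convention)."""

    gene_id: str
    gene_name: str
    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if self.start > self.end:
            raise ValueError(
                f"gene {self.gene_id}: start {self.start} > end {self.end}"
            )

    def interval(self, flank: int = 0) -> tuple[int, int]:
        """Gene span widened by ``flank`` bp on each side, clamped at 1."""
        return max(1, self.start - flank), self.end + flank


class ChromLengths(dict):
    """Mapping chromosome name -> length in bp."""

    def __setitem__(self, key: str, value: int) -> None:
        if int(value) < 1:
            raise ValueError(f"chromosome {key}: length must be >= 1")
        super().__setitem__(str(key), int(value))

    @classmethod
    def from_mapping(cls, m: Mapping[str, int]) -> "ChromLengths":
        out = cls()
        for k, v in m.items():
            out[k] = v
        return out


def chrom_sort_key(name: str) -> tuple[int, int, str]:
    """Numeric-aware chromosome ordering: 1 < 2 < ... < 10 < X < other."""
    s = re.sub(r"^chr", "", str(name), flags=re.IGNORECASE)
    if s.isdigit():
        return (0, int(s), "")
    return (1, 0, s)


@dataclass
class GenotypeMatrix:
    """Samples x variants alternate-allele dosage matrix with metadata.

    Parameters
    ----------
    samples
        Ordered unique sample identifiers (rows of ``dosage``).
    pops
        Population label for every sample.
    variants
        DataFrame with columns ``chrom, pos, ref, alt, id``, one row per
        variant (columns of ``dosage``), sorted by (chrom, pos).
    dosage
        Integer array of shape (n_samples, n_variants) with values in
        {0, 1, 2, MISSING}.
    """

    samples: list[str]
    pops: dict[str, str]
    variants: pd.DataFrame
    dosage: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        self.samples = list(self.samples)
        self.variants = self.variants.reset_index(drop=True)
        self.dosage = np.asarray(self.dosage, dtype=np.int16)
        self.validate()

    # -- invariants ----------------------------------------------------

    def validate(self) -> None:
        if len(set(self.samples)) != len(self.samples):
            raise ValueError("sample ids must be unique")
        missing_pop = [s for s in self.samples if s not in self.pops]
        if missing_pop:
            raise ValueError(f"samples without population label: {missing_pop[:5]}")
        for col in VARIANT_COLUMNS:
            if col not in self.variants.columns:
                raise ValueError(f"variants table lacks column {col!r}")
        if self.dosage.shape != (len(self.samples), len(self.variants)):
            raise ValueError(
                f"dosage shape {self.dosage.shape} != "
                f"({len(self.samples)}, {len(self.variants)})"
            )
        bad = ~np.isin(self.dosage, (0, 1, 2, MISSING))
        if bad.any():
            raise ValueError(f"invalid dosage values: {np.unique(self.dosage[bad])}")
        if len(self.variants) > 1:
            key = self._variant_order_key()
            if not all(key[i] <= key[i + 1] for i in range(len(key) - 1)):
                raise ValueError("variants must be sorted by (chrom, pos)")
        dup = self.variants.duplicated(subset=["chrom", "pos", "ref", "alt"])
        if dup.any():
            raise ValueError("duplicate (chrom, pos, ref, alt) variants")

    def _variant_order_key(self) -> list[tuple]:
        return [
            (chrom_sort_key(c), int(p))
            for c, p in zip(self.variants["chrom"], self.variants["pos"])
        ]

    # -- basic accessors ------------------------------------------------

    @property
    def n_samples(self) -> int:
        return len(self.samples)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def missing_mask(self) -> np.ndarray:
        """Boolean samples x variants mask of missing genotypes."""
        return self.dosage == MISSING

    def variant_records(self) -> list[VariantRecord]:
        return [
            VariantRecord(
                chrom=str(r.chrom),
                pos=int(r.pos),
                ref=str(r.ref),
                alt=str(r.alt),
                id=None if pd.isna(r.id) else str(r.id),
            )
            for r in self.variants.itertuples()
        ]

    def pop_labels(self) -> np.ndarray:
        """Population label per sample, in sample order."""
        return np.array([self.pops[s] for s in self.samples])

    def sample_indices(self, sample_ids: Iterable[str]) -> np.ndarray:
        pos = {s: i for i, s in enumerate(self.samples)}
        try:
            return np.array([pos[s] for s in sample_ids], dtype=np.intp)
        except KeyError as e:
            raise KeyError(f"unknown sample id {e.args[0]!r}") from None

    def samples_in_pops(self, pop_names: Iterable[str]) -> list[str]:
        wanted = set(pop_names)
        unknown = wanted - set(self.pops.values())
        if unknown:
            raise KeyError(f"unknown population labels: {sorted(unknown)}")
        return [s for s in self.samples if self.pops[s] in wanted]

    # -- frequencies -----------------------------------------------------

    def alt_allele_freq(self) -> np.ndarray:
        """Per-variant alternate-allele frequency over non-missing samples.

        NaN where every genotype is missing.
        """
        d = self.dosage.astype(float)
        obs = self.dosage != MISSING
        d[~obs] = 0.0
        n = obs.sum(axis=0)
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(n > 0, d.sum(axis=0) / (2.0 * n), np.nan)

    # -- subsetting ------------------------------------------------------

    def subset_samples(self, keep: Sequence[str] | np.ndarray) -> "GenotypeMatrix":
        if isinstance(keep, np.ndarray) and np.issubdtype(keep.dtype, np.integer):
            idx = np.asarray(keep, dtype=np.intp)
            names = [self.samples[i] for i in idx]
        else:
            names = list(keep)
            idx = self.sample_indices(names)
        return GenotypeMatrix(
            samples=names,
            pops={s: self.pops[s] for s in names},
            variants=self.variants.copy(),
            dosage=self.dosage[idx, :].copy(),
        )

    def subset_variants(self, keep: np.ndarray) -> "GenotypeMatrix":
        """Subset columns by boolean mask or index array (order preserved)."""
        keep = np.asarray(keep)
        if keep.dtype == bool:
            keep = np.flatnonzero(keep)
        return GenotypeMatrix(
            samples=list(self.samples),
            pops=dict(self.pops),
            variants=self.variants.iloc[keep],
            dosage=self.dosage[:, keep].copy(),
        )

    def restrict_chroms(self, chroms: Iterable[str]) -> "GenotypeMatrix":
        wanted = {str(c) for c in chroms}
        if not wanted:
            raise ValueError("empty chromosome set")
        mask = self.variants["chrom"].astype(str).isin(wanted).to_numpy()
        return self.subset_variants(mask)

    def sort_variants(self) -> "GenotypeMatrix":
        order = np.array(
            sorted(range(self.n_variants), key=lambda i: self._variant_order_key()[i]),
            dtype=np.intp,
        )
        return self.subset_variants(order)


def build_variant_table(records: Iterable[VariantRecord]) -> pd.DataFrame:
    rows = [(r.chrom, r.pos, r.ref, r.alt, r.id) for r in records]
    return pd.DataFrame(rows, columns=list(VARIANT_COLUMNS))
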