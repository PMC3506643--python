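"""Genotype matrix input/output and recoding.

The method consumes diploid biallelic SNP genotypes with alleles recoded
1/2 (the PLINK ``--recode12`` dialect, 0 = missing allele).  Downstream
every genotype is a single additive code: the sum of the two allele codes,
i.e. 2 (homozygous 1/1), 3 (heterozygous, either order) or 4 (homozygous
2/2).  Missing genotypes are carried as NaN and never imputed; distance
computations decide how to handle them.

Two on-disk formats are supported:

* PLINK ped/map text (``read_ped_map`` + ``recode_additive``);
* a plain additive-coded TSV with a header row of SNP ids, a leading
  ``sample_id`` column and cells in {2, 3, 4, NA}
  (``write_matrix`` / ``read_matrix``).

Merging two matrices requires allele codings already harmonized to the
same strand and reference scheme — strand flipping is out of scope here
and must be done upstream (e.g. with plink itself).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    DuplicateSampleError,
    InvalidAlleleError,
    InvalidCellError,
    MalformedFileError,
    NoOverlapError,
)

#: Sentinel for a missing additive genotype.
MISSING = np.nan

_VALID_ADDITIVE = (2.0, 3.0, 4.0)


@dataclass
class AllelePairTable:
    """Per-(sample, SNP) ordered allele-code pairs from {0, 1, 2}.

    A 0 in either position marks the whole genotype as missing.
    """

    sample_ids: list[str]
    snp_ids: list[str]
    pairs: np.ndarray  # (n_samples, n_snps, 2) integer array

    def __post_init__(self) -> None:
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DuplicateSampleError("sample ids are not unique")
        if len(set(self.snp_ids)) != len(self.snp_ids):
            raise MalformedFileError("snp ids are not unique")
        expected = (len(self.sample_ids), len(self.snp_ids), 2)
        if tuple(self.pairs.shape) != expected:
            raise MalformedFileError(
                f"pairs shape {self.pairs.shape} != expected {expected}"
            )


@dataclass
class GenotypeMatrix:
    """Samples x SNPs additive-coded genotypes with optional sample metadata.

    ``values`` is a float array whose entries are 2, 3, 4 or NaN (missing).
    ``metadata``, when present, is a DataFrame indexed like ``sample_ids``
    with at least a ``population`` column covering every sample.
    """

    sample_ids: list[str]
    snp_ids: list[str]
    values: np.ndarray  # (n_samples, n_snps) float
    metadata: pd.DataFrame | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if len(set(self.sample_ids)) != len(self.sample_ids):
            raise DuplicateSampleError("sample ids are not unique")
        if self.values.shape != (len(self.sample_ids), len(self.snp_ids)):
            raise MalformedFileError(
                f"values shape {self.values.shape} inconsistent with id lists"
            )
        finite = self.values[~np.isnan(self.values)]
        if finite.size and not np.isin(finite, _VALID_ADDITIVE).all():
            bad = finite[~np.isin(finite, _VALID_ADDITIVE)][0]
            raise InvalidCellError(f"additive genotype value {bad!r} not in {{2,3,4,NA}}")
        if self.metadata is not None:
            missing = set(self.sample_ids) - set(self.metadata.index)
            if missing:
                raise MalformedFileError(
                    f"metadata does not cover samples: {sorted(missing)[:5]}"
                )

    @property
    def n_samples(self) -> int:
        return len(self.sample_ids)

    @property
    def n_snps(self) -> int:
        return len(self.snp_ids)

    def sample_index(self, sample_id: str) -> int:
        return self.sample_ids.index(sample_id)

    def subset_samples(self, keep: list[str]) -> "GenotypeMatrix":
        idx = [self.sample_ids.index(s) for s in keep]
        meta = self.metadata.loc[keep] if self.metadata is not None else None
        return GenotypeMatrix(list(keep), list(self.snp_ids), self.values[idx], meta)

    def subset_snps(self, keep: list[str]) -> "GenotypeMatrix":
        pos = {s: j for j, s in enumerate(self.snp_ids)}
        idx = [pos[s] for s in keep]
        return replace(self, snp_ids=list(keep), values=self.values[:, idx])


def read_ped_map(ped_path: str | Path, map_path: str | Path) -> AllelePairTable:
    """Parse PLINK ped/map text files into an allele-pair table.

    The ped file has six leading pedigree columns (family id, sample id,
    paternal id, maternal id, sex, phenotype) followed by two allele
    columns per SNP; only the sample id is retained.  The map file gives
    the SNP order, one SNP per row (id in the second column of the usual
    4-column format, or the first column of a 1-column file).
    """
    snp_ids: list[str] = []
    for lineno, line in enumerate(_nonempty_lines(map_path), start=1):
        fields = line.split()
        snp_ids.append(fields[1] if len(fields) >= 2 else fields[0])
    if not snp_ids:
        raise MalformedFileError(f"{map_path}: empty map file")

    n_snps = len(snp_ids)
    sample_ids: list[str] = []
    rows: list[np.ndarray] = []
    for lineno, line in enumerate(_nonempty_lines(ped_path), start=1):
        fields = line.split()
        if len(fields) != 6 + 2 * n_snps:
            raise MalformedFileError(
                f"{ped_path}: row {lineno} has {len(fields)} columns, "
                f"expected {6 + 2 * n_snps} for {n_snps} SNPs"
            )
        sid = fields[1]
        if sid in sample_ids:
            raise DuplicateSampleError(f"{ped_path}: duplicate sample id {sid!r}")
        sample_ids.append(sid)
        try:
            alleles = np.array([int(a) for a in fields[6:]], dtype=np.int16)
        except ValueError as exc:
            raise MalformedFileError(
                f"{ped_path}: row {lineno} has a non-integer allele code"
            ) from exc
        rows.append(alleles.reshape(n_snps, 2))
    if not rows:
        raise MalformedFileError(f"{ped_path}: empty ped file")
    return AllelePairTable(sample_ids, snp_ids, np.stack(rows))


def recode_additive(table: AllelePairTable) -> GenotypeMatrix:
    """Collapse each allele pair to its additive code.

    1/1 -> 2, 1/2 and 2/1 -> 3, 2/2 -> 4; any pair containing a 0 becomes
    missing (NaN).  Allele order within a pair is irrelevant by
    construction (the code is the sum).
    """
    pairs = table.pairs
    if not np.isin(pairs, (0, 1, 2)).all():
        bad = pairs[~np.isin(pairs, (0, 1, 2))][0]
        raise InvalidAlleleError(f"allele code {bad} outside {{0,1,2}}")
    values = pairs.sum(axis=2).astype(float)
    values[(pairs == 0).any(axis=2)] = MISSING
    return GenotypeMatrix(list(table.sample_ids), list(table.snp_ids), values)


def recode_pair(a: int, b: int) -> float:
    """Additive code of a single allele pair; NaN if either allele is 0."""
    if a not in (0, 1, 2) or b not in (0, 1, 2):
        raise InvalidAlleleError(f"allele codes ({a}, {b}) outside {{0,1,2}}")
    if a == 0 or b == 0:
        return MISSING
    return float(a + b)


def filter_by_missingness(gm: GenotypeMatrix, max_rate: float = 0.01) -> GenotypeMatrix:
    """Keep SNPs whose fraction of missing genotypes is <= ``max_rate``.

    Follows plink ``--geno`` semantics (retain at the boundary).  The
    default 0.01 keeps SNPs with under-1% missingness.  SNP order is
    preserved.  Removing every SNP triggers a warning, not an error.
    """
    if not 0.0 <= max_rate <= 1.0:
        raise ValueError(f"max_rate must be in [0, 1], got {max_rate}")
    frac = np.isnan(gm.values).mean(axis=0)
    keep = frac <= max_rate
    if not keep.any():
        warnings.warn("filter_by_missingness removed every SNP", stacklevel=2)
    snp_ids = [s for s, k in zip(gm.snp_ids, keep) if k]
    return replace(gm, snp_ids=snp_ids, values=gm.values[:, keep])


def merge_datasets(a: GenotypeMatrix, b: GenotypeMatrix) -> GenotypeMatrix:
    """Union of samples over the intersection of SNP ids (in ``a``'s order).

    Inputs must be pre-harmonized additive codings with disjoint sample
    ids; values are copied unchanged.
    """
    shared_samples = set(a.sample_ids) & set(b.sample_ids)
    if shared_samples:
        raise DuplicateSampleError(
            f"sample ids present in both datasets: {sorted(shared_samples)[:5]}"
        )
    b_snps = set(b.snp_ids)
    shared_snps = [s for s in a.snp_ids if s in b_snps]
    if not shared_snps:
        raise NoOverlapError("datasets share no SNP ids")
    a_sub = a.subset_snps(shared_snps)
    b_sub = b.subset_snps(shared_snps)
    values = np.vstack([a_sub.values, b_sub.values])
    meta = None
    if a.metadata is not None and b.metadata is not None:
        meta = pd.concat([a.metadata, b.metadata])
    return GenotypeMatrix(a.sample_ids + b.sample_ids, shared_snps, values, meta)


def write_matrix(gm: GenotypeMatrix, path: str | Path) -> None:
    """Write an additive-coded genotype TSV (cells 2/3/4, NA = missing)."""
    df = pd.DataFrame(gm.values, index=gm.sample_ids, columns=gm.snp_ids)
    df.index.name = "sample_id"
    df.to_csv(path, sep="\t", na_rep="NA", float_format="%.0f")


def read_matrix(path: str | Path) -> GenotypeMatrix:
    """Read a genotype TSV written by :func:`write_matrix`.

    ``read_matrix(write_matrix(gm))`` reproduces ``gm`` exactly.  Any cell
    outside {2, 3, 4, NA} raises :class:`InvalidCellError` naming its
    (sample, SNP) coordinates.
    """
    try:
        df = pd.read_csv(
            path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False,
            dtype=str,
        )
    except (pd.errors.EmptyDataError, pd.errors.ParserError) as exc:
        raise MalformedFileError(f"{path}: {exc}") from exc
    if df.index.name != "sample_id":
        raise MalformedFileError(f"{path}: first column must be 'sample_id'")
    raw = df.to_numpy()
    values = np.full(raw.shape, MISSING)
    for cell in ("2", "3", "4"):
        values[raw == cell] = float(cell)
    bad = (~np.isin(raw, ("2", "3", "4"))) & ~pd.isna(raw)
    if bad.any():
        i, j = np.argwhere(bad)[0]
        raise InvalidCellError(
            f"{path}: cell {raw[i, j]!r} at sample {df.index[i]!r}, "
            f"SNP {df.columns[j]!r} not in {{2,3,4,NA}}"
        )
    return GenotypeMatrix(list(df.index), list(df.columns), values)


def read_metadata(path: str | Path) -> pd.DataFrame:
    """Read a sample metadata TSV.

    Required columns: ``sample_id``, ``population``.  Optional:
    ``region``, ``dataset``, ``latitude``, ``longitude``.  Returns a
    DataFrame indexed by sample_id; coordinate ranges are validated.
    """
    try:
        df = pd.read_csv(path, sep="\t")
    except pd.errors.EmptyDataError as exc:
        raise MalformedFileError(f"{path}: empty metadata file") from exc
    for col in ("sample_id", "population"):
        if col not in df.columns:
            raise MalformedFileError(f"{path}: missing required column {col!r}")
    if df["sample_id"].duplicated().any():
        dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise DuplicateSampleError(f"{path}: duplicate sample id {dup!r}")
    df = df.set_index("sample_id")
    if "latitude" in df.columns:
        lat = df["latitude"].dropna()
        if ((lat < -90) | (lat > 90)).any():
            raise MalformedFileError(f"{path}: latitude outside [-90, 90]")
    if "longitude" in df.columns:
        lon = df["longitude"].dropna()
        if ((lon < -180) | (lon > 180)).any():
            raise MalformedFileError(f"{path}: longitude outside [-180, 180]")
    return df


def write_metadata(metadata: pd.DataFrame, path: str | Path) -> None:
    metadata.to_csv(path, sep="\t", index_label="sample_id")


def _nonempty_lines(path: str | Path):
    with open(path) as fh:
        for line in fh:
            if line.strip():
                yield line
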