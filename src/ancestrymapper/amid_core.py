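"""AMid computation: distance barcodes against a reference panel.

An AMid ("Ancestry Mapper id") vector characterizes one individual as its
genetic distance to one reference individual per reference population.
The metric is the per-SNP-normalized Euclidean distance between additive
genotype vectors,

    d(g, r) = sqrt( sum_j (g_j - r_j)^2 / n ),

the root-mean-square genotype difference over the n SNPs that are
non-missing in both vectors.  Dividing by the number of SNPs actually
compared keeps distances on a common scale whatever the SNP overlap, so
AMids computed from different chips or from random SNP subsets are
directly comparable.

Each raw vector is then normalized per individual to a 0-100 "barcode":
the closest reference (smallest raw distance) scores exactly 100, the
farthest exactly 0, all others by linear interpolation.  High therefore
means similar.  Both scales carry information — the raw vector preserves
absolute divergence, the barcode the relative ranking — so both are kept
and exported.

Every individual is scored independently of any other individual in the
dataset: an AMid depends only on the individual's genotypes and the panel.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .errors import (
    DegenerateProfileError,
    InsufficientOverlapError,
    InsufficientSnpsError,
    NoOverlapError,
)
from .genotype_io import GenotypeMatrix

logger = logging.getLogger(__name__)

#: Default minimum jointly non-missing SNPs per (individual, reference) pair.
DEFAULT_MIN_OVERLAP = 1000


@dataclass
class AMidProfile:
    """One individual's raw and normalized distance vector over a panel."""

    sample_id: str
    population_names: list[str]
    raw: np.ndarray         # per-SNP-normalized Euclidean distances, >= 0
    normalized: np.ndarray  # in [0, 100]; 100 = closest reference
    n_snps_used: np.ndarray  # jointly non-missing SNP count per reference

    def closest_reference(self) -> str:
        """Population of the highest-scoring reference (first in panel
        order on ties; a tie is logged)."""
        top = self.normalized.max()
        winners = np.flatnonzero(self.normalized == top)
        if winners.size > 1:
            logger.warning(
                "sample %s: %d references tie at the maximum AMid",
                self.sample_id, winners.size,
            )
        return self.population_names[winners[0]]


@dataclass
class SubsampleReport:
    """AMid replicates under random SNP subsampling for one individual."""

    sample_id: str
    population_names: list[str]
    n_snps: int
    n_reps: int
    seed: int
    replicates: np.ndarray  # (n_reps, panel size) raw AMid vectors
    sd: np.ndarray          # per-reference standard deviation across reps
    iqr: np.ndarray         # per-reference interquartile range across reps
    full_raw: np.ndarray    # raw AMid from all shared SNPs, for comparison


def masked_sq_diff(values_a: np.ndarray, values_b: np.ndarray):
    """Pairwise sums of squared differences over jointly non-missing SNPs.

    For row sets A (n x m) and B (p x m) with NaN missing, returns
    ``(ss, n_used)`` where ``ss[i, k] = sum_j (a_ij - b_kj)^2`` over SNPs j
    non-missing in both rows, and ``n_used[i, k]`` counts those SNPs.
    Expands the square into three matrix products so missingness costs no
    python-level loop.
    """
    ma = ~np.isnan(values_a)
    mb = ~np.isnan(values_b)
    a = np.where(ma, values_a, 0.0)
    b = np.where(mb, values_b, 0.0)
    fa = ma.astype(float)
    fb = mb.astype(float)
    ss = (a ** 2) @ fb.T + fa @ (b ** 2).T - 2.0 * (a @ b.T)
    np.maximum(ss, 0.0, out=ss)  # clip tiny negative round-off
    n_used = np.rint(fa @ fb.T).astype(int)
    return ss, n_used


def distance_to_reference(
    genotypes: np.ndarray,
    ref_genotypes: np.ndarray,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> tuple[float, int]:
    """Per-SNP-normalized Euclidean distance between two genotype vectors.

    Both vectors must be aligned on the same SNP list.  Returns
    ``(distance, n_used)`` where ``n_used`` counts the jointly non-missing
    positions; fewer than ``min_overlap`` of them raises
    :class:`InsufficientOverlapError`.
    """
    g = np.asarray(genotypes, dtype=float)
    r = np.asarray(ref_genotypes, dtype=float)
    if g.shape != r.shape:
        raise ValueError(f"vector lengths differ: {g.shape} vs {r.shape}")
    joint = ~np.isnan(g) & ~np.isnan(r)
    n_used = int(joint.sum())
    if n_used < min_overlap:
        raise InsufficientOverlapError(
            f"only {n_used} jointly non-missing SNPs (< min_overlap={min_overlap})",
            n_used=n_used,
        )
    diff = g[joint] - r[joint]
    return float(np.sqrt((diff ** 2).sum() / n_used)), n_used


def normalize_amids(raw_vector: np.ndarray) -> np.ndarray:
    """Affine rescale of a raw distance vector to the 0-100 barcode.

    ``normalized_j = 100 * (d_max - d_j) / (d_max - d_min)``: the closest
    reference maps to exactly 100, the farthest to exactly 0.  A constant
    vector has no such rescale and raises :class:`DegenerateProfileError`.
    """
    raw = np.asarray(raw_vector, dtype=float)
    if raw.size < 2:
        raise DegenerateProfileError("need at least two references to normalize")
    d_min, d_max = raw.min(), raw.max()
    if d_max == d_min:
        raise DegenerateProfileError("constant raw AMid vector cannot be normalized")
    # divide before scaling so the endpoints land on exactly 100 and 0
    return 100.0 * ((d_max - raw) / (d_max - d_min))


def compute_amids(
    gm: GenotypeMatrix,
    panel,
    min_overlap: int = DEFAULT_MIN_OVERLAP,
) -> list[AMidProfile]:
    """Compute raw and normalized AMid profiles for every sample in ``gm``.

    Genotypes are aligned to the panel on shared SNP ids; each sample is
    scored independently, so a batch of one equals the corresponding row
    of a batch of many.
    """
    gm_snps = set(gm.snp_ids)
    shared = [s for s in panel.snp_ids if s in gm_snps]
    if not shared:
        raise NoOverlapError("no SNP ids shared between genotypes and panel")
    gm_vals = gm.subset_snps(shared).values
    panel_pos = {s: j for j, s in enumerate(panel.snp_ids)}
    ref_vals = panel.genotypes[:, [panel_pos[s] for s in shared]]

    ss, n_used = masked_sq_diff(gm_vals, ref_vals)
    short = n_used < min_overlap
    if short.any():
        i, k = np.argwhere(short)[0]
        raise InsufficientOverlapError(
            f"sample {gm.sample_ids[i]!r} vs reference "
            f"{panel.populations[k]!r}: only {n_used[i, k]} jointly "
            f"non-missing SNPs (< min_overlap={min_overlap})",
            n_used=int(n_used[i, k]),
        )
    raw = np.sqrt(ss / n_used)
    profiles = []
    for i, sid in enumerate(gm.sample_ids):
        profiles.append(
            AMidProfile(
                sample_id=sid,
                population_names=list(panel.populations),
                raw=raw[i],
                normalized=normalize_amids(raw[i]),
                n_snps_used=n_used[i],
            )
        )
    return profiles


def subsample_stability(
    gm: GenotypeMatrix,
    sample_id: str,
    panel,
    n_snps: int,
    n_reps: int = 10,
    seed: int = 0,
    min_overlap: int = 1,
) -> SubsampleReport:
    """Quantify AMid stability under random SNP subsampling.

    Draws ``n_reps`` independent SNP subsets of size ``n_snps`` (without
    replacement, seeded) from the SNPs shared with the panel, recomputes
    the raw AMid vector on each, and summarizes the per-reference spread
    (SD and IQR) next to the full-SNP AMid.
    """
    if n_reps < 2:
        raise ValueError("n_reps must be >= 2")
    gm_snps = set(gm.snp_ids)
    shared = [s for s in panel.snp_ids if s in gm_snps]
    if n_snps > len(shared):
        raise InsufficientSnpsError(
            f"requested {n_snps} SNPs but only {len(shared)} shared with the panel"
        )
    sub = gm.subset_samples([sample_id]).subset_snps(shared)
    panel_pos = {s: j for j, s in enumerate(panel.snp_ids)}
    ref_vals = panel.genotypes[:, [panel_pos[s] for s in shared]]

    rng = np.random.default_rng(seed)
    reps = np.empty((n_reps, len(panel.populations)))
    for r in range(n_reps):
        idx = rng.choice(len(shared), size=n_snps, replace=False)
        ss, n_used = masked_sq_diff(sub.values[:, idx], ref_vals[:, idx])
        if (n_used < min_overlap).any():
            k = int(np.argwhere(n_used[0] < min_overlap)[0][0])
            raise InsufficientOverlapError(
                f"replicate {r}: reference {panel.populations[k]!r} has "
                f"{n_used[0, k]} jointly non-missing SNPs",
                n_used=int(n_used[0, k]),
            )
        reps[r] = np.sqrt(ss[0] / n_used[0])

    ss_full, n_full = masked_sq_diff(sub.values, ref_vals)
    q75, q25 = np.percentile(reps, [75, 25], axis=0)
    return SubsampleReport(
        sample_id=sample_id,
        population_names=list(panel.populations),
        n_snps=n_snps,
        n_reps=n_reps,
        seed=seed,
        replicates=reps,
        sd=reps.std(axis=0, ddof=1),
        iqr=q75 - q25,
        full_raw=np.sqrt(ss_full[0] / n_full[0]),
    )


def profiles_to_frame(profiles: list[AMidProfile], kind: str = "normalized") -> pd.DataFrame:
    """Stack profiles into a samples x panel-populations DataFrame."""
    if not profiles:
        raise ValueError("no profiles given")
    pops = profiles[0].population_names
    data = np.vstack([getattr(p, kind) for p in profiles])
    return pd.DataFrame(data, index=[p.sample_id for p in profiles], columns=pops)


def export_amid_table(profiles: list[AMidProfile], out_dir: str | Path) -> None:
    """Write ``amids_raw.tsv`` and ``amids_normalized.tsv`` under ``out_dir``."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    for kind in ("raw", "normalized"):
        df = profiles_to_frame(profiles, kind)
        df.index.name = "sample_id"
        df.to_csv(out / f"amids_{kind}.tsv", sep="\t", float_format="%.6f")


def load_amid_table(path: str | Path) -> pd.DataFrame:
    """Read an AMid TSV written by :func:`export_amid_table`."""
    return pd.read_csv(path, sep="\t", index_col="sample_id")


def heatmap_export(
    profiles: list[AMidProfile],
    path: str | Path,
    metadata: pd.DataFrame | None = None,
) -> None:
    """Render the normalized AMid barcodes as a raster heatmap.

    Rows are grouped into population blocks when metadata with a
    ``population`` column is supplied (block order = order of first
    appearance), columns follow panel order.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    df = profiles_to_frame(profiles, "normalized")
    if metadata is not None and "population" in metadata.columns:
        pops = metadata.loc[df.index, "population"]
        order = pops.drop_duplicates().tolist()
        key = pops.map({p: i for i, p in enumerate(order)})
        df = df.loc[key.sort_values(kind="stable").index]
    fig, ax = plt.subplots(
        figsize=(max(6, 0.18 * df.shape[1]), max(4, 0.04 * df.shape[0]))
    )
    im = ax.imshow(df.to_numpy(), aspect="auto", cmap="viridis", vmin=0, vmax=100)
    ax.set_xticks(range(df.shape[1]))
    ax.set_xticklabels(df.columns, rotation=90, fontsize=6)
    ax.set_yticks([])
    ax.set_xlabel("reference population")
    ax.set_ylabel("individuals")
    fig.colorbar(im, ax=ax, label="normalized AMid")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
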