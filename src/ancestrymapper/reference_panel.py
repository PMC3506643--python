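"""Reference panel construction and reference-to-reference structure.

One individual stands in for each reference population: the member with
the smallest median genetic distance to all other members of its
population — a medoid-like "central" individual.  The ordered set of
these references is the panel against which every AMid is computed.

The panel's internal structure is summarized two ways:

* a reference distance matrix, plus a similarity rescale in which the
  most similar off-diagonal pair scores exactly 100 and the most distant
  pair 0 (the diagonal is reported as 100 by convention and excluded
  from the rescale);
* an agglomerative dendrogram over the references (complete linkage by
  default), exportable as Newick.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import scipy.cluster.hierarchy as sch
from scipy.spatial.distance import squareform

from .amid_core import masked_sq_diff
from .errors import (
    DegenerateScaleError,
    EmptyPopulationError,
    IncomparablePairError,
)
from .genotype_io import GenotypeMatrix


@dataclass
class ReferencePanel:
    """Ordered reference populations with their chosen individuals.

    ``genotypes`` holds one additive-coded row per population, aligned on
    ``snp_ids``.
    """

    populations: list[str]
    sample_ids: list[str]
    genotypes: np.ndarray  # (n_populations, n_snps) float, NaN = missing
    snp_ids: list[str]

    def __post_init__(self) -> None:
        if len(set(self.populations)) != len(self.populations):
            raise ValueError("panel population names must be unique")
        if self.genotypes.shape != (len(self.populations), len(self.snp_ids)):
            raise ValueError("panel genotype shape inconsistent with id lists")

    def __len__(self) -> int:
        return len(self.populations)

    @property
    def entries(self):
        return list(zip(self.populations, self.sample_ids, self.genotypes))

    def to_dir(self, out_dir: str | Path) -> None:
        """Serialize as ``panel.tsv`` (population, sample_id) plus a
        genotype TSV of the reference vectors."""
        from .genotype_io import write_matrix

        out = Path(out_dir)
        out.mkdir(parents=True, exist_ok=True)
        pd.DataFrame(
            {"population": self.populations, "sample_id": self.sample_ids}
        ).to_csv(out / "panel.tsv", sep="\t", index=False)
        gm = GenotypeMatrix(list(self.sample_ids), list(self.snp_ids), self.genotypes)
        write_matrix(gm, out / "reference_genotypes.tsv")

    @classmethod
    def from_dir(cls, panel_dir: str | Path) -> "ReferencePanel":
        from .genotype_io import read_matrix

        panel_dir = Path(panel_dir)
        table = pd.read_csv(panel_dir / "panel.tsv", sep="\t")
        gm = read_matrix(panel_dir / "reference_genotypes.tsv")
        rows = [gm.sample_index(s) for s in table["sample_id"]]
        return cls(
            populations=table["population"].tolist(),
            sample_ids=table["sample_id"].tolist(),
            genotypes=gm.values[rows],
            snp_ids=list(gm.snp_ids),
        )


@dataclass
class ReferenceDistanceMatrix:
    """Raw distances between references and their 0-100 similarity rescale."""

    population_names: list[str]
    raw: np.ndarray         # symmetric, zero diagonal
    similarity: np.ndarray  # off-diagonal max = 100 at the most similar pair

    def raw_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.raw, index=self.population_names,
                            columns=self.population_names)

    def similarity_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.similarity, index=self.population_names,
                            columns=self.population_names)


@dataclass
class Dendrogram:
    """Agglomerative merge tree over panel populations."""

    labels: list[str]
    linkage: np.ndarray = field(repr=False)  # scipy linkage matrix
    method: str = "complete"

    def merge_heights(self) -> np.ndarray:
        return self.linkage[:, 2]

    def to_newick(self) -> str:
        """Newick string with branch lengths from merge heights."""
        tree = sch.to_tree(self.linkage)

        def render(node, parent_height: float) -> str:
            length = parent_height - node.dist
            if node.is_leaf():
                return f"{self.labels[node.id]}:{length:.6g}"
            left = render(node.left, node.dist)
            right = render(node.right, node.dist)
            return f"({left},{right}):{length:.6g}"

        left = render(tree.left, tree.dist)
        right = render(tree.right, tree.dist)
        return f"({left},{right});"


def pairwise_distances(
    gm: GenotypeMatrix, sample_subset: list[str] | None = None
) -> pd.DataFrame:
    """Symmetric per-SNP-normalized Euclidean distance matrix.

    Distances use pairwise-complete SNPs (positions non-missing in both
    samples of a pair).  A pair with zero jointly non-missing SNPs raises
    :class:`IncomparablePairError` naming the pair.
    """
    ids = list(sample_subset) if sample_subset is not None else list(gm.sample_ids)
    if not ids:
        raise ValueError("sample subset is empty")
    sub = gm.subset_samples(ids)
    ss, n_used = masked_sq_diff(sub.values, sub.values)
    off = ~np.eye(len(ids), dtype=bool)
    if (n_used[off] == 0).any():
        i, j = np.argwhere((n_used == 0) & off)[0]
        raise IncomparablePairError(
            f"samples {ids[i]!r} and {ids[j]!r} share no non-missing SNPs"
        )
    with np.errstate(invalid="ignore"):
        dist = np.sqrt(ss / np.where(n_used > 0, n_used, 1))
    np.fill_diagonal(dist, 0.0)
    dist = (dist + dist.T) / 2.0  # enforce exact symmetry
    return pd.DataFrame(dist, index=ids, columns=ids)


def select_reference(gm: GenotypeMatrix, population_members: list[str]) -> str:
    """The member with the smallest median distance to all other members.

    Ties on the median are broken by smallest mean distance, then by
    lexicographically smallest sample id, so the choice is deterministic
    and independent of input order.
    """
    members = list(population_members)
    if not members:
        raise EmptyPopulationError("population has no members")
    if len(members) == 1:
        return members[0]
    dist = pairwise_distances(gm, members).to_numpy()
    n = len(members)
    others = ~np.eye(n, dtype=bool)
    medians = np.array([np.median(dist[i][others[i]]) for i in range(n)])
    means = np.array([dist[i][others[i]].mean() for i in range(n)])
    order = sorted(range(n), key=lambda i: (medians[i], means[i], members[i]))
    return members[order[0]]


def build_panel(gm: GenotypeMatrix, metadata: pd.DataFrame | None = None) -> ReferencePanel:
    """Select one reference per population and assemble the panel.

    ``metadata`` (indexed by sample id with a ``population`` column)
    defaults to ``gm.metadata``.  Populations appear in metadata order of
    first appearance; a population with no genotyped member is an error.
    """
    meta = metadata if metadata is not None else gm.metadata
    if meta is None:
        raise ValueError("no metadata available to define populations")
    unlabelled = [s for s in gm.sample_ids if s not in meta.index]
    if unlabelled:
        raise EmptyPopulationError(
            f"samples without a population label: {unlabelled[:5]}"
        )
    pops_in_order = meta["population"].drop_duplicates().tolist()
    sample_set = set(gm.sample_ids)
    populations, ref_ids, rows = [], [], []
    for pop in pops_in_order:
        members = [s for s in meta.index[meta["population"] == pop] if s in sample_set]
        if not members:
            raise EmptyPopulationError(f"population {pop!r} has no genotyped members")
        ref = select_reference(gm, members)
        populations.append(pop)
        ref_ids.append(ref)
        rows.append(gm.values[gm.sample_index(ref)])
    return ReferencePanel(populations, ref_ids, np.vstack(rows), list(gm.snp_ids))


def reference_similarity_matrix(panel: ReferencePanel) -> ReferenceDistanceMatrix:
    """Distances between references, rescaled so the most similar pair = 100.

    The similarity is the affine map sending the minimum off-diagonal raw
    distance to 100 and the maximum to 0; the diagonal is set to 100 by
    convention and excluded from the fit.
    """
    gm = GenotypeMatrix(list(panel.sample_ids), list(panel.snp_ids), panel.genotypes)
    raw = pairwise_distances(gm).to_numpy()
    n = len(panel)
    off = ~np.eye(n, dtype=bool)
    d_min, d_max = raw[off].min(), raw[off].max()
    if d_max == d_min:
        raise DegenerateScaleError("all off-diagonal reference distances are equal")
    similarity = 100.0 * ((d_max - raw) / (d_max - d_min))
    np.fill_diagonal(similarity, 100.0)
    return ReferenceDistanceMatrix(list(panel.populations), raw, similarity)


def cluster_references(panel: ReferencePanel, linkage_method: str = "complete") -> Dendrogram:
    """Agglomerative clustering of the references on raw distances."""
    if linkage_method not in ("complete", "average", "single"):
        raise ValueError(f"unsupported linkage method {linkage_method!r}")
    gm = GenotypeMatrix(list(panel.sample_ids), list(panel.snp_ids), panel.genotypes)
    raw = pairwise_distances(gm).to_numpy()
    Z = sch.linkage(squareform(raw, checks=False), method=linkage_method)
    return Dendrogram(list(panel.populations), Z, linkage_method)
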