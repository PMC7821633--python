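"""Core domain containers shared across the pipeline.

All coordinates on proteins are 1-based inclusive (Pfam convention).
Expression matrices are pandas DataFrames with gene rows and sample columns.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import dendropy
import numpy as np
import pandas as pd

#: Sample-type categories used throughout (early development through adult).
CATEGORIES = (
    "early_embryo",
    "endoderm_diff",
    "mesoderm_diff",
    "ectoderm_diff",
    "organ_development",
    "adult_tissue",
)


class FormatError(ValueError):
    """Raised when an external file violates a format invariant."""


class SpeciesTree:
    """Rooted species tree with named internal taxa.

    Every node (internal taxa and species leaves) carries a unique name.
    ``rank_index`` orders nodes by root distance in edges: 0 for the root,
    strictly increasing along every root-to-leaf path, so a smaller rank
    means an evolutionarily older taxon.
    """

    def __init__(self, tree: dendropy.Tree):
        self._tree = tree
        self._name_to_node: dict[str, dendropy.Node] = {}
        self.rank_index: dict[str, int] = {}
        for node in tree.preorder_node_iter():
            name = _node_name(node)
            if not name:
                raise FormatError("species tree has an unnamed node")
            if name in self._name_to_node:
                raise FormatError(f"duplicate node name in species tree: {name!r}")
            self._name_to_node[name] = node
            self.rank_index[name] = 0 if node.parent_node is None else (
                self.rank_index[_node_name(node.parent_node)] + 1
            )
        self.leaf_names = [_node_name(n) for n in tree.leaf_node_iter()]

    @property
    def root_name(self) -> str:
        return _node_name(self._tree.seed_node)

    @property
    def node_names(self) -> list[str]:
        return list(self._name_to_node)

    def has_node(self, name: str) -> bool:
        return name in self._name_to_node

    def is_leaf(self, name: str) -> bool:
        return name in self._name_to_node and self._name_to_node[name].is_leaf()

    def root_path(self, name: str) -> list[str]:
        """Node names from the root down to ``name`` (inclusive)."""
        node = self._name_to_node[name]
        path = []
        while node is not None:
            path.append(_node_name(node))
            node = node.parent_node
        return path[::-1]

    def mrca(self, species: set[str] | list[str]) -> str:
        """Most recent common ancestor taxon of a set of leaves."""
        species = list(dict.fromkeys(species))
        if not species:
            raise ValueError("empty species set")
        for s in species:
            if s not in self._name_to_node:
                raise KeyError(f"unknown species: {s!r}")
            if not self._name_to_node[s].is_leaf():
                raise KeyError(f"not a leaf of the species tree: {s!r}")
        if len(species) == 1:
            return species[0]
        taxa = [self._name_to_node[s].taxon for s in species]
        node = self._tree.mrca(taxa=taxa)
        return _node_name(node)

    def clade_leaves(self, name: str) -> set[str]:
        node = self._name_to_node[name]
        return {_node_name(n) for n in node.leaf_iter()}

    def to_newick(self) -> str:
        s = self._tree.as_string(schema="newick", suppress_rooting=True)
        return s.strip()


def _node_name(node: dendropy.Node) -> str | None:
    if node.taxon is not None and node.taxon.label:
        return node.taxon.label
    return node.label


@dataclass(frozen=True)
class Domain:
    """A domain hit on a protein; 1-based inclusive coordinates."""

    family_id: str
    start: int
    end: int
    is_krab: bool = False
    is_c2h2: bool = False

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class GeneRecord:
    """A gene with its representative (longest-isoform) protein."""

    gene_id: str
    species: str
    protein_id: str
    protein_length: int
    domains: list[Domain] = field(default_factory=list)
    gene_age_taxon: str | None = None
    znf_divergence_taxon: str | None = None

    def __post_init__(self) -> None:
        for d in self.domains:
            if not (1 <= d.start <= d.end <= self.protein_length):
                raise FormatError(
                    f"domain {d.family_id} [{d.start},{d.end}] outside protein "
                    f"{self.protein_id} of length {self.protein_length}"
                )

    @property
    def is_kzfp(self) -> bool:
        """True iff the protein carries at least one KRAB domain and one C2H2 finger."""
        return any(d.is_krab for d in self.domains) and any(
            d.is_c2h2 for d in self.domains
        )


@dataclass
class DisorderTrack:
    """Per-residue order/disorder labels for one protein ('O' or 'D')."""

    protein_id: str
    labels: str

    def __post_init__(self) -> None:
        bad = set(self.labels) - {"O", "D"}
        if bad:
            raise FormatError(
                f"disorder track {self.protein_id}: labels outside {{O,D}}: {sorted(bad)}"
            )

    def __len__(self) -> int:
        return len(self.labels)


class ExpressionDataset:
    """Counts + TPM matrices and sample metadata for one RNA-seq dataset.

    ``counts`` and ``tpm`` are genes x samples DataFrames sharing index and
    columns; ``samples`` has one row per sample with columns
    ``category`` (one of :data:`CATEGORIES`), ``stage_order`` (int) and
    ``batch_id``, indexed by sample id.
    """

    def __init__(
        self,
        dataset_id: str,
        species: str,
        counts: pd.DataFrame,
        tpm: pd.DataFrame,
        samples: pd.DataFrame,
    ):
        counts = counts.sort_index()
        tpm = tpm.sort_index()
        if list(counts.index) != list(tpm.index) or list(counts.columns) != list(
            tpm.columns
        ):
            raise FormatError(
                f"dataset {dataset_id}: counts and TPM matrices do not share "
                "gene/sample indices"
            )
        if counts.index.has_duplicates or counts.columns.has_duplicates:
            raise FormatError(f"dataset {dataset_id}: duplicate gene or sample ids")
        missing = set(counts.columns) - set(samples.index)
        if missing:
            raise FormatError(
                f"dataset {dataset_id}: samples missing from metadata: {sorted(missing)}"
            )
        cvals = counts.to_numpy()
        if not np.issubdtype(cvals.dtype, np.integer):
            if not np.allclose(cvals, np.round(cvals)):
                raise FormatError(f"dataset {dataset_id}: counts are not integers")
            counts = counts.round().astype(np.int64)
            cvals = counts.to_numpy()
        if (cvals < 0).any():
            raise FormatError(f"dataset {dataset_id}: negative count")
        if (tpm.to_numpy() < 0).any():
            raise FormatError(f"dataset {dataset_id}: negative TPM")
        bad_cat = set(samples["category"]) - set(CATEGORIES)
        if bad_cat:
            raise FormatError(
                f"dataset {dataset_id}: unknown sample category: {sorted(bad_cat)}"
            )
        self.dataset_id = dataset_id
        self.species = species
        self.counts = counts
        self.tpm = tpm
        self.samples = samples.loc[list(counts.columns)]

    @property
    def gene_ids(self) -> list[str]:
        return list(self.counts.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.counts.columns)

    @property
    def n_genes(self) -> int:
        return self.counts.shape[0]

    @property
    def n_samples(self) -> int:
        return self.counts.shape[1]

    def log_tpm(self) -> pd.DataFrame:
        """log2(TPM + 1); the pseudo-count is exactly 1."""
        return np.log2(self.tpm + 1.0)


@dataclass
class AgeTable:
    """Per-gene age taxa and old/mid/young grades.

    ``table`` is indexed by gene_id with columns ``age_taxon``, ``age_grade``
    and optionally ``znf_divergence_taxon``, ``znf_grade``.
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        if self.table.index.has_duplicates:
            dup = self.table.index[self.table.index.duplicated()][0]
            raise FormatError(f"gene appears twice in age table: {dup!r}")

    def grade(self, gene_id: str) -> str:
        return self.table.at[gene_id, "age_grade"]

    def __contains__(self, gene_id: str) -> bool:
        return gene_id in self.table.index
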