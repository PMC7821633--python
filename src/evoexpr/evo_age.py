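"""Evolutionary-age assignment and three-grade age schemes.

A domain family's age is the taxon in which it first appeared, taken as the
most recent common ancestor (MRCA) of the species where the family is
observed — the oldest clade that must contain every occurrence. Ages
(taxa) are then coarsened to three grades: ``old`` (cellular organisms
through Opisthokonta), ``mid`` (Eumetazoa through Vertebrata) and ``young``
(Mammalia and younger). The same scheme grades the divergence taxa of
C2H2 zinc-finger arrays in KZFPs.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from .types import GeneRecord, SpeciesTree

#: Default ordered taxon backbone, oldest first. The exact roster between the
#: grade boundaries varies by species; schemes are fully configurable.
DEFAULT_TAXA = (
    "CellularOrganisms",
    "Eukaryota",
    "Opisthokonta",
    "Eumetazoa",
    "Bilateria",
    "Deuterostomia",
    "Chordata",
    "Vertebrata",
    "Mammalia",
    "Theria",
    "Eutheria",
)


@dataclass(frozen=True)
class GradeScheme:
    """Maps taxa (ordered oldest to youngest) onto old/mid/young grades.

    ``old_until`` is the youngest taxon still graded old; ``young_from`` is
    the oldest taxon graded young; everything strictly between is mid.
    """

    taxa: tuple[str, ...] = DEFAULT_TAXA
    old_until: str = "Opisthokonta"
    young_from: str = "Mammalia"
    #: species leaves are younger than every named internal taxon
    leaf_grade: str = field(default="young")

    def __post_init__(self) -> None:
        if len(set(self.taxa)) != len(self.taxa):
            raise ValueError("duplicate taxa in grade scheme")
        i_old = self._index(self.old_until)
        i_young = self._index(self.young_from)
        if not i_old < i_young:
            raise ValueError("grade boundaries do not partition the taxon order")

    def _index(self, taxon: str) -> int:
        try:
            return self.taxa.index(taxon)
        except ValueError:
            raise KeyError(f"taxon not in grade scheme: {taxon!r}") from None

    def grade_of(self, taxon: str) -> str:
        """old/mid/young grade of a taxon; raises KeyError for unknown taxa."""
        i = self._index(taxon)
        if i <= self._index(self.old_until):
            return "old"
        if i >= self._index(self.young_from):
            return "young"
        return "mid"

    def grade_or_leaf(self, taxon: str, tree: SpeciesTree | None = None) -> str:
        """Like :meth:`grade_of` but species leaves grade as ``leaf_grade``."""
        if taxon not in self.taxa and tree is not None and tree.is_leaf(taxon):
            return self.leaf_grade
        return self.grade_of(taxon)

    def age_rank(self, taxon: str) -> int:
        """Position in the oldest-first order (0 = oldest); for correlations."""
        return self._index(taxon)


def domain_age(family_presence: set[str] | list[str], tree: SpeciesTree) -> str:
    """Taxon of origin of a domain family from its species presence set.

    The family is assumed to have arisen once; its origin is the MRCA of all
    species carrying it. Unknown species raise KeyError; an empty presence
    set raises ValueError.
    """
    return tree.mrca(family_presence)


def grade_of(taxon: str, scheme: GradeScheme) -> str:
    return scheme.grade_of(taxon)


def znf_grade_of(record: GeneRecord, scheme: GradeScheme) -> str:
    """Grade of the zinc-finger divergence taxon of a KZFP.

    Raises ValueError for non-KZFP genes or a missing divergence taxon:
    finger divergence times are defined only for KRAB zinc-finger proteins.
    """
    if not record.is_kzfp:
        raise ValueError(f"{record.gene_id} is not a KZFP; no zinc-finger grade")
    if record.znf_divergence_taxon is None:
        raise ValueError(f"{record.gene_id}: missing zinc-finger divergence taxon")
    return scheme.grade_of(record.znf_divergence_taxon)


def assign_domain_ages(
    presence_by_family: dict[str, set[str]], tree: SpeciesTree
) -> dict[str, str]:
    """Vectorised :func:`domain_age` over a family -> species-presence map."""
    return {fam: domain_age(sp, tree) for fam, sp in sorted(presence_by_family.items())}
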