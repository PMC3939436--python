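"""Ortholog-group assignment of metagenomic genes.

Protein percent identity over the aligned region is converted to an
evolutionary distance with Kimura's correction for protein sequences,

    d = -ln(1 - p - 0.2 p^2),   p = 1 - identity,

which saturates at p ~ 0.8541 (the positive root of 1 - p - 0.2 p^2 = 0).
Homology pairs are unidirectional best hits under joint E-value and bit-score
thresholds, ranked by distance; each metagenomic gene then joins the ortholog
group of its best reference hit, and genes without a passing hit form
singleton groups. This nearest-group assignment is a deliberate simplification
of full tree-based ortholog-table merging: the downstream statistics consume
only group membership and coverage.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import pandas as pd

from .errors import DistanceSaturationError, InputError
from .synthetic import ReferenceCatalog

#: positive root of 1 - p - 0.2 p^2 = 0 (distance undefined at or beyond it)
P_SATURATION = (math.sqrt(1.8) - 1.0) / 0.4

OUTFMT6_COLUMNS = ["qseqid", "sseqid", "pident", "length", "mismatch",
                   "gapopen", "qstart", "qend", "sstart", "send",
                   "evalue", "bitscore"]


def identity_to_distance(identity: float) -> float:
    """Kimura-corrected protein distance (substitutions/site) from fractional
    identity; 0 at identity 1, monotone increasing as identity falls."""
    if not 0.0 <= identity <= 1.0:
        raise InputError("identity must be within [0, 1]")
    p = 1.0 - identity
    arg = 1.0 - p - 0.2 * p * p
    if arg <= 0.0 or p >= P_SATURATION:
        raise DistanceSaturationError(
            f"distance undefined at identity {identity:.4f} "
            f"(p >= {P_SATURATION:.4f})")
    return -math.log(arg)


@dataclass(frozen=True)
class HomologyHit:
    """One protein-vs-protein alignment row (BLAST outfmt-6 dialect)."""

    query_id: str
    subject_id: str
    identity: float  # fraction in [0, 1]
    align_len: int
    e_value: float
    bit_score: float
    q_start: int = 0
    q_end: int = 0
    s_start: int = 0
    s_end: int = 0

    def __post_init__(self) -> None:
        if not 0.0 <= self.identity <= 1.0:
            raise InputError("identity must be within [0, 1]")
        if self.align_len < 1:
            raise InputError("align_len must be >= 1")

    @property
    def distance(self) -> float:
        """Kimura distance; +inf when saturated (hit unusable for ranking)."""
        try:
            return identity_to_distance(self.identity)
        except DistanceSaturationError:
            return math.inf


def read_hit_table(path) -> list[HomologyHit]:
    """Read a 12-column tab-separated hit table (pident as a percentage)."""
    df = pd.read_csv(path, sep="\t", names=OUTFMT6_COLUMNS, comment="#")
    return [HomologyHit(query_id=str(r.qseqid), subject_id=str(r.sseqid),
                        identity=float(r.pident) / 100.0,
                        align_len=int(r.length), e_value=float(r.evalue),
                        bit_score=float(r.bitscore),
                        q_start=int(r.qstart), q_end=int(r.qend),
                        s_start=int(r.sstart), s_end=int(r.send))
            for r in df.itertuples()]


def write_hit_table(hits, path) -> None:
    with open(path, "w") as fh:
        for h in hits:
            fh.write("\t".join(map(str, [
                h.query_id, h.subject_id, round(h.identity * 100.0, 2),
                h.align_len, 0, 0, h.q_start, h.q_end, h.s_start, h.s_end,
                h.e_value, h.bit_score])) + "\n")


def find_homology_pairs(hits, e_max: float = 1e-3,
                        score_min: float = 60.0) -> list[HomologyHit]:
    """Unidirectional best hits: per query, keep hits with E <= e_max AND
    bit score >= score_min, then the single minimum-distance hit.

    Ties at equal distance break to the higher bit score, then the
    lexicographically smaller subject id. Hits at saturated identity (no
    finite distance) are dropped.
    """
    best: dict[str, HomologyHit] = {}
    for h in hits:
        if h.e_value > e_max or h.bit_score < score_min:
            continue
        d = h.distance
        if math.isinf(d):
            continue
        cur = best.get(h.query_id)
        if cur is None or (d, -h.bit_score, h.subject_id) < (
                cur.distance, -cur.bit_score, cur.subject_id):
            best[h.query_id] = h
    return [best[q] for q in sorted(best)]


@dataclass
class GroupEntry:
    reference_members: list[tuple[str, str, int]] = field(default_factory=list)
    #: metagenomic gene id -> Kimura distance to its best reference hit
    #: (nan for singleton groups)
    metagenome_members: dict[str, float] = field(default_factory=dict)


class MergedOrthologTable:
    """Ortholog groups holding reference genes plus assigned metagenomic
    genes. Reference membership is fixed at load; metagenomic genes are added
    by :func:`assign_to_groups` and each belongs to exactly one group."""

    def __init__(self) -> None:
        self.groups: dict[str, GroupEntry] = {}
        self._ref_gene_to_group: dict[str, str] = {}
        self._mg_gene_to_group: dict[str, str] = {}

    # -- construction -----------------------------------------------------

    @classmethod
    def from_catalog(cls, catalog: ReferenceCatalog) -> "MergedOrthologTable":
        table = cls()
        for row in catalog.to_table().itertuples():
            table._add_reference(row.group_id, row.genome_id, row.gene_id,
                                 int(row.aa_length))
        return table

    @classmethod
    def read(cls, path) -> "MergedOrthologTable":
        table = cls()
        df = pd.read_csv(path, sep="\t")
        for row in df.itertuples():
            table._add_reference(row.group_id, row.genome_id, row.gene_id,
                                 int(row.aa_length))
        return table

    def _add_reference(self, group_id: str, genome_id: str, gene_id: str,
                       aa_length: int) -> None:
        entry = self.groups.setdefault(group_id, GroupEntry())
        entry.reference_members.append((genome_id, gene_id, aa_length))
        self._ref_gene_to_group[gene_id] = group_id

    # -- queries ----------------------------------------------------------

    def group_of_reference_gene(self, gene_id: str) -> str:
        try:
            return self._ref_gene_to_group[gene_id]
        except KeyError:
            raise InputError(f"unknown reference gene id: {gene_id}") from None

    def group_of_metagenome_gene(self, gene_id: str) -> str | None:
        return self._mg_gene_to_group.get(gene_id)

    def mean_reference_length_nt(self, group_id: str) -> float | None:
        entry = self.groups.get(group_id)
        if entry is None or not entry.reference_members:
            return None
        total = sum(aa for _, _, aa in entry.reference_members)
        return 3.0 * total / len(entry.reference_members)

    def reference_gene_count(self, group_id: str) -> int:
        entry = self.groups.get(group_id)
        return len(entry.reference_members) if entry else 0

    @property
    def n_reference_genes(self) -> int:
        return len(self._ref_gene_to_group)

    def add_metagenome_member(self, group_id: str, gene_id: str,
                              distance: float) -> None:
        if gene_id in self._mg_gene_to_group:
            raise InputError(f"gene {gene_id} already assigned")
        self.groups.setdefault(group_id, GroupEntry())
        self.groups[group_id].metagenome_members[gene_id] = distance
        self._mg_gene_to_group[gene_id] = group_id

    def write(self, path) -> None:
        rows = []
        for gid in sorted(self.groups):
            entry = self.groups[gid]
            for genome_id, gene_id, aa in entry.reference_members:
                rows.append((gid, "reference", genome_id, gene_id, aa, ""))
            for gene_id, dist in sorted(entry.metagenome_members.items()):
                rows.append((gid, "metagenome", "", gene_id, "", dist))
        pd.DataFrame(rows, columns=["group_id", "origin", "genome_id",
                                    "gene_id", "aa_length", "distance"]
                     ).to_csv(path, sep="\t", index=False)


def assign_to_groups(gene_ids, hits, table: MergedOrthologTable,
                     e_max: float = 1e-3, score_min: float = 60.0,
                     singleton_prefix: str = "MG_"
                     ) -> MergedOrthologTable:
    """Assign each metagenomic gene to the ortholog group of its best
    reference hit; genes with no passing hit become singleton groups
    (``MG_<gene_id>``), the "groups without genes from the reference
    genomes". Mutates and returns ``table``."""
    pairs = {h.query_id: h for h in find_homology_pairs(hits, e_max, score_min)}
    for gene_id in gene_ids:
        hit = pairs.get(gene_id)
        if hit is None:
            table.add_metagenome_member(singleton_prefix + gene_id, gene_id,
                                        float("nan"))
        else:
            group = table.group_of_reference_gene(hit.subject_id)
            table.add_metagenome_member(group, gene_id, hit.distance)
    return table
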