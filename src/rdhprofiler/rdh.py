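"""Reductive-dehalogenase (rdhA) homolog screening.

Covers the annotation side of the analysis: choosing rdhA ortholog groups
from domain annotations, sequence screens for the twin-arginine (TAT) export
signal and the twin four-cysteine Fe-S binding motifs, a hydropathy-based
transmembrane helix counter, the gene-neighborhood screen for the small
hydrophobic rdhB membrane anchor, support-value-aware pruning and cluster
extraction on Newick trees, and top-hit classification of external reads
against a cluster-labeled rdhA set.

Motif detectors are regular-expression stand-ins for profile-HMM domain
models: the default patterns are conventional consensus patterns
([ST]RR-x-[FGAVML] for TAT; C-x2-C-x2-C-x3-C ferredoxin spacing for Fe-S)
and are overridable. Transmembrane helices are counted with a Kyte-Doolittle
sliding window (19 aa, mean hydropathy >= 1.6, overlapping passing windows
merged), a heuristic stand-in for full HMM topology prediction — the only
quantity consumed downstream is the 2-3 helix count criterion.
"""

from __future__ import annotations

import re
import warnings
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import dendropy
import numpy as np
import pandas as pd

from .errors import InputError
from .orthologs import HomologyHit, MergedOrthologTable

# ---------------------------------------------------------------------------
# domain annotations


@dataclass(frozen=True)
class DomainAnnotation:
    """One domain-model hit for a gene (tabular domain-scan output)."""

    gene_id: str
    model_id: str
    bit_score: float
    passes: bool  # noise-cutoff bit score threshold


def read_domain_annotations(path) -> list[DomainAnnotation]:
    df = pd.read_csv(path, sep="\t")
    return [DomainAnnotation(str(r.gene_id), str(r.model_id),
                             float(r.score), bool(r.passes))
            for r in df.itertuples()]


def write_domain_annotations(annotations, path) -> None:
    pd.DataFrame([(a.gene_id, a.model_id, a.bit_score, a.passes)
                  for a in annotations],
                 columns=["gene_id", "model_id", "score", "passes"]
                 ).to_csv(path, sep="\t", index=False)


def select_rdh_groups(table: MergedOrthologTable,
                      annotations: Iterable[DomainAnnotation],
                      rdha_model: str = "RdhA") -> set[str]:
    """Groups in which half or more of the member genes carry a passing
    RdhA-family domain annotation (boundary inclusive)."""
    positive = {a.gene_id for a in annotations
                if a.model_id == rdha_model and a.passes}
    selected = set()
    for group_id, entry in table.groups.items():
        members = ([gid for _, gid, _ in entry.reference_members]
                   + list(entry.metagenome_members))
        if not members:
            continue
        hits = sum(1 for g in members if g in positive)
        if 2 * hits >= len(members):
            selected.add(group_id)
    return selected


# ---------------------------------------------------------------------------
# motif detectors

TAT_PATTERN = r"[ST]RR.[FGAVML]"

PRESENT = "present"
ABSENT = "absent"
NOT_ASSESSABLE = "not_assessable"


def detect_tat_motif(protein: str, has_start: bool, n_region: int = 50,
                     pattern: str = TAT_PATTERN) -> str:
    """Twin-arginine export signal within the N-terminal region.

    Genes without a start codon cannot be assessed (the N-terminus is
    missing) and return ``not_assessable``.
    """
    if not protein:
        raise InputError("empty protein sequence")
    if not has_start:
        return NOT_ASSESSABLE
    return PRESENT if re.search(pattern, protein[:n_region]) else ABSENT


def fes_pattern(spacings: Sequence[int] = (2, 2, 3)) -> str:
    """Regex for a four-cysteine ferredoxin-type cluster-binding block."""
    a, b, c = spacings
    return f"C.{{{a}}}C.{{{b}}}C.{{{c}}}C"


def detect_fes_motifs(protein: str,
                      spacings: Sequence[int] = (2, 2, 3)) -> int:
    """Count non-overlapping four-cysteine blocks; a typical RdhA carries
    two (the twin Fe-S motif means count >= 2)."""
    if not protein:
        raise InputError("empty protein sequence")
    return len(re.findall(fes_pattern(spacings), protein))


def has_twin_fes(protein: str, spacings: Sequence[int] = (2, 2, 3)) -> bool:
    return detect_fes_motifs(protein, spacings) >= 2


# Kyte-Doolittle hydropathy; unknown residues (X) score 0 so masked runs
# can never reach the helix threshold
_KD = {"A": 1.8, "R": -4.5, "N": -3.5, "D": -3.5, "C": 2.5, "Q": -3.5,
       "E": -3.5, "G": -0.4, "H": -3.2, "I": 4.5, "L": 3.8, "K": -3.9,
       "M": 1.9, "F": 2.8, "P": -1.6, "S": -0.8, "T": -0.7, "W": -0.9,
       "Y": -1.3, "V": 4.2}


def count_tm_helices(protein: str, window: int = 19,
                     threshold: float = 1.6) -> int:
    """Number of disjoint hydrophobic stretches: windows of mean
    Kyte-Doolittle hydropathy >= threshold, with overlapping passing windows
    merged into a single helix. Sequences shorter than the window give 0."""
    if len(protein) < window:
        return 0
    h = np.array([_KD.get(a, 0.0) for a in protein])
    means = np.convolve(h, np.ones(window) / window, mode="valid")
    passing = np.flatnonzero(means >= threshold)
    if passing.size == 0:
        return 0
    # windows starting at i and j overlap iff |i - j| < window
    breaks = np.flatnonzero(np.diff(passing) >= window)
    return int(breaks.size + 1)


# ---------------------------------------------------------------------------
# rdhB gene-neighborhood screen


def _interval_gap(a: tuple[int, int], b: tuple[int, int]) -> int:
    """Distance between nearest boundaries; 0 when overlapping/abutting."""
    return max(a[0], b[0]) - min(a[1], b[1]) if (
        a[1] <= b[0] or b[1] <= a[0]) else 0


def screen_rdhB_neighbors(gene_calls: pd.DataFrame,
                          rdhA_loci: pd.DataFrame,
                          proteins: Mapping[str, str] | None = None,
                          contig_lengths: Mapping[str, int] | None = None,
                          window: int = 2000, max_len: int = 150,
                          tm_range: tuple[int, int] = (2, 3),
                          tm_window: int = 19, tm_threshold: float = 1.6
                          ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Candidate rdhB companions near rdhA loci.

    A candidate gene lies within ``window`` bp of an rdhA interval boundary
    (strand-agnostic, nearest boundaries), encodes < ``max_len`` aa, and has
    a transmembrane helix count within ``tm_range``. Genes truncated at a
    contig end (when ``contig_lengths`` is given) are returned separately as
    unassessable-length flanking homologs. Protein sequences come from
    ``proteins`` (gene_id -> aa); aa length falls back to interval length/3.

    Returns ``(candidates, unassessable)`` DataFrames with columns
    (gene_id, rdhA_id, contig, distance_bp, aa_len, n_tm).
    """
    rdha_ids = set(rdhA_loci["gene_id"])
    cand_rows, trunc_rows = [], []
    for a in rdhA_loci.itertuples():
        near = gene_calls[(gene_calls["contig"] == a.contig)
                          & (~gene_calls["gene_id"].isin(rdha_ids))]
        for g in near.itertuples():
            gap = _interval_gap((a.start, a.end), (g.start, g.end))
            if gap > window:
                continue
            truncated = False
            if contig_lengths is not None:
                clen = contig_lengths.get(g.contig)
                if clen is not None and (g.start == 0 or g.end == clen):
                    truncated = True
            prot = proteins.get(g.gene_id) if proteins else None
            aa_len = len(prot) if prot else (g.end - g.start) // 3
            n_tm = (count_tm_helices(prot, tm_window, tm_threshold)
                    if prot else 0)
            row = (g.gene_id, a.gene_id, g.contig, gap, aa_len, n_tm)
            if truncated:
                trunc_rows.append(row)
            elif aa_len < max_len and tm_range[0] <= n_tm <= tm_range[1]:
                cand_rows.append(row)
    cols = ["gene_id", "rdhA_id", "contig", "distance_bp", "aa_len", "n_tm"]
    return (pd.DataFrame(cand_rows, columns=cols),
            pd.DataFrame(trunc_rows, columns=cols))


# ---------------------------------------------------------------------------
# support trees


def load_support_tree(newick: str) -> dendropy.Tree:
    """Parse a Newick string/path with internal node labels as support
    values in [0, 1]."""
    src = {"path": newick} if str(newick).endswith((".nwk", ".tree", ".nex")) \
        else {"data": newick}
    tree = dendropy.Tree.get(schema="newick", **src,
                             suppress_internal_node_taxa=True)
    return tree


def node_support(node: dendropy.Node) -> float:
    """Support of an internal node; the root (no parent edge) counts 1.0;
    unlabeled non-root nodes count 0.0 (never 'supported' by default)."""
    if node.parent_node is None:
        return 1.0
    if node.label is None:
        return 0.0
    return float(node.label)


def prune_tree_by_domain(tree: dendropy.Tree,
                         positive_leaves: Iterable[str]) -> dendropy.Tree:
    """Remove maximal all-negative clades (internal nodes whose leaves all
    lack the domain). Elimination is per-subtree, not per-leaf: a lone
    negative leaf inside a positive clade is retained. Idempotent. A tree
    with no positive leaf at all yields an empty tree with a warning."""
    positive = set(positive_leaves)
    tree = tree.clone(depth=1)
    all_leaves = [l.taxon.label for l in tree.leaf_node_iter()]
    if not any(l in positive for l in all_leaves):
        warnings.warn("no domain-positive leaves; pruned tree is empty")
        empty = dendropy.Tree()
        return empty

    def clade_negative(node) -> bool:
        return all(l.taxon.label not in positive
                   for l in node.leaf_iter())

    to_remove = []
    stack = [tree.seed_node]
    while stack:
        node = stack.pop()
        for child in node.child_nodes():
            if child.is_leaf():
                continue
            if clade_negative(child):
                to_remove.append(child)  # maximal: do not descend
            else:
                stack.append(child)
    for node in to_remove:
        node.parent_node.remove_child(node)
    tree.suppress_unifurcations()
    return tree


def extract_supported_clusters(tree: dendropy.Tree,
                               seeds: Mapping[str, Sequence[str]],
                               support_min: float = 0.90) -> pd.DataFrame:
    """Name clusters from seed leaves: each cluster is the smallest clade
    containing its seeds; every leaf of the clade joins the cluster, with
    status ``supported`` iff clade support >= ``support_min`` (inclusive),
    else ``tentative`` with the support recorded. Where clades nest, leaves
    keep the most specific (smallest) cluster.

    Returns a DataFrame (gene_id, cluster, support, status).
    """
    labels = {l.taxon.label for l in tree.leaf_node_iter()}
    assignment: dict[str, tuple[str, float, str, int]] = {}
    for cluster, seed_leaves in seeds.items():
        missing = [s for s in seed_leaves if s not in labels]
        if missing:
            raise InputError(f"seed leaves absent from tree: {missing}")
        mrca = tree.mrca(taxon_labels=list(seed_leaves))
        support = node_support(mrca)
        status = "supported" if support >= support_min else "tentative"
        clade_leaves = [l.taxon.label for l in mrca.leaf_iter()]
        size = len(clade_leaves)
        for leaf in clade_leaves:
            prev = assignment.get(leaf)
            if prev is None or size < prev[3]:
                assignment[leaf] = (cluster, support, status, size)
    rows = [(leaf, c, s, st) for leaf, (c, s, st, _)
            in sorted(assignment.items())]
    return pd.DataFrame(rows, columns=["gene_id", "cluster", "support",
                                       "status"])


UNCLASSIFIED = "unclassified"


def classify_by_top_hit(read_hits: Iterable[HomologyHit],
                        assignments: Mapping[str, str],
                        e_max: float = 1e-3, score_min: float = 60.0,
                        reads: Iterable[str] | None = None
                        ) -> dict[str, str]:
    """Label each read with the cluster of its best-scoring rdhA subject.

    Ties at equal bit score break to higher identity, then lexicographically
    smaller subject id. Reads with no passing hit are ``unclassified``
    (listed explicitly when the read universe ``reads`` is given).
    """
    best: dict[str, HomologyHit] = {}
    for h in read_hits:
        if h.e_value > e_max or h.bit_score < score_min:
            continue
        if h.subject_id not in assignments:
            continue
        cur = best.get(h.query_id)
        if cur is None or (-h.bit_score, -h.identity, h.subject_id) < (
                -cur.bit_score, -cur.identity, cur.subject_id):
            best[h.query_id] = h
    labels = {q: assignments[h.subject_id] for q, h in best.items()}
    if reads is not None:
        for r in reads:
            labels.setdefault(r, UNCLASSIFIED)
    return labels
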