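"""16S rRNA fragment acceptance, coverage and taxon frequency tables.

Fragment acceptance mirrors the clone-library rules: an rRNA hit counts only
when the aligned region is at least 100 bp AND either the match runs to an
end of the query sequence or the reference gene is matched over its full
length (an internal partial match against a longer reference is rejected —
it would imply a chimeric or spurious alignment). Reads of the same clone
whose accepted fragments overlap on the same reference are counted once.
Taxonomy is transferred from the matched reference's taxonomy path
(classification itself is external); frequencies are tabulated per pool at a
chosen rank.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Iterable

import pandas as pd

from .errors import InputError


@dataclass(frozen=True)
class RnaFragmentHit:
    """One rRNA alignment of a read/contig against a reference rRNA gene.

    Intervals are 0-based half-open on the query (length ``q_len``) and on
    the subject (length ``subject_len``); ``taxonomy`` is a
    semicolon-separated path for the subject.
    """

    query_id: str
    clone_id: str
    subject_id: str
    subject_len: int
    align_len: int
    bit_score: float
    q_start: int
    q_end: int
    q_len: int
    s_start: int
    s_end: int
    taxonomy: str = ""
    pool: str = "pool1"

    def __post_init__(self) -> None:
        if self.align_len < 1:
            raise InputError("alignment length must be >= 1")
        if not (0 <= self.q_start < self.q_end <= self.q_len):
            raise InputError("query interval out of bounds")
        if not (0 <= self.s_start < self.s_end <= self.subject_len):
            raise InputError("subject interval out of bounds")


def best_hit_per_query(hits: Iterable[RnaFragmentHit]) -> list[RnaFragmentHit]:
    """Resolve multiple subjects per query (including LSU/SSU conflicts on
    the same region) by keeping the highest-scoring hit per query."""
    best: dict[str, RnaFragmentHit] = {}
    for h in hits:
        cur = best.get(h.query_id)
        if cur is None or (-h.bit_score, h.subject_id) < (
                -cur.bit_score, cur.subject_id):
            best[h.query_id] = h
    return [best[q] for q in sorted(best)]


def _accept(h: RnaFragmentHit, min_len: int, end_tol: int) -> bool:
    if h.align_len < min_len:
        return False
    reaches_end = h.q_start <= end_tol or h.q_end >= h.q_len - end_tol
    full_subject = h.s_start == 0 and h.s_end == h.subject_len
    return reaches_end or full_subject


def filter_rrna_fragments(hits: Iterable[RnaFragmentHit],
                          min_len: int = 100,
                          end_tol: int = 0) -> list[RnaFragmentHit]:
    """Accepted rRNA fragments after the length/end rules and clone-level
    deduplication.

    Overlapping accepted fragments from the two reads of one clone on the
    same subject merge into a single fragment spanning their union of the
    subject interval (counted once).
    """
    accepted = [h for h in hits if _accept(h, min_len, end_tol)]
    by_clone: dict[tuple[str, str], list[RnaFragmentHit]] = {}
    for h in accepted:
        by_clone.setdefault((h.clone_id, h.subject_id), []).append(h)
    out: list[RnaFragmentHit] = []
    for key in sorted(by_clone):
        group = sorted(by_clone[key], key=lambda h: (h.s_start, h.s_end))
        merged: list[RnaFragmentHit] = []
        for h in group:
            if merged and h.s_start < merged[-1].s_end:
                prev = merged[-1]
                s_end = max(prev.s_end, h.s_end)
                merged[-1] = replace(prev, s_end=s_end,
                                     align_len=s_end - prev.s_start,
                                     bit_score=max(prev.bit_score,
                                                   h.bit_score))
            else:
                merged.append(h)
        out.extend(merged)
    return out


def rrna_coverage_value(fragments: Iterable[RnaFragmentHit],
                        subject_len: int) -> float:
    """Total accepted fragment length over the reference gene length."""
    if subject_len <= 0:
        raise InputError("subject_len must be > 0")
    return sum(f.align_len for f in fragments) / subject_len


def taxon_frequency_table(fragments: Iterable[RnaFragmentHit],
                          rank: int = 1,
                          unclassified: str = "unclassified"
                          ) -> pd.DataFrame:
    """Per-pool taxon frequency fractions at path index ``rank``
    (0 = domain, 1 = phylum, ...). Fragments whose path does not resolve at
    the rank are binned as unclassified; fractions sum to 1 per pool.

    Returns a DataFrame (pool, taxon, fraction).
    """
    rows = []
    for f in fragments:
        parts = [p for p in f.taxonomy.split(";") if p]
        taxon = parts[rank] if rank < len(parts) else unclassified
        rows.append((f.pool, taxon))
    if not rows:
        return pd.DataFrame(columns=["pool", "taxon", "fraction"])
    df = pd.DataFrame(rows, columns=["pool", "taxon"])
    counts = df.groupby(["pool", "taxon"]).size().rename("count").reset_index()
    counts["fraction"] = counts.groupby("pool")["count"].transform(
        lambda c: c / c.sum())
    return counts[["pool", "taxon", "fraction"]].sort_values(
        ["pool", "taxon"], ignore_index=True)
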