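"""Average-coverage-ratio computation (copies per genome-equivalent).

The central statistic: a gene's *average coverage* is the total number of
read nucleotides overlapping it divided by the expected length of its
ortholog group (the mean nucleotide length of the group's reference members).
Dividing by the mean average coverage of universally conserved single-copy
marker genes normalizes out sequencing depth, giving the *average coverage
ratio* — the estimated number of copies of the gene per genome-equivalent of
community DNA. Two reads of the same clone that overlap on one contig are
counted once (their union interval), since they sequence the same insert.
"""

from __future__ import annotations

from decimal import ROUND_HALF_UP, Decimal
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .errors import ConfigurationError, InputError, NormalizationError
from .synthetic import PLACEMENT_COLUMNS, ReferenceCatalog
from .orthologs import MergedOrthologTable


# ---------------------------------------------------------------------------
# clone deduplication


def dedup_clone_overlap(placements: pd.DataFrame) -> pd.DataFrame:
    """Merge a clone's reads into one interval where they overlap on a single
    contig; reads on different contigs, or non-overlapping mates, are kept
    as-is. Total counted nucleotides never increase."""
    if placements.empty:
        return placements.copy()
    if (placements["start"] >= placements["end"]).any():
        raise InputError("placement intervals must satisfy start < end")
    rows = []
    for (clone_id, contig_id), grp in placements.groupby(
            ["clone_id", "contig_id"], sort=True):
        ivs = sorted(zip(grp["start"], grp["end"], grp["read_id"]))
        merged: list[list] = []
        for s, e, rid in ivs:
            if merged and s < merged[-1][1]:  # strict overlap, not abutment
                merged[-1][1] = max(merged[-1][1], e)
                merged[-1][2] = merged[-1][2] + "+" + rid
            else:
                merged.append([s, e, rid])
        for s, e, rid in merged:
            rows.append((clone_id, rid, contig_id, s, e))
    return pd.DataFrame(rows, columns=PLACEMENT_COLUMNS)


# ---------------------------------------------------------------------------
# expected lengths and per-gene coverage


def expected_gene_length(group_id: str,
                         source: ReferenceCatalog | MergedOrthologTable
                         ) -> float:
    """Mean nucleotide length of the group's reference members."""
    if isinstance(source, MergedOrthologTable):
        length = source.mean_reference_length_nt(group_id)
        if length is None:
            raise InputError(f"group {group_id} has no reference members")
        return length
    return source.mean_reference_length_nt(group_id)


def average_coverage(gene_interval: tuple[str, int, int],
                     placements: pd.DataFrame, expected_len: float) -> float:
    """Sum of placement overlaps with the gene (nt) / expected length."""
    if expected_len <= 0:
        raise InputError("expected_len must be > 0")
    contig, gs, ge = gene_interval
    if placements.empty:
        return 0.0
    on = placements[placements["contig_id"] == contig]
    if on.empty:
        return 0.0
    ov = (np.minimum(on["end"].to_numpy(), ge)
          - np.maximum(on["start"].to_numpy(), gs)).clip(min=0)
    return float(ov.sum()) / expected_len


# ---------------------------------------------------------------------------
# universal single-copy marker selection


def select_universal_single_copy(catalog: ReferenceCatalog,
                                 frac: float = 0.95,
                                 copy_max: float = 1.2) -> set[str]:
    """Groups present (copy >= 1) in >= ``frac`` of complete archaeal genomes
    AND >= ``frac`` of complete bacterial genomes, with mean copy number
    < ``copy_max`` among complete genomes of each domain. Incomplete genomes
    are excluded from every denominator."""
    for domain in ("archaea", "bacteria"):
        if not any(g.complete and g.domain == domain for g in catalog.genomes):
            raise ConfigurationError(
                f"no complete {domain} genomes in the catalog")
    selected = set()
    for group in catalog.groups:
        ok = True
        for domain in ("archaea", "bacteria"):
            if catalog.presence_fraction(group, domain) < frac:
                ok = False
                break
            if catalog.mean_copy(group, domain=domain,
                                 complete_only=True) >= copy_max:
                ok = False
                break
        if ok:
            selected.add(group)
    return selected


# ---------------------------------------------------------------------------
# the ratio


def average_coverage_ratio(gene_coverage: float,
                           single_copy_coverages: Sequence[float]) -> float:
    """``gene_coverage`` / unweighted mean of the marker coverages."""
    if len(single_copy_coverages) == 0:
        raise NormalizationError("no single-copy marker coverages given")
    mean = float(np.mean(single_copy_coverages))
    if mean <= 0:
        raise NormalizationError("single-copy marker mean coverage is zero")
    return gene_coverage / mean


def format_ratio(value: float) -> str:
    """Printed precision for reports: two decimals below one, one decimal at
    one or above (e.g. 0.675 -> '0.68', 1.2105 -> '1.2')."""
    # round away float representation noise before half-up quantization
    d = Decimal(repr(round(float(value), 9)))
    q = Decimal("0.1") if abs(value) >= 1 else Decimal("0.01")
    return str(d.quantize(q, rounding=ROUND_HALF_UP))


# ---------------------------------------------------------------------------
# profile over a whole pool

COVERAGE_COLUMNS = ["pool", "group_id", "gene_id", "avg_coverage",
                    "avg_coverage_ratio", "length_fallback"]


def _overlap_nt_per_gene(gene_calls: pd.DataFrame,
                         placements: pd.DataFrame) -> np.ndarray:
    """Total overlapping nucleotides per gene-call row (vectorized per
    contig)."""
    out = np.zeros(len(gene_calls), dtype=float)
    if placements.empty or gene_calls.empty:
        return out
    by_contig = dict(tuple(placements.groupby("contig_id", sort=False)))
    for contig, idx in gene_calls.groupby("contig", sort=False).groups.items():
        on = by_contig.get(contig)
        if on is None:
            continue
        gs = gene_calls.loc[idx, "start"].to_numpy()[:, None]
        ge = gene_calls.loc[idx, "end"].to_numpy()[:, None]
        ps = on["start"].to_numpy()[None, :]
        pe = on["end"].to_numpy()[None, :]
        ov = np.clip(np.minimum(ge, pe) - np.maximum(gs, ps), 0, None)
        out[gene_calls.index.get_indexer(idx)] = ov.sum(axis=1)
    return out


def compute_coverage_profile(gene_calls: pd.DataFrame,
                             placements: pd.DataFrame,
                             table: MergedOrthologTable | ReferenceCatalog,
                             universal_groups: Iterable[str],
                             pool: str = "pool1", *,
                             group_column: str = "group_id",
                             dedup: bool = True) -> pd.DataFrame:
    """Per-gene average coverage and average coverage ratio for one pool.

    ``gene_calls`` must carry the ortholog group of each gene in
    ``group_column`` (either truth labels from the synthetic generator or
    the result of homology assignment). Groups with no reference members
    fall back to the observed gene-call length (``length_fallback=True``).
    The marker mean is the unweighted mean of per-group coverages over
    ``universal_groups``; each group's coverage is the sum of its member
    genes' coverages (equivalently total overlapping nt over expected
    length).
    """
    effective = dedup_clone_overlap(placements) if dedup else placements
    calls = gene_calls.reset_index(drop=True)
    nts = _overlap_nt_per_gene(calls, effective)

    expected: dict[str, float | None] = {}
    for group in calls[group_column].unique():
        if isinstance(table, MergedOrthologTable):
            expected[group] = table.mean_reference_length_nt(group)
        else:
            try:
                expected[group] = table.mean_reference_length_nt(group)
            except InputError:
                expected[group] = None

    rows = []
    for i, row in enumerate(calls.itertuples()):
        group = getattr(row, group_column)
        exp_len = expected[group]
        fallback = exp_len is None
        if fallback:
            exp_len = float(row.end - row.start)
        rows.append((pool, group, row.gene_id, nts[i] / exp_len, fallback))
    prof = pd.DataFrame(rows, columns=["pool", "group_id", "gene_id",
                                       "avg_coverage", "length_fallback"])

    universal = set(universal_groups)
    group_cov = prof.groupby("group_id")["avg_coverage"].sum()
    marker_cov = [group_cov.get(g, 0.0) for g in sorted(universal)]
    mean = float(np.mean(marker_cov)) if marker_cov else 0.0
    if mean <= 0:
        raise NormalizationError(
            "single-copy marker mean coverage is zero for pool " + pool)
    prof["avg_coverage_ratio"] = prof["avg_coverage"] / mean
    return prof[COVERAGE_COLUMNS]


def group_coverage(profile: pd.DataFrame) -> pd.DataFrame:
    """Collapse a per-gene profile to per-(pool, group) coverage sums."""
    agg = (profile.groupby(["pool", "group_id"], as_index=False)
           [["avg_coverage", "avg_coverage_ratio"]].sum())
    return agg


def single_copy_mean(profile: pd.DataFrame,
                     universal_groups: Iterable[str]) -> float:
    """Unweighted mean of per-group coverage over the selected markers."""
    cov = (profile[profile["group_id"].isin(set(universal_groups))]
           .groupby("group_id")["avg_coverage"].sum())
    missing = set(universal_groups) - set(cov.index)
    values = list(cov) + [0.0] * len(missing)
    if not values:
        raise NormalizationError("no marker groups given")
    return float(np.mean(values))
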