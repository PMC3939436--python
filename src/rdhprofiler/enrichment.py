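"""Overrepresentation statistics for ortholog groups (S/F scatter).

Each group gets two descriptive statistics:

* ``S`` — the sum over pools of the group's average coverage (an estimated
  count of metagenomic genes in the group);
* ``F`` — fold change: the group's copies per genome-equivalent in the
  metagenome divided by its copies per genome in the reference catalog.

Overrepresentation is tested with an upper-tail hypergeometric probability
(equivalent to a one-sided Fisher exact test): drawing k genes (the floored
total metagenomic gene count) from an urn of m genes labeled with group X and
n others, the p-value is P(X >= q) where q is the group's floored coverage
sum. p-values are adjusted with the Benjamini-Hochberg step-up FDR procedure
and groups with adjusted p strictly below alpha are flagged.

Urn convention (documented, configurable by passing counts directly): m
counts the group's reference genes plus its floored metagenomic gene count;
n is every other gene (reference and metagenome); k is the metagenome total.
"""

from __future__ import annotations

import math
from typing import Iterable, Mapping

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .errors import ParameterError, InputError
from .coverage import single_copy_mean
from .orthologs import MergedOrthologTable
from .synthetic import ReferenceCatalog

ENRICHMENT_COLUMNS = ["group_id", "S", "F", "q", "m", "n", "k",
                      "p_raw", "p_adj", "flagged"]


def compute_group_statistics(group_id: str, s_values: Mapping[str, float],
                             s_universal_mean: float,
                             reference_rate: float) -> tuple[float, float]:
    """(S, F) for one group.

    ``s_values`` maps group ids to coverage sums over pools;
    ``s_universal_mean`` is the mean S of the universal single-copy markers;
    ``reference_rate`` is the group's reference copies per genome. F is
    +inf (sentinel) for groups absent from the reference catalog.
    """
    s = float(s_values.get(group_id, 0.0))
    if reference_rate <= 0:
        return s, math.inf
    return s, (s / s_universal_mean) / reference_rate


def hypergeom_upper_tail(q: int, m: int, n: int, k: int) -> float:
    """P(X >= q) for X ~ Hypergeometric(m labeled, n unlabeled, k drawn)."""
    for name, v in (("q", q), ("m", m), ("n", n), ("k", k)):
        if not isinstance(v, (int, np.integer)):
            raise ParameterError(f"{name} must be an integer")
    if not (0 <= q <= k <= m + n and q <= m):
        raise ParameterError(
            f"invalid urn counts: q={q}, m={m}, n={n}, k={k}")
    return float(stats.hypergeom.sf(q - 1, m + n, m, k))


def bh_adjust(p_values: Iterable[float]) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, input order preserved."""
    p = np.asarray(list(p_values), dtype=float)
    if p.size == 0:
        return p
    if ((p < 0) | (p > 1)).any() or np.isnan(p).any():
        raise InputError("p-values must lie within [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def flag_overrepresented(records: pd.DataFrame,
                         alpha: float = 1e-4) -> pd.DataFrame:
    """Set ``flagged = (p_adj < alpha)`` (strict inequality)."""
    out = records.copy()
    out["flagged"] = out["p_adj"] < alpha
    return out


def enrichment_table(profiles: Iterable[pd.DataFrame],
                     table: MergedOrthologTable | ReferenceCatalog,
                     universal_groups: Iterable[str],
                     alpha: float = 1e-4) -> pd.DataFrame:
    """Build the per-group S/F/p table from per-pool coverage profiles.

    ``profiles`` are outputs of :func:`rdhprofiler.coverage
    .compute_coverage_profile` (one per pool). Groups whose coverage sum
    floors to zero stay in the testing family with q=0 (p_raw=1) so the
    multiple-testing correction is computed over the full set of groups.
    """
    profiles = list(profiles)
    universal = sorted(set(universal_groups))
    combined = pd.concat(profiles, ignore_index=True)
    s_values = combined.groupby("group_id")["avg_coverage"].sum().to_dict()

    # marker mean of S across pools: sum of per-pool marker means
    s_univ_mean = sum(single_copy_mean(p, universal) for p in profiles)

    if isinstance(table, MergedOrthologTable):
        ref_count = {g: table.reference_gene_count(g) for g in s_values}
        total_ref = table.n_reference_genes
        n_ref_genomes = len({genome for e in table.groups.values()
                             for genome, _, _ in e.reference_members})
    else:
        ref_count = {g: (table.reference_gene_count(g)
                         if g in table.groups else 0) for g in s_values}
        total_ref = int(table.copy_matrix.sum())
        n_ref_genomes = table.n_genomes

    q_by_group = {g: int(math.floor(s)) for g, s in s_values.items()}
    k = sum(q_by_group.values())
    grand_total = total_ref + k

    rows = []
    for group in sorted(s_values):
        rate = ref_count[group] / n_ref_genomes if n_ref_genomes else 0.0
        s, f = compute_group_statistics(group, s_values, s_univ_mean, rate)
        q = q_by_group[group]
        m = ref_count[group] + q
        n = grand_total - m
        p = hypergeom_upper_tail(q, m, n, k) if k > 0 else 1.0
        rows.append((group, s, f, q, m, n, k, p))
    df = pd.DataFrame(rows, columns=["group_id", "S", "F", "q", "m", "n",
                                     "k", "p_raw"])
    df["p_adj"] = bh_adjust(df["p_raw"]) if len(df) else []
    return flag_overrepresented(df, alpha)[ENRICHMENT_COLUMNS]
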