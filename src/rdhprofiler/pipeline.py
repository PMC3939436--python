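"""End-to-end orchestration: synthetic community -> merged ortholog table ->
coverage -> enrichment -> rdhA screen -> 16S table, with a reproducibility
manifest.

Pools (sediment horizons, labeled by depth in meters below seafloor) are
processed independently through coverage normalization, then joined for the
cross-pool S/F statistics, mirroring per-sample sequencing-depth
normalization before community-wide testing. Every stage logs record counts
in and out so filter behavior is auditable, and the manifest snapshots the
configuration, input/output checksums and stage timings; rerunning with the
same config and seed reproduces every analytical table byte for byte.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import coverage as cov
from . import enrichment as enr
from . import rdh as rdhmod
from . import synthetic as syn
from . import taxonomy as tax
from .errors import ConfigurationError
from .orthologs import HomologyHit, MergedOrthologTable, assign_to_groups

log = logging.getLogger("rdhprofiler")

_PHYLA = ["Chloroflexi", "Proteobacteria", "Firmicutes", "Bacteroidetes",
          "Crenarchaeota", "Euryarchaeota"]


@dataclass
class PoolConfig:
    label: str
    mbsf: float
    n_clones: int


@dataclass
class PipelineConfig:
    """Every tunable of the synthetic end-to-end run."""

    seed: int = 0
    # community: the reference catalog must stay large relative to the
    # floored metagenomic gene count or the hypergeometric urn loses power
    n_genomes: int = 200
    n_groups: int = 80
    universal_fraction: float = 0.25
    target_rate_reference: float = 0.04
    target_rate_community: float = 0.5
    pools: list[PoolConfig] = field(default_factory=lambda: [
        PoolConfig("0.8mbsf", 0.8, 600),
        PoolConfig("5.1mbsf", 5.1, 600)])
    read_len_range: tuple[int, int] = (650, 800)
    insert_len_range: tuple[int, int] = (2000, 3000)
    # thresholds
    e_max: float = 1e-3
    score_min: float = 60.0
    frac: float = 0.95
    copy_max: float = 1.2
    alpha: float = 1e-4
    support_min: float = 0.90
    rdhb_window: int = 2000
    rdhb_max_len: int = 150
    tm_window: int = 19
    tm_threshold: float = 1.6
    tat_pattern: str = rdhmod.TAT_PATTERN
    # planted loci
    n_rdhA: int = 4
    with_rdhB: float = 1.0
    tat_prob: float = 0.0
    family: str = "smkt1"
    # synthetic homology noise
    hit_identity_mean: float = 0.88
    hit_identity_sd: float = 0.04
    # 16S
    n_rrna_fragments: int = 400

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["read_len_range"] = list(self.read_len_range)
        d["insert_len_range"] = list(self.insert_len_range)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        d["pools"] = [PoolConfig(**p) if isinstance(p, dict) else p
                      for p in d.get("pools", [])]
        for key in ("read_len_range", "insert_len_range"):
            if key in d:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=True)

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


# ---------------------------------------------------------------------------
# synthetic homology hits (stand-in for a BLASTP run against the reference)


def simulate_homology_hits(gene_calls: pd.DataFrame,
                           table: MergedOrthologTable, seed: int,
                           identity_mean: float = 0.88,
                           identity_sd: float = 0.04) -> list[HomologyHit]:
    """Give every metagenomic gene whose true group exists in the reference a
    strong hit to one of that group's members, plus a weaker off-group decoy
    hit; genes of groups absent from the reference get no hits."""
    rng = np.random.default_rng(seed)
    all_ref = [(gid, grp) for grp, e in table.groups.items()
               for _, gid, _ in e.reference_members]
    hits: list[HomologyHit] = []
    for row in gene_calls.itertuples():
        entry = table.groups.get(row.group_id)
        if entry is None or not entry.reference_members:
            continue
        members = entry.reference_members
        _, subject, aa = members[int(rng.integers(len(members)))]
        ident = float(np.clip(rng.normal(identity_mean, identity_sd),
                              0.60, 0.99))
        hits.append(HomologyHit(row.gene_id, subject, ident, aa,
                                e_value=1e-40, bit_score=2.0 * aa))
        decoy_gid, decoy_grp = all_ref[int(rng.integers(len(all_ref)))]
        if decoy_grp != row.group_id:
            hits.append(HomologyHit(row.gene_id, decoy_gid,
                                    float(rng.uniform(0.25, 0.45)), 150,
                                    e_value=5e-4, bit_score=65.0))
    return hits


def simulate_rrna_fragments(catalog, phylum_of: dict[str, str],
                            n_fragments: int, seed: int,
                            pool: str) -> list[tax.RnaFragmentHit]:
    """Fragments drawn from genomes by abundance; taxonomy follows the
    genome; geometry passes the acceptance rules (end-anchored, >=100 bp)."""
    rng = np.random.default_rng(seed)
    ab = np.array([g.relative_abundance for g in catalog.genomes])
    ab = ab / ab.sum()
    picks = rng.choice(catalog.n_genomes, size=n_fragments, p=ab)
    frags = []
    for i, gi in enumerate(picks):
        genome = catalog.genomes[gi]
        aln = int(rng.integers(300, 750))
        frags.append(tax.RnaFragmentHit(
            query_id=f"{pool}_r16s{i:05d}", clone_id=f"{pool}_cl16s{i:05d}",
            subject_id=f"ssu_{genome.id}", subject_len=1500,
            align_len=aln, bit_score=2.0 * aln,
            q_start=0, q_end=aln, q_len=700 if aln <= 700 else aln,
            s_start=100, s_end=100 + aln,
            taxonomy=f"{genome.domain.capitalize()};{phylum_of[genome.id]}",
            pool=pool))
    return frags


# ---------------------------------------------------------------------------
# the run


def _sha256(path: Path) -> str:
    h = hashlib.sha256()
    h.update(path.read_bytes())
    return h.hexdigest()


def _translate(contigs: dict[str, str], row) -> str:
    from Bio.Seq import Seq
    nt = contigs[row.contig][row.start:row.end]
    return str(Seq(nt).translate())


def run_pipeline(config: PipelineConfig, outdir) -> dict:
    """Run the synthetic end-to-end analysis; returns the manifest dict."""
    out = Path(outdir)
    out.mkdir(parents=True, exist_ok=True)
    t0 = time.time()
    timings: dict[str, float] = {}
    manifest: dict = {"config": config.to_dict()}

    # -- stage 1: reference + community -----------------------------------
    t = time.time()
    catalog = syn.generate_reference_catalog(
        config.n_genomes, config.n_groups, config.universal_fraction,
        config.target_rate_reference, config.seed)
    markers = cov.select_universal_single_copy(catalog, config.frac,
                                               config.copy_max)
    if not markers:
        raise ConfigurationError("no universal single-copy markers selected")
    community = syn.set_target_family_rate(
        catalog, config.target_rate_community, config.seed + 1)
    catalog.write_table(out / "reference_catalog.tsv")
    log.info("reference: %d genomes, %d groups, %d markers",
             catalog.n_genomes, len(catalog.groups), len(markers))
    timings["reference"] = time.time() - t

    # -- stage 2: per-pool metagenomes + assignment + coverage -------------
    table = MergedOrthologTable.from_catalog(catalog)
    profiles = []
    pool_data = {}
    for i, pool in enumerate(config.pools):
        t = time.time()
        contigs, reads, calls, placements, truth = syn.generate_metagenome(
            community, None, pool.n_clones, config.read_len_range,
            seed=config.seed + 10 + i,
            insert_len_range=config.insert_len_range, pool=pool.label)
        contigs, calls, planted = syn.plant_rdh_loci(
            contigs, calls, config.n_rdhA,
            syn.MotifConfig(tat_prob=config.tat_prob),
            with_rdhB=config.with_rdhB, seed=config.seed + 100 + i,
            family=config.family)
        calls = calls.copy()
        calls["gene_id"] = pool.label + ":" + calls["gene_id"]
        hits = simulate_homology_hits(calls, table,
                                      config.seed + 200 + i,
                                      config.hit_identity_mean,
                                      config.hit_identity_sd)
        assign_to_groups(calls["gene_id"], hits, table,
                         config.e_max, config.score_min)
        assigned = calls.assign(assigned_group=[
            table.group_of_metagenome_gene(g) for g in calls["gene_id"]])
        log.info("pool %s: %d clones, %d genes, %d hits",
                 pool.label, len(placements) // 2, len(calls), len(hits))
        profile = cov.compute_coverage_profile(
            assigned, placements, table, markers, pool.label,
            group_column="assigned_group")
        profiles.append(profile)
        pool_data[pool.label] = dict(contigs=contigs, calls=calls,
                                     placements=placements, truth=truth,
                                     planted=planted, profile=profile)
        timings[f"pool:{pool.label}"] = time.time() - t
    pd.concat(profiles, ignore_index=True).to_csv(
        out / "coverage.tsv", sep="\t", index=False)

    # -- stage 3: enrichment ----------------------------------------------
    t = time.time()
    enrich = enr.enrichment_table(profiles, table, markers, config.alpha)
    enrich.to_csv(out / "enrichment.tsv", sep="\t", index=False)
    enrich[["group_id", "S", "F", "flagged"]].to_csv(
        out / "sf_scatter.tsv", sep="\t", index=False)
    log.info("enrichment: %d groups, %d flagged",
             len(enrich), int(enrich["flagged"].sum()))
    timings["enrichment"] = time.time() - t

    # -- stage 4: depth profile for the target family ----------------------
    t = time.time()
    rows = []
    for pool in config.pools:
        profile = pool_data[pool.label]["profile"]
        ratio = float(profile.loc[profile["group_id"] == catalog.target_group,
                                  "avg_coverage_ratio"].sum())
        rows.append((pool.label, pool.mbsf, catalog.target_group, ratio,
                     cov.format_ratio(ratio)))
    depth_profile = pd.DataFrame(rows, columns=[
        "pool", "mbsf", "group_id", "avg_coverage_ratio", "printed"])
    depth_profile.to_csv(out / "depth_profile.tsv", sep="\t", index=False)
    timings["depth_profile"] = time.time() - t

    # -- stage 5: rdhA screen ---------------------------------------------
    t = time.time()
    screen_rows = []
    cluster_depth_rows = []
    for pool in config.pools:
        data = pool_data[pool.label]
        planted = data["planted"]
        contigs = data["contigs"]
        calls = data["calls"]
        loci = pd.DataFrame(planted.planted_motifs)
        if loci.empty:
            continue
        loci["gene_id"] = pool.label + ":" + loci["gene_id"]
        proteins = {}
        for row in calls.itertuples():
            if row.gene_id.split(":", 1)[1].startswith(config.family):
                proteins[row.gene_id] = _translate(contigs, row)
        n = len(loci)
        n_tat = sum(rdhmod.detect_tat_motif(
            proteins[g], True, pattern=config.tat_pattern) == rdhmod.PRESENT
            for g in loci["gene_id"])
        n_fes = sum(rdhmod.has_twin_fes(proteins[g]) for g in loci["gene_id"])
        contig_lengths = {c: len(s) for c, s in contigs.items()}
        cands, trunc = rdhmod.screen_rdhB_neighbors(
            calls, loci, proteins, contig_lengths,
            config.rdhb_window, config.rdhb_max_len,
            tm_window=config.tm_window, tm_threshold=config.tm_threshold)
        screen_rows.append((pool.label, config.family, n, n, n_fes, n_tat,
                            len(cands), len(trunc)))
        # cluster-by-depth: coverage ratio of the planted family's genes
        profile = data["profile"]
        fam_ratio = float(profile.loc[
            profile["gene_id"].isin(set(loci["gene_id"])),
            "avg_coverage_ratio"].sum())
        cluster_depth_rows.append((config.family, pool.label, pool.mbsf,
                                   fam_ratio))
    screen = pd.DataFrame(screen_rows, columns=[
        "pool", "cluster", "n_genes", "rdh_domain", "twin_fes", "tat",
        "adjacent_rdhB", "unassessable_rdhB"])
    screen.to_csv(out / "rdh_screen.tsv", sep="\t", index=False)
    cluster_depth = pd.DataFrame(cluster_depth_rows, columns=[
        "cluster", "pool", "mbsf", "avg_coverage_ratio"])
    cluster_depth.to_csv(out / "cluster_by_depth.tsv", sep="\t", index=False)
    timings["rdh_screen"] = time.time() - t

    # -- stage 6: 16S taxonomy --------------------------------------------
    t = time.time()
    phylum_of = {g.id: _PHYLA[i % len(_PHYLA)]
                 for i, g in enumerate(catalog.genomes)}
    frags: list[tax.RnaFragmentHit] = []
    for i, pool in enumerate(config.pools):
        raw = simulate_rrna_fragments(community, phylum_of,
                                      config.n_rrna_fragments,
                                      config.seed + 300 + i, pool.label)
        frags.extend(tax.filter_rrna_fragments(raw))
    taxa = tax.taxon_frequency_table(frags, rank=1)
    taxa.to_csv(out / "taxon_frequency.tsv", sep="\t", index=False)
    timings["taxonomy"] = time.time() - t

    # -- manifest ----------------------------------------------------------
    import rdhprofiler
    outputs = sorted(p.name for p in out.glob("*.tsv"))
    manifest.update({
        "outputs": {name: _sha256(out / name) for name in outputs},
        "timings_s": {k: round(v, 3) for k, v in timings.items()},
        "total_s": round(time.time() - t0, 3),
        "versions": {"rdhprofiler": rdhprofiler.__version__,
                     "numpy": np.__version__, "pandas": pd.__version__},
        "markers": sorted(markers),
        "n_flagged": int(enrich["flagged"].sum()),
    })
    with open(out / "manifest.json", "w") as fh:
        json.dump(manifest, fh, indent=2, sort_keys=True)
    return manifest


# ---------------------------------------------------------------------------
# printed-series preset and report


def depth_profile_from_coverages(coverages, single_copy_means, depths
                                 ) -> pd.DataFrame:
    """Depth profile from externally measured per-horizon coverages: the
    target family's average coverage and the single-copy marker mean per
    horizon yield the ratio series (rounded for printing)."""
    rows = []
    for c, m, d in zip(coverages, single_copy_means, depths):
        ratio = cov.average_coverage_ratio(c, [m])
        rows.append((d, c, m, ratio, cov.format_ratio(ratio)))
    return pd.DataFrame(rows, columns=["mbsf", "avg_coverage",
                                       "single_copy_mean",
                                       "avg_coverage_ratio", "printed"])


def write_report(outdir, path=None) -> str:
    """Human-readable summary of a finished run's tables."""
    out = Path(outdir)
    lines = ["rdhprofiler run report", "=" * 22, ""]
    enrich = pd.read_csv(out / "enrichment.tsv", sep="\t")
    if enrich.empty:
        lines.append("Enrichment: zero orthologous groups tested.")
    else:
        flagged = enrich[enrich["flagged"]].sort_values("p_adj")
        lines.append(f"Enrichment: {len(enrich)} groups tested, "
                     f"{len(flagged)} overrepresented (adjusted p < alpha).")
        for r in flagged.itertuples():
            lines.append(f"  {r.group_id}: S={r.S:.1f} F={r.F:.3g} "
                         f"p_adj={r.p_adj:.3g}")
    depth = pd.read_csv(out / "depth_profile.tsv", sep="\t")
    if not depth.empty:
        series = ", ".join(depth["printed"].astype(str))
        lines.append("")
        lines.append(f"Target-family coverage ratio by horizon: {series}")
    screen_path = out / "rdh_screen.tsv"
    if screen_path.exists():
        screen = pd.read_csv(screen_path, sep="\t")
        lines.append("")
        lines.append("rdhA screen (per pool): "
                     + "; ".join(
                         f"{r.pool} {r.cluster}: Rdh {r.rdh_domain}/{r.n_genes}, "
                         f"2xFe-S {r.twin_fes}/{r.n_genes}, "
                         f"TAT {r.tat}/{r.n_genes}, rdhB {r.adjacent_rdhB}"
                         for r in screen.itertuples()))
    text = "\n".join(lines) + "\n"
    target = Path(path) if path else out / "report.txt"
    target.write_text(text)
    return text
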