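"""Synthetic community generator.

Builds reference gene catalogs, metagenomic contigs with clone-library
paired-end reads, gene calls, planted reductive-dehalogenase loci and truth
tables with the statistical structure the downstream analysis assumes:

* universal single-copy marker groups present once in (essentially) every
  genome, so that their mean coverage estimates sequencing depth in
  genome-equivalents;
* a rare "target family" group whose community copy rate is the planted
  quantity the coverage module must recover;
* paired-end clones of 650-800 bp reads sampled from genomes in proportion
  to abundance x genome length, mirroring a Sanger shotgun clone library of
  2-3 kb inserts sequenced from both ends.

All randomness flows through one explicit integer seed per call; there is no
module-level random state.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .errors import CapacityError, InputError, ParameterError

# ---------------------------------------------------------------------------
# constants

AA_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"

# one unambiguous codon per amino acid (standard code); back-translation only
_CODON = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCT", "Q": "CAA", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")

#: residues used for random protein bodies: no C (would create spurious Fe-S
#: cysteine spacings) and no R (would create spurious twin-arginine pairs)
_BODY_AA = "ADEFGHIKLMNPQSTVWY"
_HYDROPHILIC_AA = "DEKNQS"

TARGET_GROUP = "rdhA"

GENE_CALL_COLUMNS = ["contig", "start", "end", "strand", "gene_id", "group_id"]
PLACEMENT_COLUMNS = ["clone_id", "read_id", "contig_id", "start", "end"]


# ---------------------------------------------------------------------------
# domain types


@dataclass(frozen=True)
class GenomeRecord:
    """One reference or community genome."""

    id: str
    domain: str  # "archaea" | "bacteria"
    complete: bool
    relative_abundance: float = 0.0


@dataclass
class ReferenceCatalog:
    """Genomes x ortholog groups with per-copy gene lengths.

    ``copy_matrix[i, j]`` is the copy count of group ``groups[j]`` in genome
    ``genomes[i]``. ``gene_lengths_aa[(genome_id, group_id)]`` holds one
    amino-acid length per copy; nucleotide lengths are ``3 * aa``.
    """

    genomes: list[GenomeRecord]
    groups: list[str]
    copy_matrix: np.ndarray
    gene_lengths_aa: dict[tuple[str, str], tuple[int, ...]]
    universal_groups: frozenset[str] = frozenset()
    target_group: str | None = None

    def __post_init__(self) -> None:
        self.copy_matrix = np.asarray(self.copy_matrix, dtype=int)
        if self.copy_matrix.shape != (len(self.genomes), len(self.groups)):
            raise InputError("copy_matrix shape does not match genomes x groups")
        if (self.copy_matrix < 0).any():
            raise InputError("copy counts must be non-negative")
        for lengths in self.gene_lengths_aa.values():
            if any(l <= 0 for l in lengths):
                raise InputError("gene lengths must be positive")

    # -- lookups ----------------------------------------------------------

    @property
    def n_genomes(self) -> int:
        return len(self.genomes)

    def group_index(self, group_id: str) -> int:
        return self.groups.index(group_id)

    def presence_fraction(self, group_id: str, domain: str) -> float:
        """Fraction of *complete* genomes of ``domain`` carrying >=1 copy."""
        j = self.group_index(group_id)
        rows = [i for i, g in enumerate(self.genomes)
                if g.complete and g.domain == domain]
        if not rows:
            return 0.0
        return float((self.copy_matrix[rows, j] >= 1).mean())

    def mean_copy(self, group_id: str, domain: str | None = None,
                  complete_only: bool = True) -> float:
        j = self.group_index(group_id)
        rows = [i for i, g in enumerate(self.genomes)
                if (not complete_only or g.complete)
                and (domain is None or g.domain == domain)]
        if not rows:
            return 0.0
        return float(self.copy_matrix[rows, j].mean())

    def reference_gene_count(self, group_id: str) -> int:
        return int(self.copy_matrix[:, self.group_index(group_id)].sum())

    def mean_reference_length_nt(self, group_id: str) -> float:
        """Arithmetic mean nucleotide length over all reference copies."""
        lengths: list[int] = []
        for genome in self.genomes:
            lengths.extend(self.gene_lengths_aa.get((genome.id, group_id), ()))
        if not lengths:
            raise InputError(f"group {group_id} has no reference members")
        return 3.0 * float(np.mean(lengths))

    # -- tabular I/O (group_id, genome_id, gene_id, aa_length) ------------

    def to_table(self) -> pd.DataFrame:
        rows = []
        for genome in self.genomes:
            for group in self.groups:
                for copy_i, aa in enumerate(
                        self.gene_lengths_aa.get((genome.id, group), ())):
                    rows.append((group, genome.id,
                                 f"{genome.id}|{group}|{copy_i}", aa))
        return pd.DataFrame(rows, columns=["group_id", "genome_id",
                                           "gene_id", "aa_length"])

    def write_table(self, path) -> None:
        self.to_table().to_csv(path, sep="\t", index=False)


@dataclass(frozen=True)
class ReadRecord:
    read_id: str
    sequence: str
    qualities: tuple[int, ...]
    source_genome: str
    source_interval: tuple[int, int]


@dataclass
class CloneReadSet:
    """Paired-end clone reads: each clone has exactly a forward and a
    reverse read."""

    clones: list[tuple[str, ReadRecord, ReadRecord]] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.clones)

    def total_read_length(self) -> int:
        return sum(len(f.sequence) + len(r.sequence) for _, f, r in self.clones)


@dataclass
class TruthTable:
    """Planted ground truth for parameter-recovery oracles."""

    copies_per_genome: dict[str, float] = field(default_factory=dict)
    expected_copy_rate: dict[str, float] = field(default_factory=dict)
    gene_sources: pd.DataFrame | None = None  # gene_id, group_id, genome_id
    total_read_nt: int = 0
    community_genome_length: float = 0.0
    planted_motifs: list[dict] = field(default_factory=list)
    planted_rdhB: list[dict] = field(default_factory=list)
    planted_decoys: list[dict] = field(default_factory=list)
    cluster_memberships: dict[str, str] = field(default_factory=dict)

    @property
    def expected_single_copy_coverage(self) -> float:
        """Closed-form expectation of a universal single-copy gene's depth."""
        if self.community_genome_length == 0:
            return 0.0
        return self.total_read_nt / self.community_genome_length


@dataclass
class MotifConfig:
    """Features planted into synthetic rdhA/rdhB loci."""

    tat_prob: float = 1.0
    n_fes: int = 2
    fes_spacings: tuple[int, int, int] = (2, 2, 3)
    rdha_len_aa: int = 350
    rdhb_len_aa: int = 100
    rdhb_tm_count: int = 3
    rdhb_gap_bp: int = 300  # distance from rdhA end to companion start


# ---------------------------------------------------------------------------
# reference catalog generation


def generate_reference_catalog(n_genomes: int, n_groups: int,
                               universal_fraction: float,
                               target_family_rate: float,
                               seed: int, *,
                               complete_fraction: float = 0.9,
                               archaea_fraction: float = 0.5,
                               background_presence: float = 0.3,
                               multi_copy_prob: float = 0.05,
                               length_range_aa: tuple[int, int] = (200, 500),
                               target_length_aa: int = 350) -> ReferenceCatalog:
    """Emit a catalog with universal single-copy markers and a rare target
    family.

    The target family's total copy count is ``round(rate * n_genomes)``
    distributed one per genome (then round-robin for rates > 1), so the mean
    copy number over genomes equals the requested rate to within rounding;
    markers are copy 1 in every genome. Deterministic under ``seed``.
    """
    if n_genomes < 4:
        raise ParameterError("need n_genomes >= 4 with both domains")
    if not 0.0 <= universal_fraction <= 1.0:
        raise ParameterError("universal_fraction must be within [0, 1]")
    if target_family_rate < 0:
        raise ParameterError("target_family_rate must be >= 0")
    if n_groups < 2:
        raise ParameterError("need n_groups >= 2 (markers + target family)")

    rng = np.random.default_rng(seed)

    n_arch = max(1, int(round(archaea_fraction * n_genomes)))
    n_arch = min(n_arch, n_genomes - 1)  # both domains represented
    genomes = []
    for i in range(n_genomes):
        domain = "archaea" if i < n_arch else "bacteria"
        complete = bool(rng.random() < complete_fraction)
        genomes.append(GenomeRecord(id=f"G{i:04d}", domain=domain,
                                    complete=complete,
                                    relative_abundance=1.0 / n_genomes))
    # guarantee >=1 complete genome per domain (normalization needs both)
    if not any(g.complete and g.domain == "archaea" for g in genomes):
        genomes[0] = dataclasses.replace(genomes[0], complete=True)
    if not any(g.complete and g.domain == "bacteria" for g in genomes):
        genomes[-1] = dataclasses.replace(genomes[-1], complete=True)

    n_universal = int(round(universal_fraction * (n_groups - 1)))
    universal = [f"uscg{j:04d}" for j in range(n_universal)]
    background = [f"og{j:05d}" for j in range(n_groups - 1 - n_universal)]
    groups = universal + [TARGET_GROUP] + background

    copy = np.zeros((n_genomes, n_groups), dtype=int)
    # universal markers: single copy everywhere
    copy[:, :n_universal] = 1
    # target family: deterministic allocation hitting the requested rate
    total_target = int(round(target_family_rate * n_genomes))
    t_col = n_universal
    if total_target > 0:
        base, extra = divmod(total_target, n_genomes)
        copy[:, t_col] = base
        lucky = rng.permutation(n_genomes)[:extra]
        copy[lucky, t_col] += 1
    # background groups: sparse presence, occasional duplications
    n_bg = len(background)
    if n_bg:
        present = rng.random((n_genomes, n_bg)) < background_presence
        dup = rng.random((n_genomes, n_bg)) < multi_copy_prob
        copy[:, t_col + 1:] = present.astype(int) + (present & dup).astype(int)

    # canonical length per group, +-10% jitter per copy
    lo, hi = length_range_aa
    canonical = rng.integers(lo, hi + 1, size=n_groups)
    canonical[t_col] = target_length_aa
    lengths: dict[tuple[str, str], tuple[int, ...]] = {}
    for i, genome in enumerate(genomes):
        for j, group in enumerate(groups):
            c = int(copy[i, j])
            if c == 0:
                continue
            jitter = rng.integers(-canonical[j] // 10, canonical[j] // 10 + 1,
                                  size=c)
            lengths[(genome.id, group)] = tuple(
                int(max(30, canonical[j] + d)) for d in jitter)

    return ReferenceCatalog(genomes=genomes, groups=groups, copy_matrix=copy,
                            gene_lengths_aa=lengths,
                            universal_groups=frozenset(universal),
                            target_group=TARGET_GROUP)


def set_target_family_rate(catalog: ReferenceCatalog, rate: float,
                           seed: int) -> ReferenceCatalog:
    """Return a copy of ``catalog`` with the target family re-planted at a
    new copy rate (used to build enriched communities against an unchanged
    reference)."""
    if rate < 0:
        raise ParameterError("rate must be >= 0")
    rng = np.random.default_rng(seed)
    n = catalog.n_genomes
    j = catalog.group_index(catalog.target_group)
    copy = catalog.copy_matrix.copy()
    total = int(round(rate * n))
    base, extra = divmod(total, n)
    copy[:, j] = base
    lucky = rng.permutation(n)[:extra]
    copy[lucky, j] += 1
    lengths = dict(catalog.gene_lengths_aa)
    target_len = 350
    for genome in catalog.genomes:
        old = lengths.pop((genome.id, catalog.target_group), None)
        if old:
            target_len = old[0]
    for i, genome in enumerate(catalog.genomes):
        c = int(copy[i, j])
        if c:
            lengths[(genome.id, catalog.target_group)] = (target_len,) * c
    return ReferenceCatalog(genomes=list(catalog.genomes),
                            groups=list(catalog.groups),
                            copy_matrix=copy, gene_lengths_aa=lengths,
                            universal_groups=catalog.universal_groups,
                            target_group=catalog.target_group)


# ---------------------------------------------------------------------------
# genome layout & metagenome generation


@dataclass
class _GenomeLayout:
    genome_id: str
    contig_id: str
    length: int
    gene_calls: pd.DataFrame  # 0-based half-open


def _layout_genome(catalog: ReferenceCatalog, genome: GenomeRecord,
                   rng: np.random.Generator | None = None,
                   spacer_bp: int = 100) -> _GenomeLayout:
    """Lay genes end to end with fixed intergenic spacers (forward strand).

    Gene order is shuffled per genome when ``rng`` is given: a linear
    "genome" under-covers its two ends (no clone insert extends past a
    boundary), so a fixed gene order would bias the same ortholog groups low
    in every genome.
    """
    genes = []
    for group in catalog.groups:
        for copy_i, aa in enumerate(
                catalog.gene_lengths_aa.get((genome.id, group), ())):
            genes.append((group, copy_i, aa))
    if rng is not None and len(genes) > 1:
        genes = [genes[i] for i in rng.permutation(len(genes))]
    rows = []
    pos = spacer_bp
    contig = f"{genome.id}_c0"
    for group, copy_i, aa in genes:
        nt = 3 * aa
        gene_id = f"{genome.id}|{group}|{copy_i}|mg"
        rows.append((contig, pos, pos + nt, "+", gene_id, group))
        pos += nt + spacer_bp
    calls = pd.DataFrame(rows, columns=GENE_CALL_COLUMNS)
    return _GenomeLayout(genome.id, contig, pos, calls)


def _random_protein(rng: np.random.Generator, n: int) -> str:
    body = np.frombuffer(_BODY_AA.encode(), dtype="S1")
    return rng.choice(body, size=n).tobytes().decode()


def back_translate(protein: str) -> str:
    """Map a protein to nucleotides with one fixed codon per residue."""
    return "".join(_CODON[a] for a in protein)


def reverse_complement(seq: str) -> str:
    return seq.translate(_COMPLEMENT)[::-1]


def _genome_sequence(layout: _GenomeLayout, rng: np.random.Generator) -> str:
    """Fill the layout with coding sequence; spacers are random nucleotides."""
    bases = np.frombuffer(b"ACGT", dtype="S1")
    out = rng.choice(bases, size=layout.length).tobytes().decode()
    chunks = []
    cursor = 0
    for row in layout.gene_calls.itertuples():
        chunks.append(out[cursor:row.start])
        aa = (row.end - row.start) // 3
        protein = "M" + _random_protein(rng, aa - 1)
        chunks.append(back_translate(protein))
        cursor = row.end
    chunks.append(out[cursor:])
    return "".join(chunks)


def generate_metagenome(catalog: ReferenceCatalog,
                        abundances: Mapping[str, float] | Sequence[float] | None,
                        n_clones: int,
                        read_len_range: tuple[int, int] = (650, 800),
                        seed: int = 0, *,
                        insert_len_range: tuple[int, int] = (2000, 3000),
                        emit_sequences: bool = True,
                        base_quality: int = 40,
                        pool: str = "pool1"
                        ) -> tuple[dict[str, str], CloneReadSet,
                                   pd.DataFrame, pd.DataFrame, TruthTable]:
    """Sample a clone library from the community defined by ``catalog``.

    Returns ``(contigs, reads, gene_calls, placements, truth)``. Contigs are
    the community genome sequences (assembly is assumed perfect; the
    downstream analysis consumes contigs, gene calls and read placements, not
    the assembler). Clones are drawn from genomes with probability
    proportional to ``abundance x genome_length``; each clone yields a
    forward and a reverse read from the two insert ends. With
    ``emit_sequences=False`` contigs and read strings are skipped and only
    placements/gene calls/truth are produced (interval-only simulations).
    """
    if not catalog.genomes:
        raise InputError("empty catalog")
    if n_clones < 0:
        raise ParameterError("n_clones must be >= 0")

    n = catalog.n_genomes
    if abundances is None:
        ab = np.full(n, 1.0 / n)
    elif isinstance(abundances, Mapping):
        ab = np.array([abundances[g.id] for g in catalog.genomes], dtype=float)
    else:
        ab = np.asarray(list(abundances), dtype=float)
    if abs(ab.sum() - 1.0) > 1e-9 or (ab < 0).any():
        raise InputError("abundances must be non-negative and sum to 1")

    rng = np.random.default_rng(seed)
    layouts = [_layout_genome(catalog, g, rng) for g in catalog.genomes]
    glens = np.array([l.length for l in layouts], dtype=float)

    gene_calls = pd.concat([l.gene_calls for l in layouts], ignore_index=True) \
        if layouts else pd.DataFrame(columns=GENE_CALL_COLUMNS)

    placements_rows = []
    clone_rows: list[tuple[str, ReadRecord, ReadRecord]] = []
    total_nt = 0

    if n_clones > 0:
        weights = ab * glens
        weights = weights / weights.sum()
        picks = rng.choice(n, size=n_clones, p=weights)
        rl_lo, rl_hi = read_len_range
        il_lo, il_hi = insert_len_range
        for c in range(n_clones):
            gi = int(picks[c])
            L = int(glens[gi])
            insert = int(rng.integers(il_lo, il_hi + 1))
            insert = min(insert, L)
            start = int(rng.integers(0, L - insert + 1))
            end = start + insert
            fwd_len = min(int(rng.integers(rl_lo, rl_hi + 1)), insert)
            rev_len = min(int(rng.integers(rl_lo, rl_hi + 1)), insert)
            clone_id = f"{pool}_cl{c:06d}"
            contig = layouts[gi].contig_id
            f_iv = (start, start + fwd_len)
            r_iv = (end - rev_len, end)
            placements_rows.append((clone_id, clone_id + "/1", contig, *f_iv))
            placements_rows.append((clone_id, clone_id + "/2", contig, *r_iv))
            total_nt += fwd_len + rev_len
            if emit_sequences:
                clone_rows.append((clone_id, (gi, f_iv, False), (gi, r_iv, True)))

    contigs: dict[str, str] = {}
    reads = CloneReadSet()
    if emit_sequences:
        for layout in layouts:
            contigs[layout.contig_id] = _genome_sequence(layout, rng)
        for clone_id, (gi, f_iv, _), (gj, r_iv, _) in clone_rows:
            cid = layouts[gi].contig_id
            seq = contigs[cid]
            fwd = ReadRecord(clone_id + "/1", seq[f_iv[0]:f_iv[1]],
                             (base_quality,) * (f_iv[1] - f_iv[0]),
                             layouts[gi].genome_id, f_iv)
            rev = ReadRecord(clone_id + "/2",
                             reverse_complement(seq[r_iv[0]:r_iv[1]]),
                             (base_quality,) * (r_iv[1] - r_iv[0]),
                             layouts[gj].genome_id, r_iv)
            reads.clones.append((clone_id, fwd, rev))

    placements = pd.DataFrame(placements_rows, columns=PLACEMENT_COLUMNS)

    truth = TruthTable(
        copies_per_genome={
            group: float(catalog.copy_matrix[:, j].mean())
            for j, group in enumerate(catalog.groups)},
        expected_copy_rate={
            group: float((ab * catalog.copy_matrix[:, j]).sum())
            for j, group in enumerate(catalog.groups)},
        gene_sources=gene_calls[["gene_id", "group_id"]].assign(
            genome_id=[g.split("|")[0] for g in gene_calls["gene_id"]]),
        total_read_nt=total_nt,
        community_genome_length=float((ab * glens).sum()),
    )
    return contigs, reads, gene_calls, placements, truth


# ---------------------------------------------------------------------------
# planted rdhA / rdhB loci


def _random_dna(rng: np.random.Generator, n: int) -> str:
    bases = np.frombuffer(b"ACGT", dtype="S1")
    return rng.choice(bases, size=n).tobytes().decode()


def _tm_stretch(rng: np.random.Generator, n: int = 21) -> str:
    hydrophobic = np.frombuffer(b"LIVFA", dtype="S1")
    return rng.choice(hydrophobic, size=n).tobytes().decode()


def _hydrophilic(rng: np.random.Generator, n: int) -> str:
    aas = np.frombuffer(_HYDROPHILIC_AA.encode(), dtype="S1")
    return rng.choice(aas, size=n).tobytes().decode()


def _build_rdha_protein(rng: np.random.Generator, cfg: MotifConfig,
                        with_tat: bool) -> tuple[str, dict]:
    """rdhA-like protein: optional N-terminal TAT signal, two (or ``n_fes``)
    ferredoxin-type four-cysteine blocks at recorded positions."""
    a, b, c = cfg.fes_spacings
    fes = ("C" + _random_protein(rng, a) + "C" + _random_protein(rng, b)
           + "C" + _random_protein(rng, c) + "C")
    parts = ["M"]
    motifs: dict = {"tat": with_tat, "fes_positions": []}
    if with_tat:
        parts.append("SRR" + "G" + "F" + "LK")  # canonical [ST]RRxF motif
    pad = cfg.rdha_len_aa // 2 - sum(len(p) for p in parts)
    parts.append(_random_protein(rng, max(10, pad)))
    for _ in range(cfg.n_fes):
        motifs["fes_positions"].append(sum(len(p) for p in parts))
        parts.append(fes)
        parts.append(_random_protein(rng, 20))
    tail = cfg.rdha_len_aa - sum(len(p) for p in parts)
    if tail > 0:
        parts.append(_random_protein(rng, tail))
    return "".join(parts), motifs


def _build_rdhb_protein(rng: np.random.Generator, n_tm: int,
                        total_aa: int) -> str:
    parts = ["M", _hydrophilic(rng, 4)]
    for _ in range(n_tm):
        parts.append(_tm_stretch(rng))
        parts.append(_hydrophilic(rng, 19))
    prot = "".join(parts)
    if len(prot) < total_aa:
        prot += _hydrophilic(rng, total_aa - len(prot))
    return prot


def plant_rdh_loci(contigs: dict[str, str], gene_calls: pd.DataFrame,
                   n_rdhA: int, motif_config: MotifConfig | None = None,
                   with_rdhB: float = 0.0, seed: int = 0, *,
                   family: str = "smkt1",
                   decoy_kinds: Sequence[str] = ()
                   ) -> tuple[dict[str, str], pd.DataFrame, TruthTable]:
    """Append rdhA loci (and optional rdhB companions / decoys) to contigs.

    One locus is planted per contig (end-appended after a 200-bp spacer), so
    ``n_rdhA`` may not exceed the number of contigs. Decoy kinds:

    * ``"long"``  — 160-aa companion (fails the <150 aa rule)
    * ``"far"``   — qualifying companion placed >2 kb away
    * ``"few_tm"``— 100-aa companion with a single TM helix
    """
    cfg = motif_config or MotifConfig()
    if not 0.0 <= with_rdhB <= 1.0:
        raise ParameterError("with_rdhB must be within [0, 1]")
    contig_ids = sorted(contigs)
    if n_rdhA > len(contig_ids):
        raise CapacityError(
            f"cannot plant {n_rdhA} loci on {len(contig_ids)} contigs")

    rng = np.random.default_rng(seed)
    new_contigs = dict(contigs)
    rows = []
    truth = TruthTable()
    n_companion = int(round(with_rdhB * n_rdhA))
    chosen = contig_ids[:n_rdhA]
    for i, cid in enumerate(chosen):
        seq = new_contigs[cid]
        pos = len(seq) + 200
        with_tat = bool(rng.random() < cfg.tat_prob)
        prot, motifs = _build_rdha_protein(rng, cfg, with_tat)
        nt = back_translate(prot)
        seq = seq + _random_dna(rng, 200) + nt
        gene_id = f"{family}_rdhA_{i:03d}"
        rows.append((cid, pos, pos + len(nt), "+", gene_id, f"{family}_rdhA"))
        truth.planted_motifs.append(
            {"gene_id": gene_id, "contig": cid, "start": pos,
             "end": pos + len(nt), **motifs})
        truth.cluster_memberships[gene_id] = family
        if i < n_companion:
            gap = min(cfg.rdhb_gap_bp, 1900)
            bprot = _build_rdhb_protein(rng, cfg.rdhb_tm_count, cfg.rdhb_len_aa)
            bnt = back_translate(bprot)
            bpos = len(seq) + gap
            seq = seq + _random_dna(rng, gap) + bnt
            bid = f"{family}_rdhB_{i:03d}"
            rows.append((cid, bpos, bpos + len(bnt), "+", bid, f"{family}_rdhB"))
            truth.planted_rdhB.append(
                {"gene_id": bid, "partner": gene_id, "contig": cid,
                 "start": bpos, "end": bpos + len(bnt), "aa_len": len(bprot)})
        for kind in decoy_kinds:
            if kind == "long":
                dprot = _build_rdhb_protein(rng, 3, 160)
                dgap = 200
            elif kind == "far":
                dprot = _build_rdhb_protein(rng, 3, 100)
                dgap = 2500
            elif kind == "few_tm":
                dprot = _build_rdhb_protein(rng, 1, 100)
                dgap = 200
            else:
                raise ParameterError(f"unknown decoy kind: {kind}")
            dnt = back_translate(dprot)
            dpos = len(seq) + dgap
            seq = seq + _random_dna(rng, dgap) + dnt
            did = f"{family}_decoy_{kind}_{i:03d}"
            rows.append((cid, dpos, dpos + len(dnt), "+", did,
                         f"{family}_decoy"))
            truth.planted_decoys.append(
                {"gene_id": did, "kind": kind, "partner": gene_id,
                 "contig": cid, "start": dpos, "end": dpos + len(dnt)})
        # trailing spacer so planted genes do not abut the contig end
        # (genes touching the end read as truncated in the rdhB screen)
        seq = seq + _random_dna(rng, 200)
        new_contigs[cid] = seq

    new_calls = pd.concat(
        [gene_calls, pd.DataFrame(rows, columns=GENE_CALL_COLUMNS)],
        ignore_index=True)
    return new_contigs, new_calls, truth


# ---------------------------------------------------------------------------
# read quality rules


def quality_trim(qualities: Sequence[int], window: int = 20, step: int = 20,
                 q_min: int = 20, frac: float = 0.8) -> tuple[int, int]:
    """Longest run of passing quality windows, as a half-open bp interval.

    A window passes iff >= ``frac`` of its bases have Phred quality >=
    ``q_min``. Windows are laid at 0, step, 2*step, ...; a trailing partial
    window is judged against its own length. Ties between equally long runs
    keep the leftmost. Returns ``(0, 0)`` when no window passes.
    """
    q = np.asarray(qualities, dtype=int)
    if q.size == 0:
        return (0, 0)
    if window < 1 or step < 1:
        raise ParameterError("window and step must be >= 1")
    starts = list(range(0, q.size, step))
    passes = []
    for s in starts:
        w = q[s: s + window]
        passes.append((w >= q_min).sum() >= frac * w.size)
    best = (0, 0)
    run_start = None
    for i, ok in enumerate(passes + [False]):
        if ok and run_start is None:
            run_start = i
        elif not ok and run_start is not None:
            lo = starts[run_start]
            hi = min(starts[i - 1] + window, q.size)
            if hi - lo > best[1] - best[0]:
                best = (lo, hi)
            run_start = None
    return best


def mask_low_quality(sequence: str, qualities: Sequence[int],
                     q_mask: int = 15) -> str:
    """Replace bases below ``q_mask`` with 'X'; length is preserved."""
    if len(sequence) != len(qualities):
        raise InputError("sequence and qualities must have equal length")
    return "".join("X" if q < q_mask else b
                   for b, q in zip(sequence, qualities))


# ---------------------------------------------------------------------------
# file I/O (FASTA / FASTQ / GFF-like / placements)


def write_fasta(contigs: Mapping[str, str], path) -> None:
    with open(path, "w") as fh:
        for cid in sorted(contigs):
            fh.write(f">{cid}\n")
            seq = contigs[cid]
            for i in range(0, len(seq), 70):
                fh.write(seq[i:i + 70] + "\n")


def write_fastq(reads: CloneReadSet, path) -> None:
    with open(path, "w") as fh:
        for _, fwd, rev in reads.clones:
            for rec in (fwd, rev):
                qual = "".join(chr(q + 33) for q in rec.qualities)
                fh.write(f"@{rec.read_id}\n{rec.sequence}\n+\n{qual}\n")


def write_gene_calls(calls: pd.DataFrame, path) -> None:
    """GFF-like TSV; coordinates converted to 1-based inclusive on disk."""
    out = calls.copy()
    out["start"] = out["start"] + 1
    out.to_csv(path, sep="\t", index=False)


def read_gene_calls(path) -> pd.DataFrame:
    calls = pd.read_csv(path, sep="\t")
    calls["start"] = calls["start"] - 1
    return calls[GENE_CALL_COLUMNS]


def write_placements(placements: pd.DataFrame, path) -> None:
    placements.to_csv(path, sep="\t", index=False)


def read_placements(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")[PLACEMENT_COLUMNS]
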