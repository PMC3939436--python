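# rdhprofiler

Quantitative profiling of a target gene family — reductive dehalogenase
catalytic-subunit homologs (*rdhA*) — in clone-library shotgun metagenomes,
normalized by universally conserved single-copy marker genes.

Organohalide-respiring prokaryotes use reductive dehalogenases as terminal
reductases, and *rdhA*-like genes turn up far from polluted sites, including
deep subseafloor sediments. Measuring how *frequent* such a family is in a
metagenome is not a counting problem: sequencing depth differs between
samples and genes fragment across contigs. This package implements the
marker-normalized coverage approach for that measurement, together with the
overrepresentation statistics, motif/neighborhood screens and tree-cluster
logic that turn raw homology evidence into an annotated family profile. A
synthetic community generator with planted ground truth stands in for
sediment data, so every stage is testable against known parameters.

## The statistics at the core

For a gene (or ortholog group) *g* in one sample, the **average coverage**
is

```
cov(g) = (nucleotides of clone reads overlapping g) / L̄(g)
```

where `L̄(g)` is the mean nucleotide length of the group's reference members,
and reads of the same clone that overlap on a contig are counted once (they
sequence the same insert). The **average coverage ratio**

```
acr(g) = cov(g) / mean{ cov(u) : u ∈ U }
```

divides by the mean coverage of the set *U* of universal single-copy genes
(present once in ≥95% of complete archaeal *and* bacterial genomes, mean
copy number < 1.2). Since each marker occurs once per genome, their mean
coverage estimates sequencing depth in genome-equivalents, and `acr(g)` is
the estimated copy number of *g* per genome.

Across samples, each group gets `S` (the summed coverage — an estimated
metagenomic gene count) and `F` (fold change of the per-genome-equivalent
frequency over the reference per-genome frequency). Overrepresentation of a
group is the upper tail of a hypergeometric distribution — drawing `k` genes
(the floored metagenome total) from an urn of `m` group members and `n`
others, `P(X ≥ q)` with `q = ⌊S⌋` — equivalent to a one-sided Fisher exact
test, with Benjamini–Hochberg FDR control and a strict `p < 1e-4` flag.

Annotation screens: Kimura-corrected protein distance
`d = −ln(1 − p − 0.2p²)` ranks homology hits (unidirectional best hits,
`E ≤ 0.001`, bit score ≥ 60); regex detectors find the twin-arginine (TAT)
export signal and twin four-cysteine Fe-S motifs; a Kyte–Doolittle
hydropathy window counts transmembrane helices for the *rdhB* neighborhood
rule (gene within 2 kb of an *rdhA*, < 150 aa, 2–3 helices); and clusters
are extracted from support-labeled Newick trees (supported at SH support
≥ 0.90, tentative below).

## Worked example

Reproduce a printed ratio series from externally measured coverages — the
target family's per-horizon average coverage over the single-copy marker
mean:

```bash
rdhprofiler run-all --preset paper-ratios --out run_ratios
# ratio series: 0.68, 0.35, 0.49, 0.44, 1.2
```

Each number is copies of the family per genome-equivalent at one sediment
horizon (e.g. 5.4/8.0 = 0.675 → printed 0.68 at 0.8 m below seafloor).

Run the full synthetic pipeline (200-genome reference, two sediment-horizon
pools of 600 clones, target family at 0.04 copies/genome in the reference
but 0.5 in the community, four planted TAT-less *rdhA* loci with *rdhB*
companions per pool):

```bash
rdhprofiler -v run-all --seed 7 --out run_syn
rdhprofiler report --run run_syn
```

```
Enrichment: 96 groups tested, 1 overrepresented (adjusted p < alpha).
  rdhA: S=22.1 F=14.7 p_adj=2.13e-10

Target-family coverage ratio by horizon: 0.53, 0.64

rdhA screen (per pool): 0.8mbsf smkt1: Rdh 4/4, 2xFe-S 4/4, TAT 0/4, rdhB 4;
5.1mbsf smkt1: Rdh 4/4, 2xFe-S 4/4, TAT 0/4, rdhB 4
```

Reading this: the planted family is the only group flagged as
overrepresented (its community rate is 12.5× its reference rate; the
estimated `F` is 14.7), its recovered copy rate per horizon (0.53, 0.64)
matches the planted 0.5 copies/genome, and the motif screen reproduces the
planted family's composition — every locus carries the twin Fe-S motif,
none carries a TAT signal, and all companions pass the *rdhB* rules. The
run directory holds the machine-readable tables (`coverage.tsv`,
`enrichment.tsv`, `depth_profile.tsv`, `rdh_screen.tsv`,
`cluster_by_depth.tsv`, `taxon_frequency.tsv`) plus `manifest.json` with
config, checksums and timings; a rerun with the same seed is byte-identical.

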