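# cablediv

Delineation of cable bacteria diversity from long 16S rRNA gene sequences.

Cable bacteria are filamentous, sulfur-oxidizing Desulfobulbaceae that conduct
electrical currents over centimeter distances in aquatic sediments. Their
diversity is conventionally surveyed by compiling long (≥800 bp) 16S rRNA gene
sequences from enrichments, literature and public databases, curating them, and
grouping them into **species-level clades** (≥98.7% pairwise identity, valid
only when a nearly complete ≥1,200 bp member is present) nested inside
monophyletic **genus-level clusters** (94.5% identity guide combined with the
topology of an outgroup-rooted tree). `cablediv` implements that whole
procedure as a tested, reusable library for people who study environmental 16S
datasets of this kind: sequence screening against a trusted reference panel,
quality curation, tree building, threshold clustering, an in-silico twin of the
nested PCR protocol used to obtain full-length sequences from single filaments,
and per-site biogeographic summaries.

## The method in brief

Given records $x_1,\dots,x_n$ and trusted queries $q_1,\dots,q_m$:

1. **Screen**: keep $x_i$ iff $\max_j \mathrm{pid}(x_i,q_j) \ge 92\%$, where
   `pid` is percent identity from a semi-global pairwise alignment (free end
   gaps, IUPAC codes matching by set intersection). A curated whitelist can
   retain known exceptions below the cutoff.
2. **Curate**: remove records with more than 5 violations (gap or incompatible
   base) inside conserved regions of a per-column consensus profile; remove
   records falling outside the most recent common ancestor of the trusted
   queries in an outgroup-rooted neighbor-joining tree; apply the ≥800 bp
   length cutoff.
3. **Species-level clades**: complete-linkage agglomerative clustering on
   $d = 100 - \mathrm{pid}$, cut at $100 - 98.7$, so *every* within-clade pair
   meets the cutoff. A clade is valid iff its longest member is ≥1,200 bp; the
   longest member is the clade representative.
4. **Genus-level clusters**: preorder decomposition of the rooted tree over
   clade representatives — a node becomes a cluster as soon as its leaves'
   linkage identity reaches $94.5\% - \text{tolerance}$ — so clusters are
   monophyletic by construction.
5. **Biogeography**: salinity classes (freshwater S < 0.5, brackish
   0.5 ≤ S < 30, marine 30 ≤ S ≤ 36, hypersaline S > 36), per-site clade and
   cluster composition, co-occurrence counts and endemic (single-site) clades.

A synthetic-data generator (`cablediv.synthetic_data`) emulates the study
structure — a two-level genus/species radiation with controlled identity bands,
planted primer windows, off-clade contaminants, short fragments and
conserved-region violators — so every stage is testable without downloads.

## Worked example

```bash
python examples/01_simulate_and_delineate.py
```

prints (seed 42):

```
input sequences          : 142 (+1 outgroup)
planted structure        : 6 genera, 90 species, 38 singletons
recovered species clades : 90
recovered genus clusters : 6
recovered singletons     : 38
min identity inside a cluster  : 97.47%
max identity between clusters  : 93.07%
  stage screen            142 -> 142
  stage conserved         142 -> 142
  stage monophyly         142 -> 142
  stage length            142 -> 142
  stage species_clades    142 -> 90
  stage genus_clusters     90 -> 6
```

The pipeline recovers the planted taxonomy exactly: 90 species-level clades in
6 genus-level clusters with 38 singletons, and the smallest identity inside any
cluster (97.47%) stays well above the largest identity between clusters
(93.07%), which is what makes the 94.5% genus guide decisive on these data.
The other examples cover the in-silico nested PCR (`02`), the curation filters
on planted artifacts (`03`) and the per-site summaries (`04`).

The same functionality is exposed on the shell:

```bash
cablediv simulate --seed 1 --outdir run/
cablediv run run/records.fasta run/sites.tsv \
    --queries run/queries.txt --outgroup outgroup --outdir run/out
```

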