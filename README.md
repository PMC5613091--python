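# plasmidfusion

Dissection of composite (fusion) plasmids in multipartite bacterial genomes.

Alphaproteobacteria — rhizobia and roseobacters alike — carry chromosomes
alongside extrachromosomal replicons (ECRs) that replicate via **RepABC
modules**: *repA*-*repB*-*repC* operons with the replication origin inside
*repC* and, downstream, a doublet of 14-nt perfect inverted repeats whose arm
sequence (`TTAACAG` vs `TTCACAG`) defines the plasmid compatibility group.
When a plasmid from one order fuses with a replicon of another, the chimera
keeps both donors' molecular imprints: two replication modules, two G+C
regimes, two codon-usage signatures and two gene-origin inventories.
`plasmidfusion` reads those imprints back out:

* **Replication modules** — annotation-driven detection of RepABC operons and
  solitary replicases; palindrome-doublet scanning (500-bp padded window,
  11–42-bp spacers) to type compatibility groups.
* **Composition** — windowed G+C content (1-kb) and skew (10-kb), cumulative
  skew with ori/terminus prediction (ori at the detrended cumulative minimum,
  terminus at the maximum), and *in-silico ligation* of a sub-replicon to
  recover its ancestral replication landmarks.
* **Codon usage** — codon counting, RSCU (relative synonymous codon usage:
  `RSCU_i = count_i / (family total / family size)`, 59 codons of bacterial
  code 11), PCA ordination, hierarchical clustering, and chromid-vs-plasmid
  classification: an ECR is a *chromid* iff its RSCU distance to its own
  chromosome is at most half the median inter-chromosome distance of the set.
* **Origin painting** — per-gene order-level origin from best homology hits
  (self-TaxID exclusion, E < 1e-5, deterministic tie-breaks), per-replicon
  origin fractions, and segmentation of the gene order into donor blocks
  whose boundaries localize the fusion breakpoints (transposases masked).
* **Synthetic data** — a generator emitting composite plasmids and genome
  sets with full ground truth (segment bounds, planted oris, operon and
  palindrome coordinates, primer sites, per-gene origin labels), so every
  stage is testable offline.
* **In-silico PCR** — exact primer-site search with product lengths,
  including origin-spanning products on circular templates and reverse
  primers given 3'→5' as printed in cloning protocols.

## Worked example

Generate the default scenario — a 260-kb composite plasmid: 200-kb
rhodobacteral backbone (G+C 62%, roseobacter RepABC module) + 60-kb rhizobial
insertion (G+C 58%, own RepABC module and solitary replicase) — and analyse
it:

```sh
$ plasmidfusion simulate --seed 1 --out sim
$ plasmidfusion find-modules sim/pSYN259.gbk
pSYN259  100000-104001  +  pSYN259_00475;pSYN259_00480;pSYN259_00485  group-2
pSYN259  220000-224649  +  pSYN259_01000;pSYN259_01005;pSYN259_01010  group-1
pSYN259  245000-246301  +  pSYN259_01115  solitary_repC
```

Two complete RepABC modules are found and typed from their palindrome
doublets — the backbone module carries group-2 repeats, the insertion module
group-1 — plus one solitary replicase.

```sh
$ plasmidfusion composition sim/pSYN259.gbk
pSYN259  ori=103575  ter=254276
```

The cumulative-skew minimum (the active origin) falls inside the backbone
module's *repC* gene (102,700–104,001).

```sh
$ plasmidfusion pcr sim/pSYN259.gbk CGTCGAGCAGGTAAAGAACG GTTTCGACCCCTTCAGCATC --rev-3to5
pSYN259  99830  104244  4415  insert=4375
```

The module-flanking primer pair amplifies a single 4,415-bp product.

```sh
$ plasmidfusion run-all --genome sim/pSYN259.gbk --hits sim/pSYN259.hits.tsv --out report
```

`report/origin_blocks.tsv` then contains the donor-block segmentation:

```
replicon  start   end     origin           n_genes
pSYN259   132     199611  Rhodobacterales  158
pSYN259   200023  259147  Rhizobiales      45
```

— two blocks whose boundary (breakpoint near 199,817) recovers the planted
fusion joint at 200,000, with 67% of genes painted rhodobacteral and 23%
rhizobial (`report/report.json`). Chromid classification needs the full
genome set (`plasmidfusion simulate --genome-set`), where the two chromids
affiliate with the chromosome and the composite plasmid is called a genuine
plasmid.

Every command is a thin wrapper over the library (`plasmidfusion.replication`,
`.composition`, `.codon_usage`, `.painting`, `.pcr`, `.synthetic`,
`.pipeline`), which is the intended programmatic interface.

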