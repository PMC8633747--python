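# recombikit

Design toolkit for cloning large, complex nuclear genes by recombineering
from BAC/fosmid libraries, built around the *Chlamydomonas reinhardtii*
use case: a GC-rich (~64% whole-gene, higher in coding regions), highly
repetitive genome where PCR- and synthesis-based cloning routinely fail.

Recombineering retrieves a target gene from a clone in *E. coli* by
homologous recombination with a linear tagging cassette carrying two 50-bp
homology arms — one placed 2,000–3,000 bp upstream of the annotated ATG
(so the native promoter and 5′-UTR come along) and one ending at the last
base before the stop codon (so the product reads in frame into a
linker–fluorophore–affinity-tag module). `recombikit` provides the
computational half of that pipeline:

* **Clone coverage search** — for every gene, the five smallest BACs or
  fosmids whose mapped interval contains the required region, plus
  library-wide coverage fractions (strict, and allowing clones that
  terminate within the 3′-UTR).
* **Homology-arm and primer design** — complexity-aware ranking of 50-bp
  upstream arm windows (homopolymer runs, dinucleotide tandems, GC
  content), the 3′ pre-stop arm, full cloning primers against any of the
  tagging vectors, and four check-primer pairs per gene screened through
  the primer-QC rules.
* **Sequence-complexity profiling** — tandem repeats (mono/di/tri/tetra+;
  ≥10 bp for mononucleotide, ≥20 bp otherwise, ≥90% identity to a perfect
  unit tiling) and inverted repeats (stem ≥10 bp, spacer ≤10 bp, total
  ≤210 bp, ≤1 mismatch per 10 bp of stem), per gene and per subregion
  (5′-UTR / ATG–Stop / 3′-UTR).
* **uORF classification** — every upstream ATG in a 5′-UTR classified as
  class 1 (in frame with the main ORF, a potential N-terminal extension),
  class 2 (out of frame, terminating inside the CDS) or class 3 (complete
  ORF within the 5′-UTR).
* **Primer quality screening** — length ≤30 nt; secondary-structure ΔG
  (nearest-neighbor thermodynamics: self-dimer, cross-dimer, hairpin)
  above −9 kcal/mol at 66/72 °C; ≤4 tandem mono-/dinucleotide units; ≤4
  consecutive 3′ G/C bases.
* **Construct simulation** — GenBank vector models (pLM099 family
  grammar), in-silico cassette PCR (ccdB excluded, single I-SceI site),
  assembly of the circular recombineering product with junction contexts
  and reading-frame verification, and restriction-digest prediction with
  diagnostic-enzyme suggestions.
* **Statistics** — Wilson score intervals, per-size-bin clonability
  extrapolation, and Mann–Whitney rank-sum comparison (U = number of
  (a, b) pairs with a < b plus half-ties).
* **Synthetic fixtures** — a deterministic genome/annotation/clone-map/
  vector generator with planted ground truth, so the whole pipeline is
  testable offline (`recombikit.fixtures`).

## Worked example

```python
from recombikit import fixtures, clone_search, arm_design, construct, genome_io

fx = fixtures.generate_fixture(fixtures.FixtureConfig(seed=1, n_genes=4))
gene = fx.genes[0]

cov = clone_search.clones_covering(gene, upstream_bp=3000, clones=fx.clones)
print(cov.covered, cov.covering_clones)
# True ['clone_synth01.g100_a', 'clone_synth01.g100_b', 'clone_synth01.g100_c']

arm5 = arm_design.design_5prime_arms(gene, fx.genome)[0]
arm3 = arm_design.three_prime_arm(gene, fx.genome)
print(arm5.offset_from_atg, round(arm5.gc, 2))
# -2500 0.6

pair = arm_design.build_cloning_primers(arm5, arm3, fx.vector)
cassette = construct.simulate_cassette_pcr(fx.vector, pair)
print(len(cassette))
# 4700

region = fx.genome.slice(gene.chromosome, arm5.genomic_interval[0],
                         arm3.genomic_interval[1])
product = construct.assemble_product(region, arm5, arm3, cassette,
                                     cds_len_before_stop=1200)
print(product.length, product.fusion_frame_ok, product.isce1_positions)
# 8300 True [7432]
```

The clone search finds three covering BACs ranked smallest-first; the best
5′ arm sits 2,500 bp upstream of the ATG at the scoring optimum (GC 0.60);
the simulated cassette amplicon is 4,700 bp (4.6-kbp cassette plus two
50-bp arms); and the assembled 8,300-bp circular product carries exactly
one I-SceI linearization site with the gene in frame with the
linker–fluorophore module.

The same steps are available from the shell:

```bash
recombikit make-fixtures --seed 1 --n-genes 4 --outdir fx
recombikit search-clones --genome fx/genome.fasta --annotation fx/genes.gff3 \
    --clone-map fx/clones.bed --upstream-bp 3000 --out coverage.tsv
recombikit design-arms --genome fx/genome.fasta --annotation fx/genes.gff3 \
    --vector fx/vector.gb --out arms.tsv
recombikit complexity-report --genome fx/genome.fasta \
    --annotation fx/genes.gff3 --out profile.tsv
```

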