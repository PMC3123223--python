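# homeosort

Sorting cloned amplicon sequences into homoeologous groups in
allopolyploids — with chimera exclusion, indel coding, distance and
selection statistics, and parsimony tree machinery.

## The problem

When a single-copy nuclear gene (e.g. *GBSSI*/waxy) is PCR-amplified and
cloned from an allopolyploid grass, the clone library mixes:

* several divergent **homoeologs**, one per subgenome, each tracing back to
  a different diploid progenitor;
* **polymerase errors** — rare bases carried by exactly one clone
  ("singletons");
* **PCR-mediated recombinants** — chimeric molecules splicing the 5' part
  of one homoeolog onto the 3' part of another, which would be
  misinterpreted as extra gene variants if kept.

`homeosort` implements the clone-processing workflow such studies use,
as deterministic, testable code:

1. **Singleton masking** — a base carried by exactly one clone at a column
   where ≥2 clones agree is replaced by `?`.
2. **Grouping** — clones identical after masking form a sequence group;
   masked cells act as wildcards; one-clone groups one step away from a
   larger group are absorbed as residual polymerase errors.
3. **Recombinant screening** — each clone is tested against every pair of
   donor groups: a clone whose sequence is reproduced (up to a handful of
   mismatches) by donor A up to a single breakpoint and donor B after it,
   with ≥ `min_run` diagnostic sites on both sides, is excluded as a PCR
   chimera.
4. **Representative choice** — per group, the clone with the fewest
   singletons (ties broken by id).
5. **Downstream statistics** on the representatives:
   * Kimura 2-parameter distances with pairwise deletion,
     `d = -½·ln((1−2P−Q)·√(1−2Q))`;
   * substitution/indel difference accounting between pairs;
   * translation-based pseudogene screening (internal stop codons,
     frame-disrupting exonic indels);
   * pairwise Ka/Ks (Nei–Gojobori 1986 pathway counting with
     Jukes–Cantor correction);
   * Tajima's relative rate test, `χ² = (m₁−m₂)²/(m₁+m₂)` on unique
     substitutions versus an outgroup;
   * modified complex indel coding (MCIC) of alignment gaps into standard
     characters with step-cost matrices, NEXUS export;
   * neighbor joining, Fitch/Sankoff parsimony scoring, heuristic MP
     search (random addition + NNI/SPR/TBR), ensemble CI/RI, bootstrap
     majority-rule consensus.

A ground-truthed **simulator** generates allopolyploid clone libraries
(progenitor panel evolved under a K2P process, intron-only indels,
pseudogenized copies, template-switch chimeras, per-site errors), so every
stage is exercisable and scoreable without external data.

## Worked example

```bash
homeosort simulate --seed 5 -o sim/
homeosort pipeline sim/clones.fasta --regions sim/regions.tsv --seed 5 -o out/
```

The first command writes a simulated accession (`panel.fasta`,
`clones.fasta`, `truth.tsv`, `regions.tsv`). The second runs the whole
workflow; for seed 5 the sorting stage prints

```
groups  5
recombinants    3
```

meaning the 30-clone library resolved into 5 sequence groups after 3
clones were excluded as PCR recombinants. `out/k2p.tsv` holds the
representative-to-representative K2P matrix (for this seed the first
entries are 0.024, 0.020, 0.043 … — within-accession homoeolog divergences
of 2–4%), `out/pseudogene_screen.tsv` the stop-codon/frameshift verdicts,
`out/kaks.tsv` the pairwise Ka/Ks classifications, and `out/mp_stats.tsv`
the parsimony tree length with its consistency and retention indices
(`length 54, CI 0.981, RI 0.952` for this seed: nearly homoplasy-free, as
expected for a clean four-lineage mixture). Every output directory carries
a `manifest.json` with the seed and parameters; reruns are byte-identical.

The same operations are available as a library:

```python
import numpy as np, homeosort as hs

cfg = hs.SimConfig(seed=5)
rng = np.random.default_rng(cfg.seed)
panel, tree, regions = hs.simulate_progenitors(cfg, rng)
clones, truth = hs.simulate_clone_library(panel, cfg, rng)
grouping = hs.sort_clones(clones)
print(len(grouping.groups), grouping.recombinant_ids)
```

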