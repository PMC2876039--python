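# hoxclans

Similarity-network classification of Hox-like protein families, comparing
three sequence-region definitions: the 60-residue homeodomain core, an
*extended* homeodomain running from the YPWM/W motif through the linker to
the core's C-terminus, and the full-length protein.

Hox proteins share a nearly identical DNA-binding homeodomain, which is why
homeodomain-only phylogenies collapse the functionally distinct central
groups into one unresolved cluster, and why full-length comparisons tend to
sort proteins by lineage (clade) rather than by orthology group.  The
classification signal that separates the central groups sits just upstream
of the homeodomain, in the short cofactor-interaction motif (YPWM, or a
single W in posterior paralogs) and the linker between motif and domain.
`hoxclans` implements the whole pipeline needed to demonstrate and exploit
this — and ships a synthetic Hox-like family generator with known ground
truth so every stage is testable without downloading any database:

1. **Retrieval** — iterative PSSM search (PSI-BLAST-style; inclusion
   E < 1e-5, gathering E < 10, up to 50 iterations) of seed sequences
   against a protein database, plus exact-duplicate removal.
2. **Region extraction** — Plan-7-style profile HMMs built from seed
   alignments, calibrated on 5000 random sequences with an extreme-value
   fit; regions matching at E < 10 are extracted and records containing
   more than one homeodomain (concatemer mis-annotations) are removed.
3. **All-vs-all similarity** — exact Smith–Waterman with affine gaps and
   Karlin–Altschul statistics: `E = K·m·n·e^(−λS)`, `P = 1 − e^(−E)`.
4. **Clustering** — CLANS-style P-value-thresholded similarity graphs,
   deterministic force-directed 2-D/3-D layouts, connected-component
   clustering, seed-connected filtering, automated outlier flagging,
   cluster naming and stricter-cutoff subclustering.
5. **Region comparison** — the pipeline runs once per region definition on
   the same database and reports cluster counts, adjusted Rand index
   against the designed groups, clade purity, and which groups merge or
   split under each definition.

See `docs/methods.md` for the models, parameter choices and limitations.

## Worked example

Run the full pipeline on the generated benchmark (215 records: 7 groups ×
2 clades × 10 members, 20 decoy sister-family sequences, 50 background
proteins, 3 concatemers, 2 hyper-diverged outliers):

```sh
hoxclans all --seed 7 --out run7 -v
```

which logs, among other things:

```
INFO all: 215 records generated, 215 after dedup
INFO all: retrieval gathered 165 records
INFO compare[core60]: 142 records, 5 clusters, ARI=0.621
INFO compare[extended]: 142 records, 7 clusters, ARI=1.000
INFO compare[full]: 142 records, 5 clusters, ARI=0.112
```

Reading the three lines: clustering on the homeodomain core alone finds
only 5 clusters for 7 designed groups (ARI 0.62) because the central
triplet's near-identical cores merge into one cluster; the extended
homeodomain resolves all 7 groups perfectly (ARI 1.00); and full-length
clustering is dominated by clade-specific flanks, so its clusters are
clade-pure but split every group across clades (low ARI against groups).
The output directory contains the generated database and truth table, the
retrieval hits, per-region cluster reports with group names and outlier
flags, a three-region comparison digest (`comparison.txt`), and
CLANS-compatible map files (`map_*.clans`) with the graph, layout
coordinates and edge P-values.  Re-running with the same seed reproduces
every file byte for byte.

The same stages are available as a library:

```python
from hoxclans import (GeneratorConfig, generate_benchmark, blosum62,
                      karlin_altschul_params, compare_regions)

bench = generate_benchmark(GeneratorConfig(rng_seed=7))
report = compare_regions(
    bench.records, bench.truth,
    {"core60": bench.seed_alignment("core60"),
     "extended": bench.seed_alignment("extended")},
    bench.seed_ids,
)
print(report.to_text())
```

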