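# tetrasieve

Tetranucleotide-signature **sieving**: pre-select closely related
(candidate intraspecies) genome pairs so that expensive whole-genome
ANI/PSG species demarcation only has to run on a small fraction of all
pairs. The package also implements the ANI / PSG definitions over
NUCmer `.delta` alignments and a seeded simulator for validating the
sieve end to end without any external downloads.

## How it works

1. **Pre-processing** (`genome_io`) — sequences `< 1 kb` are discarded;
   draft genomes are concatenated into a single sequence after sorting
   contigs by a naive-Bayes posterior under a tetranucleotide Markov
   model trained on the whole genome.
2. **Fragmenting** (`fragment_signature`, `tetra_core`) — the genome is
   divided by a sliding `l`-kb window with `0.5 l` overlap (genomes of
   40–800 kb always yield 8 fragments with `l = L/4`; larger genomes use
   `l = L/4` when the average contig exceeds 200 kb, otherwise
   `l = 200 kb`). Each fragment gets 136 canonical tetranucleotide
   z-values (double-stranded counts, maximal-order Markov expectation);
   the genome's representative vector (ZRF) averages the central 3–4
   values per channel across fragments.
3. **Cutoffs** (`calibration`) — the genome-specific cutoff is
   `GSC = mean − SD − 0.01` over fragment-vs-ZRF Pearson correlations
   (PCCDs). GSC is floored by the length-specific cutoff
   `LSC1 = mean_intra − sd_intra − 0.01`; when the raw GSC falls at or
   below `LSC2 = mean_intra − 2 sd_intra`, the genome is re-fragmented
   at 10 kb and the ZRF recomputed. A packaged calibration table
   (`data/default_lsc.tsv`, regenerable via `tetrasieve calibrate`)
   supplies the length-specific distributions; user tables are accepted
   as TSV.
4. **Determining** (`sieve_engine`) — a pair is sieved when the PCCD of
   the two ZRFs reaches `GSC_p = min(GSC_query, GSC_ref)`; queries that
   sieve nothing are rescued with their top-100 highest-PCCD references.
5. **Validation** (`ani_psg`, `synthetic_data`) — ANI and
   overlap-deduplicated PSG are computed from NUCmer `.delta` files;
   the simulator builds genomes from block mixtures of Markov models
   and genome pairs with exact target PSG (70–100 %) and completeness
   (10–100 %), plus sensitivity/specificity benchmarking.

Note on naming: the PCCD is the Pearson correlation coefficient itself
(not `1 − r`); **higher means more similar**, and thresholds are
"keep if PCCD ≥ cutoff".

## CLI

```bash
# simulate labeled genome pairs over a PSG x completeness grid
tetrasieve simulate --genomes 10 --length 1000000 --psg 70,80,90,100 \
    --completeness 10:100:10 --seed 1 --out simdir

# build a length-specific calibration table (from FASTAs or synthetic genomes)
tetrasieve calibrate --sim-genomes 8 --bins 10:200:10 --pairs 200 --seed 42 \
    --out lsc.tsv

# sieve all query x reference pairs
tetrasieve sieve --queries simdir/queries --refs simdir/refs \
    --calibration lsc.tsv --rescue-n 100 --out pairs.tsv --summary summary.json

# score a sieve run against truth labels
tetrasieve benchmark --pairs pairs.tsv --truth simdir/truth.tsv

# ANI / PSG from a NUCmer .delta file
tetrasieve anipsg --delta out.delta --l1 4600000 --l2 4500000
```

`tetrasieve sieve --config run.cfg` reads a `key = value` file mirroring
the flags (see `RunConfig` in `tetrasieve.cli_app`). All commands are
deterministic for a fixed `--seed`.

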