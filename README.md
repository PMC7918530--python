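# terminus

Alternative polyadenylation (APA) analysis for subcellular 3′-end RNA-seq.

Neurons localize mRNA isoforms with different 3′ UTR lengths to different
compartments: a transcript may use a promoter-proximal poly(A) site (PAS) in
axons and a distal one in the cell body, and short 3′ UTR isoforms can even
arise locally by cleavage of a long isoform. Detecting this requires
(1) annotating 3′ UTR isoform ends de novo from sequencing coverage — genome
annotations miss most of them in the rat — and (2) statistics for
proximal-versus-distal PAS usage between two compartments.

`terminus` implements that pipeline for 3′-biased coverage, the profile
produced by linear-amplification 3′-end RNA-seq where reads accumulate in
the last ~read length of every transcript:

1. **End annotation** (`end_annotation`). Expressed regions from a sliding
   window (depth ≥ 7 at more than 80 of 100 positions), merged across poorly
   mappable gaps, assigned to annotated 3′ UTRs (or to the closest upstream
   UTR within 10 kb with nothing in between). Within each longest expressed
   3′ UTR, coverage is smoothed by a 150-nt running median and segmented by
   an exact dynamic program maximizing a piecewise-constant negative-binomial
   likelihood (≤ 10 segments; a Gaussian model on log2 coverage for the
   log-scale runs). Change-points where the mean drops are candidate 3′
   ends; candidates from the four runs ({cell body, axon} × {raw, log2}) are
   single-linkage clustered at 50 nt, keeping the most promoter-distal
   member of each cluster.
2. **Quantification and expression calls** (`isoform_quant`). Reads in the
   terminal 500 nt of each isoform; log10 densities are bimodal, and a
   two-component Gaussian mixture (EM) separates background from expressed.
   An isoform is called when every replicate has < 5% background posterior,
   or any replicate has > 10% expressed posterior.
3. **Differential PAS usage** (`differential_apa`). For each transcript's
   outermost called pair,

       S1 = log2(I_prox/I_dist)_CB − log2(I_prox/I_dist)_axon
       S2 = (I_prox/(I_prox+I_dist))_CB − (I_prox/(I_prox+I_dist))_axon

   with a two-sided Fisher exact test on summed raw counts and BH-FDR.
   Proximal shift in axons: S1 ≤ −1, S2 ≤ −0.15, FDR < 0.01 (distal:
   mirrored signs); a stringent flag marks pairs whose cell-body proximal
   fraction is ≤ 0.2 (or ≥ 0.8).
4. **PAS motifs and atlas recovery** (`pas_analysis`), scanning −100..+50 nt
   around each end for the 12 canonical/non-canonical PAS hexamers, and
   **cleavage-fragment mapping** (`cleavage_mapping`), binning clone 5′ ends
   by distance from a predicted cleavage site in 50-nt bins.
5. **Synthetic data** (`synthetic_data`): a generator that plants tandem
   isoform structure, negative-binomial counts, end jitter and Poisson
   background on a synthetic chromosome, with a machine-readable truth
   table, so every stage can be scored against ground truth.

## Worked example

The bundled three-isoform IMPA1 locus plants 3′ UTR ends at 451 nt
(axon-specific; withheld from the input GTF), 1128 nt (cell-body restricted)
and 1248 nt (both compartments), and recovers them from coverage alone:

```python
from terminus import SimConfig, impa1_fixture, simulate_dataset, annotate_ends
from terminus.synthetic_data import COMPARTMENTS

ds = simulate_dataset([impa1_fixture()], SimConfig(seed=1))
pooled = {c: ds.pooled_track(c) for c in COMPARTMENTS}
isoforms, log = annotate_ends(pooled, ds.transcripts)
for iso in isoforms:
    print(f"{iso.transcript_id}  end={iso.end}  utr_length={iso.utr_length}  {iso.provenance}")
```

```
T_IMPA1  end=5468  utr_length=469  novel
T_IMPA1  end=6127  utr_length=1128  ensembl
T_IMPA1  end=6247  utr_length=1248  ensembl
```

The hidden short end is rediscovered as a `novel` isoform 18 nt from its
planted position (segmentation reports the most distal member of the
candidate cluster, so novel ends carry a small distal bias within the 50-nt
cluster radius); the two annotated ends are found and snapped exactly.

The same objects drive the downstream stages; `terminus run` executes all
six on a simulated dataset. A typical differential row for a planted
proximal shift looks like

```
transcript_id  I_prox_CB  I_dist_CB  I_prox_ax  I_dist_ax     S1      S2       fdr          shift
T0000              127.7      139.9      221.4       47.1  -2.37   -0.35   8.3e-17  proximal_in_axon
```

i.e. the proximal isoform dominates in axons (S1, S2 < 0) at an FDR far
below the 0.01 threshold.

## Command line

```bash
terminus simulate --out sim/ --seed 3
terminus annotate --gtf sim/annotation.gtf \
    --coverage cell_body=sim/cell_body_rep0.plus.bedGraph \
    --coverage cell_body=sim/cell_body_rep1.plus.bedGraph \
    --coverage axon=sim/axon_rep0.plus.bedGraph \
    --coverage axon=sim/axon_rep1.plus.bedGraph \
    --out-ends ends.bed
terminus quantify --ends ends.bed --coverage cell_body_rep0=... \
    --out-counts counts.tsv --out-calls calls.tsv
terminus diffapa --counts counts.tsv --calls calls.tsv --out diffapa.tsv
terminus pas --ends ends.bed --genome sim/genome.fa --out-prefix pas
terminus clones --positions sim/clones.tsv --site 12345 --out hist.tsv
terminus run --out results/   # all stages, one seed, one manifest
```

Coverage is stranded bedGraph (0-based half-open), annotation is
Ensembl-dialect GTF, isoform ends are BED6 with the provenance encoded in
the score column. All tunables live in a flat YAML config (`terminus run
--config cfg.yaml`); flags override the file.

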