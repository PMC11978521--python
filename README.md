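# spotdecon

Spot-level spatial transcriptomics deconvolution, single-cell decomposition
and spatial imputation — with a built-in ground-truth simulator and
benchmarking metrics, so the whole pipeline is testable offline.

Given (1) a spot × gene count matrix from a sequencing-based ST platform
(e.g. Visium), (2) an annotated scRNA-seq count matrix and (3) nucleus
centroid coordinates from any upstream segmenter, the pipeline:

1. **reference** — selects per-type marker genes (fold-change quantile,
   one-sided Welch z-test, coverage rate) and builds a per-type
   gene-proportion signature matrix by pooled-count maximum likelihood;
2. **geometry** — assigns nuclei to capture areas (boundary-inclusive
   radius test) and counts nuclei per spot;
3. **deconvolution** — fits a multinomial generative model with a
   contribution simplex `Q` per spot and gene-wise log2 batch effects `r`
   (MAP or mean-field variational inference, analytic gradients, Adam),
   then converts contribution scores to cell-number proportions;
4. **decomposition** — apportions each spot's nuclei into integer type
   counts (largest-remainder, L1-optimal), splits the spot's full-genome
   counts across types by posterior-mean weights (gene totals conserved
   bit-exactly) and emits per-nucleus inferred single-cell profiles;
5. **imputation** — per-type Gaussian-process regression over spot centers
   predicts proportions at out-spot nuclei, types are sampled from the
   predicted simplex, and expression is imputed by Gaussian-kernel
   smoothing of nearby per-cell type profiles.

A simulator (`spotdecon.simulation`) samples annotated scRNA cells into
spots on a hex/square grid with planted spatial patterns, scatters nuclei
inside and outside spots, and corrupts counts with batch effects,
artificial zeros and multiplicative noise at three severity presets.
`spotdecon.evaluation` implements six per-spot proportion metrics
(absolute/square error, Jensen-Shannon distance, Pearson, cosine,
fraction of cells correctly mapped).

## CLI

One entry point with a subcommand per stage:

```sh
# simulate a dataset with ground truth
spotdecon simulate --scrna sc.mtx --rows sc.rows.txt --genes sc.genes.txt \
    --labels sc.labels.csv --pattern blocks --spots 100 --noise medium \
    --seed 7 --out sim/

# build the marker signature
spotdecon reference --scrna sc.mtx --rows sc.rows.txt --genes sc.genes.txt \
    --labels sc.labels.csv --out signature.csv --markers markers.csv

# estimate proportions
spotdecon deconvolve --st sim/st.mtx --rows sim/st.rows.txt \
    --genes sim/st.genes.txt --signature signature.csv --out proportions.csv \
    --iterations 8000 --seed 7

# score against truth
spotdecon evaluate --est proportions.csv --truth sim/truth_proportions.csv \
    --out report.csv

# or run everything from one JSON config
spotdecon pipeline --config run.json --out out/
```

`spotdecon decompose` and `spotdecon impute` cover the remaining stages;
see `spotdecon <cmd> --help`. The pipeline config is a JSON object with
the input paths (`st_mtx`, `scrna_mtx`, `positions_csv`, …), a master
`seed`, and optional `params` overriding any `PipelineConfig` field. A
`manifest.json` with input hashes and derived per-stage seeds makes reruns
byte-identical.

## Layout

- `src/spotdecon/io.py` — domain types (counts, geometry, nuclei, config) and all readers/writers
- `src/spotdecon/reference.py` — marker selection, signature construction
- `src/spotdecon/geometry.py` — nucleus-to-spot assignment, toy segmenter
- `src/spotdecon/deconvolution.py` — generative model and inference
- `src/spotdecon/decomposition.py` — integer apportionment, spot decomposition, per-cell split
- `src/spotdecon/imputation.py` — GP proportion field, out-spot annotation/expression
- `src/spotdecon/simulation.py` — truth patterns, spot simulator, synthetic reference
- `src/spotdecon/evaluation.py` — six proportion metrics, pseudo-spot re-merge, benchmark report
- `src/spotdecon/pipeline.py`, `cli.py` — orchestration and the `spotdecon` command
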