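# gratiomap

Compare five myelin-sensitive MRI measures and the aggregate g-ratio maps
derived from them, end to end, on a synthetic multi-modal brain-phantom
cohort with healthy and lesioned subjects.

The five myelin measures are:

| channel    | source data                         | MVF model                |
|------------|-------------------------------------|--------------------------|
| MWF_NNLS   | multi-echo spin-echo (48 echoes)    | hydration model (κ_my = 0.36, κ_nm = 0.86) |
| MWF_SPIJN  | same data, joint-sparsity fit       | hydration model          |
| ihMTR      | 4 MT-weighted images + reference    | calibrated linear scaling |
| MTsat      | T1w/PDw/MTw gradient-echo triple    | calibrated linear scaling |
| MTV        | calibrated proton density (1 − PD)  | identity surrogate       |

Each myelin volume fraction (MVF) is combined with diffusion-model signal
fractions (v_ic, v_iso) into an axonal volume fraction
`AVF = (1 − MVF − NMVF)·(1 − v_iso)·v_ic` and an aggregate g-ratio
`g = sqrt(AVF / (AVF + MVF))`. Linear scalings for the MT channels are
calibrated so the healthy-cohort mean splenium g-ratio hits a target
(default 0.7). VOI statistics (lesion erosion, perilesional shells,
tissue masks, group t-tests, Pearson correlations) complete the pipeline.

No patient data ships with the package: the `phantom` module simulates
every acquired contrast (EPG-based multi-compartment T2 decay, MT-weighted
quadruples, spoiled gradient-echo triples, noisy diffusion fractions) from
ground-truth microstructure, so everything is testable offline.

## Layout

- `src/gratiomap/phantom.py` — synthetic cohort + forward simulators
- `src/gratiomap/epg.py` — extended-phase-graph echo amplitudes
- `src/gratiomap/relaxometry.py` — MWF via regularized NNLS (with
  stimulated-echo / flip-angle correction) and via joint-sparsity fitting
- `src/gratiomap/mtmaps.py` — ihMTR, MTsat/R1/A_app, PD calibration, MTV
- `src/gratiomap/gratio.py` — MVF models, AVF, g-ratio, α calibration
- `src/gratiomap/voistats.py` — VOI morphology and cohort statistics
- `src/gratiomap/{volume,io,config,pipeline,cli}.py` — I/O (NIfTI-1 + JSON
  sidecars), configuration, orchestration, CLI

## CLI

```bash
gratiomap simulate --config cohort.yaml --out cohort/        # write NIfTI bundles
gratiomap fit-mwf --echoes sub/echo_series.nii.gz --mask sub/brain_mask.nii.gz \
    --algorithm nnls --out sub/MWF_NNLS.nii.gz
gratiomap mtmaps --manifest cohort/ms-00 --out maps/ms-00
gratiomap gratio --manifest cohort/ms-00 --maps-dir maps/ms-00 \
    --method mtv --out g/ms-00
gratiomap run-all --out results/                             # simulate + everything
```

`run-all` writes per-subject MVF/AVF/g maps for all five methods plus three
tidy CSV tables (`voi_means.csv`, `ttests.csv`, `correlations.csv`) and a
provenance JSON (config hash, seed, calibrated α values). Reruns with the
same config and seed are byte-identical.

Configuration is a flat YAML file mirroring `gratiomap.config.PipelineConfig`
(T2 grid, myelin window, regularization, SPIJN settings, ihMTR dialect,
PD calibration mode, κ constants, g target, cohort/noise parameters).

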