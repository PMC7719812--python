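# closurenet

Analysis pipeline for multimodal (EEG + fMRI) studies of **perceptual
closure** — the "filling-in" that lets observers identify fragmented
line drawings — and **repetition priming**, in a two-group design
(patients vs. controls). The package covers the full chain from
stimulus/design generation to directed functional connectivity, and
ships a synthetic-data module that emulates the behavioral, EEG and
BOLD structure of such a study so every stage can be verified against
known ground truth without any recordings.

## What it computes

**Stimulus & design generation** (`closurenet.design`). Pictures are
segment lists; segments are randomly and cumulatively deleted into 7
nested fragmentation levels, where the deleted proportion at level *L*
is 1 − 0.7^(L−1). Scrambled control images permute the tiles of a
16 × 16 grid. ERP blocks follow the ascending method of limits (AML):
10 pictures per block, 5 repeated after 1–2 intervening sequences (15
sequences/block), levels 6 → 3. fMRI sessions are blocked schedules at
TR resolution: 9-TR stimulus runs (primed / unprimed / scrambled) with
4-TR rests at block starts and between runs.

**ERP components** (`closurenet.erp`). Trials exceeding ±120 μV between
−100 and 500 ms are rejected; accepted trials are baselined to the
pre-stimulus mean and averaged per condition; component amplitudes are
window means — P1 (100–120 ms, PO5/PO6), N1 (170–200 ms, PO7/PO8), Ncl
(300–340 ms, PO7/PO8) — reported per hemisphere. Group/condition
effects use a mixed-model repeated-measures ANOVA with Cohen's *d*;
component–component Pearson correlations are computed per group.

**fMRI GLM** (`closurenet.glm`). Condition boxcars convolved with a
canonical double-gamma HRF (peak 6 s, undershoot 16 s, ratio 1/6),
per-voxel OLS with optional AR(1) prewhitening, *t* contrasts, ROI
means, and one-/two-sample group *t* tests (df = n−1 within,
n₁+n₂−2 between).

**Directed connectivity** (`closurenet.granger`) — the core. Series are
modeled as a VAR(p), x[n] = −Σᵢ A[i] x[n−i] + u[n], and pairwise linear
dependence is decomposed à la Geweke:

    F_x→y = ln( var(y | own past) / var(y | both pasts) )
    F_y→x = symmetric counterpart
    F_x.y = ln( var(x|pasts)·var(y|pasts) / det Σ_joint )
    F_x,y = F_x→y + F_y→x + F_x.y       (exact identity)

Granger causality maps (GCM) take an ROI mean as x and every voxel as
y; the difference map dGCM stores F_x→y − F_y→x (positive = ROI drives
voxel). Map thresholds come from circularly time-shifted surrogates of
the reference series with Benjamini–Hochberg FDR; group-level GCIs are
summarized by median/IQR and tested with Wilcoxon signed-rank and
rank-sum statistics.

**Synthetic data** (`closurenet.simulate`). A latent-threshold AML
observer; Gaussian-bump ERP components with per-group/condition
amplitudes; and a 4-node latent VAR network — dorsal stream (DS),
lateral occipital complex (LOC), prefrontal cortex (PFC), hippocampal
formation (HIPP) — driven by condition boxcars and projected into ROI
voxels through the HRF. Controls route closure through DS→PFC→LOC;
patients use DS↔LOC plus HIPP→DS. Ground truth is always returned.

## Worked example

```sh
closurenet run --seed 3 --outdir demo
cat demo/report.json
```

which prints (abridged):

```json
{
 "behavior_mean_identification_level": {
  "control_novel": 4.08, "control_repeat": 5.07,
  "patient_novel": 3.52, "patient_repeat": 4.33
 },
 "gci_significant_connections": {
  "control": ["DS->PFC", "LOC->PFC", "PFC->DS", "PFC->LOC"],
  "patient": ["DS->HIPP", "DS->LOC", "HIPP->DS", "LOC->DS"]
 }
}
```

Reading the numbers: simulated patients identify pictures at less
fragmented levels than controls (3.52 vs. 4.08) but gain a comparable
~1-level benefit from repetition — the behavioral signature of impaired
closure with intact priming. The connectivity stage recovers each
group's injected route from the primed-condition BOLD runs: the
prefrontal path in controls, the alternate occipito-hippocampal path in
patients (each connection appears with its mirror because
dGCI(B→A) = −dGCI(A→B) and the signed-rank test is two-sided).
Stage-by-stage equivalents: `closurenet simulate|erp|glm|gcm|report`,
each reading/writing CSV, `.npy`+JSON and NIfTI artifacts in the run
directory.

Library use:

```python
import numpy as np
from closurenet import geweke_measures

rng = np.random.default_rng(0)
x = rng.standard_normal(50_000)
y = np.r_[0.0, x[:-1]] + rng.standard_normal(50_000)
print(geweke_measures(x, y, p=1))
# GciResult(f_x_to_y=0.6888..., f_y_to_x=1.4e-06, f_instantaneous=3.9e-06, ...)
```

F_x→y ≈ ln 2 ≈ 0.693 is the population value for a unit-gain lagged
copy in unit noise; the reverse and instantaneous terms are at their
null.

## Layout

```
src/closurenet/
  design.py      fragmentation, scrambling, ERP/fMRI presentation designs
  simulate.py    observer, EEG and network-BOLD generators (+ ground truth)
  containers.py  EpochSet/Evoked containers and .npy+JSON serialization
  erp.py         rejection, averaging, window amplitudes, group stats
  glm.py         canonical HRF, design matrices, per-voxel GLM, ROI tests
  granger.py     VAR, Geweke measures, GCM/dGCM, bootstrap+FDR, Wilcoxon
  pipeline.py    staged orchestration with per-stage seeds
  cli.py         closurenet simulate|erp|glm|gcm|report|run
```

See `docs/methods.md` for model assumptions, parameter choices, and
known limitations.
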