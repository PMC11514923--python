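# qt1bbb — quantitative-T1 mapping of blood–brain-barrier dysfunction

`qt1bbb` is a tested, end-to-end pipeline for studying gadolinium leakage
across the blood–brain barrier (BBB) with quantitative T1 relaxometry
(qT1), built around the study design used in focal epilepsy: each subject
receives one noncontrast qT1 scan and two contrast-enhanced qT1 scans
(one after interictal injection, one after ictal injection), and regional
leakage is quantified from subtraction maps of the three T1 volumes.

It is aimed at imaging-methods researchers who want to prototype, verify
and power such analyses on a fully synthetic digital phantom before (or
instead of) touching patient data: every stage — from the spoiled
gradient-echo signal model to the cohort statistics — is importable,
deterministic and covered by tests against independent oracles.

## The model in brief

**T1 estimation (VFA / DESPOT1).** The spoiled gradient-recalled echo
steady-state signal at flip angle α is

    S(α) = M0 · sin α · (1 − E1) / (1 − E1 · cos α),   E1 = exp(−TR/T1).

Acquiring several flip angles at fixed TR (default 16.4 ms, angles
4°/10°/18°/25°) and plotting S/sin α against S/tan α gives a line with
slope E1, so T1 = −TR / ln(slope) per voxel.

**Contrast.** Gadolinium shortens T1 by fast-exchange relaxivity,
1/T1_post = 1/T1_pre + r1·C (default r1 = 5 L·mmol⁻¹·s⁻¹). Intravascular
tracer stays in vessels; BBB dysfunction is modelled as a leakage
fraction λ ∈ [0, 1] of the concurrent vascular concentration reaching an
ROI's parenchyma.

**Biomarkers.** After rigid co-registration of the post-contrast
sessions onto the noncontrast volume,

    ΔqT1_ni = noncontrast − interictal     (interictal BBB dysfunction)
    ΔqT1_ip = interictal − postictal       (peri-ictal BBB dysfunction)

each normalized by the mean ΔqT1 over the superior sagittal sinus (SSS),
a vascular reference that cancels between-subject differences in
circulating gadolinium. Per-ROI means/SDs are read out for the whole
cortex, hippocampus, amygdala and piriform cortex, per hemisphere.

**Statistics.** Kruskal–Wallis across ROIs with Dunn's post hoc test
(Bonferroni, capped at 1), Glass' Δ against the whole cortex
(|Δ| > 0.8 flagged large), OLS models with duration×ROI interactions
under treatment coding (cortex reference), and memory-impairment
dichotomization at standardized score < 90.

## Worked example

Simulate one subject with 10% piriform leakage, run the imaging stages
and inspect the biomarkers:

```python
from qt1bbb import PhantomSpec, simulate_sessions, rigid_register
from qt1bbb.bbb_mapping import compute_delta, normalize_by_sss, roi_readout

spec = PhantomSpec(leakage_interictal={"piriform": 0.1}, seed=7)
ses = simulate_sessions(spec)                       # 3 sessions + labels
xf, ii_reg = rigid_register(ses.interictal, ses.noncontrast)
dmap = normalize_by_sss(compute_delta(ses.noncontrast, ii_reg, "ni"), ses.labels)
print(f"SSS reference: {dmap.sss_mean:.1f} ms")
print(roi_readout(dmap, ses.labels, erode_voxels=1)[["roi", "mean", "sd", "n_voxels"]])
```

```
SSS reference: 1213.8 ms
           roi      mean        sd  n_voxels
0       cortex  0.000446  0.012624     27674
1  hippocampus  0.000986  0.011747       320
2     amygdala -0.000350  0.012827       106
3     piriform  0.273217  0.012582       112
```

The piriform mean of ≈ 0.273 says its tissue lost about 27% of the
vascular T1 enhancement — the injected leakage — while the null ROIs sit
at the noise floor. (Exact numbers vary with the seed; these are from
`seed=7` as shown.)

The same flow is scriptable from the shell:

```bash
qt1 simulate --seed 7 --out subj/           # sessions + labels + truth CSV
qt1 run --config cohort.yaml                # full cohort -> CSVs + JSON
qt1 stats --cohort cohort.csv --scenario all
```

`qt1 run` takes a YAML config naming either simulated subjects or real
NIfTI volumes per session (plus an integer ROI label map), and writes a
tidy per-subject×ROI×hemisphere×kind table, scenario result tables, a
log with each subject's SSS normalization factor, and a config snapshot
that replays to byte-identical outputs.

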