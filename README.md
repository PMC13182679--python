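# gammaplan

Automated treatment planning for rotating gamma system (RGS) radiosurgery by
deep reinforcement learning.

Forward planning for gamma-unit stereotactic radiosurgery — Gamma Knife and
rotating gamma systems — means packing focused radiation *shots* into an
intracranial target: for each shot a planner picks a collimator size, a 3D
isocenter, and a relative weight, then inspects the resulting dose and
iterates. `gammaplan` frames that workflow as a sequential decision process
and trains a proximal policy optimization (PPO) agent, per case, to place
shots automatically. It is aimed at medical-physics researchers studying
automated planning algorithms; it operates on synthetic phantoms and binary
masks, not on clinical DICOM data.

## The model

A plan is a weighted list of shots on a 1 mm isotropic dose grid. Each shot
delivers a spherically symmetric dose kernel (full-arc rotational delivery):

    dose(v) = w · TMR(depth) · P_c(‖v − center‖)

where `P_c` is the collimator's radial dose profile (crossing 50% at the
nominal radius) and TMR is the tissue-maximum ratio at the shot's depth in a
spherical head phantom. Plans are normalised to the 50% isodose line: the
prescription dose is half the plan's maximum dose, recomputed after every
shot.

Plan quality uses the standard radiosurgery indices, with TV the target
volume, PIV the prescription isodose volume, and TV_PIV their intersection:

* coverage `Cov = TV_PIV / TV`
* selectivity `SI = TV_PIV / PIV`
* conformity index (RTOG) `CI = PIV / TV = Cov / SI`
* conformity index (Paddick) `CI = TV_PIV² / (TV·PIV) = Cov × SI`

The agent observes four binary mask channels — uncovered target (the
feasibility mask), the current 50% isodose region, the OAR union, and the
overdose region outside the target — through four 3D convolutional layers
(kernel 3, stride 1, padding 1). An executable-action mask restricts the
softmax to shots placed inside the uncovered target. The reward after each
shot is `ΔCov + ΔSI − 0.5·spill`, and an episode ends when `Cov ≥ 0.95` and
`SI ≥ 0.80`, when the target is fully covered, or at 30 shots. Training uses
clipped-surrogate PPO (lr 0.003, γ 0.99, ε 0.2, 5 epochs per update, batch
size 8) with a plain return-minus-value advantage. The best plan across
training episodes is retained, after a coordinate-ascent refinement of shot
weights. A deterministic greedy packing baseline provides an agent-free
reference.

All beam data are synthetic (logistic radial profiles, exponential TMR),
generated by the package; see `docs/methods.md` for every assumption and
parameter.

## Worked example

```python
import gammaplan as gp

beam = gp.packaged_beam_data()
case = gp.make_case(gp.PhantomSpec("sphere", volume_cc=0.9, seed=0))
run = gp.plan_case(case, beam, seed=0, iterations=50)

m = run.best_metrics
print(f"coverage      : {100 * m.coverage:.1f}%")
print(f"selectivity   : {m.selectivity:.2f}")
print(f"CI (RTOG)     : {m.ci_rtog:.2f}")
print(f"CI (Paddick)  : {m.ci_paddick:.2f}")
```

prints (about a minute on one CPU core):

```
coverage      : 98.1%
selectivity   : 0.97
CI (RTOG)     : 1.01
CI (Paddick)  : 0.95
```

The best plan (found here in episode 9, using 18 shots) covers 98.1% of the
0.9 cc spherical target with the prescription dose while keeping 97% of the
prescription isodose volume inside the target; both clinical thresholds
(coverage ≥ 95%, selectivity ≥ 0.8) are met, and a Paddick CI of 0.95 is a
highly conformal plan.

The same pipeline is available from the shell:

```sh
gammaplan phantom --kind sphere --volume-cc 0.9 --seed 0 --out case/
gammaplan plan --target case/target.nii.gz --seed 0 --iterations 200 --out plan/
gammaplan evaluate --plan plan/plan.json --target case/target.nii.gz --out eval/
gammaplan table2-check
```

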