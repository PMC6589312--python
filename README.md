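# hyperkds

Evaluation toolkit for **ordinal severity grading of conjunctival
hyperaemia** — the redness of the eye caused by dilated vessels in the
bulbar conjunctiva, graded 0 (none) to 3 (advanced) on the Japan Ocular
Allergy Society (JOAS) scale.

It is written for researchers who build or audit automated graders
(e.g. CNN classifiers of slit-lamp photographs) and need to answer the
question *"is this model as consistent as a panel of certified human
graders?"* without access to the original clinical images.  The package
provides:

* **Grade panels** — long-format tables of (image, rater, grade /
  ungradable / missing) responses, with CSV I/O and the
  two-grader-plus-specialist *adjudication* workflow that turns raw
  responses into reference labels.
* **Agreement** — quadratic-weighted Cohen's κ on the fixed 4-category
  scale, pairwise κ matrices, and the grader-qualification screen
  (qualified ⇔ κ against the reference strictly above 0.7).
* **Kappa distance score (KDS)** — the expert-referenced evaluation
  statistic.  With two expert pairs (A, B) and (C, D), each grading one
  half of the validation set,

  ```
  KDS = (κ_na + κ_nb − 2 κ_ab) + (κ_nc + κ_nd − 2 κ_cd)
  ```

  where κ_na is the responder's weighted κ against expert A, and κ_ab
  the experts' mutual κ.  A responder that agrees with each expert as
  well as the experts agree with each other scores 0; KDS > 0 is taken
  as clinically acceptable.
* **Ensembles** — the expert-referenced *half rule* (answer the expert
  grade if strictly more than half of the members match it) and *least
  rule* (a single match suffices), a mean-round combiner, iterative
  screening of models by mean inter-model κ (drop while ≤ 0.7), and the
  multimodel score KDS_(n,multi) = z(KDS_(n,half)) + z(KDS_(n,least))
  standardised across ensemble sizes n.
* **Image side** — grade-stratified augmentation planning (multipliers
  4/2/2/18 with mandatory mirroring), 256×192 preprocessing, a pluggable
  grade-classifier interface with a redness-feature baseline, and
  per-pixel-threshold **vessel-area occupancy** measurement.
* **Statistics** — Spearman rank correlation, tie-corrected
  Kruskal–Wallis, and Steel–Dwass all-pairs comparisons (analytic and
  permutation modes).
* **Synthetic data** — rater panels with controllable pairwise κ via an
  adjacency-error confusion model (with a closed-form expected κ), and
  conjunctiva-like images whose vessel density grows with grade, so the
  entire pipeline runs end-to-end on a desk.

## Worked example

Single-responder KDS from six weighted kappas (here, the published
values of a DenseNet201 grader against the two expert pairs):

```python
>>> from hyperkds import kds_single
>>> kds_single(0.693, 0.707, 0.748, 0.712, 0.643, 0.653).kds
-0.047
```

The score is just below zero: the network agrees with each expert almost
— but not quite — as well as the experts agree with each other.

The full synthetic replay (panel simulation → adjudication → grader
qualification → stand-in model training → screening → KDS ranking →
multimodel table → vessel-area statistics):

```python
>>> from hyperkds import RunConfig, replay
>>> rep = replay(RunConfig(seed=7, n_train=250, n_validation=250, out_dir="out"))
>>> [(d["responder"], round(d["kds"], 3)) for d in rep["single_kds"]]
[('M4', -0.204), ('M3', -0.258), ('M1', -0.275), ('M2', -0.38), ('M5', -0.394), ('M0', -0.424)]
>>> [round(v, 3) for v in rep["multimodel"]["kds_least"]]
[-0.025, 0.098, 0.135, 0.168, 0.23]
>>> rep["multimodel"]["best_n"]
5
>>> round(rep["vessel_area"]["spearman_rho"], 3)
0.898
```

Reading the output: no single stand-in model reaches KDS 0, but the
least-rule ensembles cross it from n = 3 members on — adding models
improves the chance that at least one of them matches the expert
grade — and the combined score picks the 5-model ensemble as the best
trade-off.  The ensemble's grades correlate strongly (ρ = 0.898) with
the measured vessel-area percentage, i.e. the discrete grading tracks
the continuous redness signal.

The same pipeline is scriptable from the shell:

```
hyperkds simulate --n-images 500 --seed 3 --out panel.csv
hyperkds kappa --panel panel.csv --raters A,B
hyperkds replay --seed 7 --out results/
```

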