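# gaitsynergy

Muscle-synergy analysis of walking EMG: linear-envelope preprocessing,
nonnegative matrix factorization, VAF-based selection of the number of
synergies, and between-group comparison of synergy patterns and muscle
weights — with a seeded synthetic-EMG generator so the whole pipeline is
testable by parameter recovery.

## Who this is for

Movement scientists and biomechanists who record multi-channel surface
EMG during gait (here: gastrocnemius medialis GA, tibialis anterior TA,
vastus lateralis VL, gluteus maximus GM, biceps femoris BF at 1000 Hz)
and want a reproducible, scripted version of the standard synergy
workflow, including the statistics used to compare two cohorts (e.g. a
clinical group against controls).

## The model

Each subject's gait cycle is summarized as a nonnegative matrix
`M` (101 cycle points × 5 muscles) of normalized linear-envelope
amplitudes, factorized as

    M ≈ H W,   H ≥ 0 (101 × k),   W ≥ 0 (k × 5)

where column `j` of `H` is synergy `j`'s activation coefficient over the
cycle and row `j` of `W` its relative muscle weights (scaled to max 1).
Fit quality per muscle is the uncentered variance accounted for,
`VAF_m = 1 − Σ_t(rec − exp)² / Σ_t exp²`, and the number of synergies is
the smallest `k` with `VAF_m > 0.9` for every muscle. Factors are
estimated by Lee–Seung multiplicative updates with seeded multi-restart
and a warm start across `k` that makes the VAF curve monotone.
See `docs/methods.md` for the full account.

## Worked example

Simulate two groups of 10 subjects from a four-synergy ground truth
(moderate envelope noise, and a 1.5× increase of the VL weight in the
first synergy of group B), then run the full pipeline:

```python
import gaitsynergy as gs

perturb = {("B", "VL", 0): 1.5}
cfg = gs.RunConfig(seed=1, n_subjects=10, noise_sigma=0.1,
                   weight_perturbations=perturb)
model = gs.default_walking_model(seed=1, noise_sigma=0.1)
spec = gs.CohortSpec(n_subjects=10, weight_perturbations=perturb)
cohort = gs.generate_cohort(model, spec)
analysis = gs.analyze_cohort(cohort, cfg)

print(analysis.modal_k)                      # {'A': 4, 'B': 4}
rep = analysis.report
for t in rep.vaf_tests:
    print(f"k={t.k}: A {t.mean_a:.3f}  B {t.mean_b:.3f}  p={t.p:.3f}")
for t in rep.weight_tests:
    if t.significant:
        print(f"synergy {t.synergy+1} {t.muscle}: "
              f"A {t.mean_a:.3f}  B {t.mean_b:.3f}  p={t.p:.4f}")
```

Output:

```
{'A': 4, 'B': 4}
k=1: A 0.629  B 0.640  p=0.009
k=2: A 0.787  B 0.793  p=0.022
k=3: A 0.923  B 0.927  p=0.026
k=4: A 1.000  B 1.000  p=0.631
synergy 1 VL: A 0.307  B 0.397  p=0.0065
synergy 4 GA: A 0.017  B 0.038  p=0.0360
synergy 4 TA: A 0.134  B 0.076  p=0.0070
```

Both groups select four synergies (the VAF > 0.9 rule is first met at
k = 4, where global VAF ≈ 1.000 and does not differ between groups).
The planted VL increase in synergy 1 is recovered as a significant
group difference in exactly that cell (0.31 → 0.40, p = 0.007); the two
additional synergy-4 flags are the kind of secondary/false positives an
uncorrected 20-cell scan produces, which is why the report also carries
Shapiro–Wilk p-values and an optional Holm correction.

## Command line

```bash
synergy simulate   --config cohort.yaml --out cohort/
synergy preprocess --emg cohort/group_A/subject_00_emg.csv \
                   --events cohort/group_A/subject_00_events.csv \
                   --out matrix.csv
synergy extract    --matrix matrix.csv --threshold 0.9 --seed 1 --out dec/
synergy compare    --group-a decsA/ --group-b decsB/ --out report/
synergy run        --config cohort.yaml --out run/     # all of the above
```

All tabular I/O is CSV with documented headers, metadata is JSON, and a
`run` directory contains a manifest (config echo, checksums, warnings)
sufficient to reproduce every output byte.

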