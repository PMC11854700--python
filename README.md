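# hipsono

Automated analysis of infant-hip (Graf-style) B-mode ultrasound frames:

1. **Apex-point estimation** — a trainable per-pixel heatmap estimator
   (reference backbone: a small numpy patch network trained with pixelwise
   binary cross-entropy) locates the apex of the ilium; an oracle mode
   passes ground truth through for isolated testing of later stages.
2. **Signal-heterogeneity ridge extraction** — local intensity maxima
   inside a 10-pixel-wide region of interest anchored at the estimated
   apex are thinned to one per row and fitted with an orthogonal
   least-squares line; frames whose iliac angle falls outside the
   87–93° verticality band are disqualified.
3. **Alpha angle and DDH classification** — the acetabular-roof edge is
   the topmost local maximum in a search rectangle infero-medial to the
   apex; maxima inside the sector between the horizontal and the
   45°-descending ray from that edge define the roof ridge line. The
   angle between the two ridge lines is the alpha angle; alpha < 60°
   classifies the hip as dysplastic (DDH).
4. **Evaluation statistics** — ROC/AUC (Mann–Whitney, ties 0.5),
   sensitivity/specificity at the 60° cutoff, pooled-variance Student
   t-tests, Benjamini–Hochberg FDR adjustment, and a
   qualified-vs-disqualified rater-error comparison.

Because no clinical data ship with the package, a **synthetic phantom
generator** (`hipsono.phantom`) renders B-mode-like frames with exact
ground truth — bright textured bone ridges at controlled iliac and alpha
angles, multiplicative Rayleigh speckle, reverberation ghost echoes,
soft-tissue distractor streaks and blur — so every stage is testable
end to end.

## Test

```bash
python -m pytest -q tests/
```

`tests/test_acceptance.py` holds the acceptance suite: oracle-equivalence
checks (brute-force local-maxima scan, brute-force total-least-squares
minimizer, brute-force AUC/BH-FDR/t statistics), angle-recovery
tolerances on clean and artifact-laden phantoms, end-to-end ROC AUC, and
apex-estimator training sanity. The full suite runs in a few minutes on
one CPU.

## CLI

```bash
hipsono phantom generate --n 50 --seed 1 --out cohort/      # frames + manifest.csv
hipsono apex train cohort/manifest.csv --out model.pkl      # train heatmap estimator
hipsono apex predict model.pkl cohort/phantom_00000.png     # eAP as JSON
hipsono ridge assess IMG --eap X Y [--surface-out s.csv]    # quality gate + 3D export
hipsono alpha measure IMG --eap X Y                         # alpha angle + DDH call
hipsono pipeline run cohort/manifest.csv --out results.jsonl [--model model.pkl]
hipsono evaluate cohort/manifest.csv results.jsonl          # AUC / sens / spec report
```

`pipeline run` without `--model` uses the manifest's annotated apex
(oracle mode). A YAML file passed with `--config` overrides
`PipelineConfig` fields (gate bounds, max-filter neighborhood, roof
rectangle extents, DDH cutoff inclusivity, ...).

## Library quick start

```python
from hipsono import apex, pipeline
from hipsono.phantom import PhantomParams, generate_phantom

img, truth = generate_phantom(PhantomParams(alpha_deg=55.0, seed=7))
verdict = pipeline.run_pipeline(img, apex.OracleApexEstimator(truth.apex))
print(verdict.status, verdict.quality.iliac_angle_deg, verdict.alpha.alpha_deg, verdict.ddh)
```

Coordinates are (x, y) with the origin at the top-left, x rightward and
y downward; orientation angles are measured from the +x axis in
[0, 180) with 90 = vertical.
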