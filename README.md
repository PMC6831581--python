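# synreach

Muscle-synergy analysis of reaching EMG and its association with myofascial
trigger points (TPs).

Myofascial trigger points — hyperirritable spots in taut bands of skeletal
muscle, *active* when palpation reproduces familiar pain and *latent*
otherwise — have long been suspected of altering motor control beyond the
single hosting muscle. One way to ask the question at the multi-muscle level
is through **motor modules** (muscle synergies): surface-EMG envelopes
`X` (muscles × time) recorded during center-out reaching are factorized by
non-negative matrix factorization as

```
X ≈ S · P
```

with nonnegative muscle weightings `S` (muscles × k) and activation signals
`P` (k × time). Reconstruction quality is the variance accounted for,
`VAF = 1 − SSE/SST`, and the number of modules k is chosen at the inflexion
point of the VAF-vs-k curve. A muscle is *dominant* in a module when its
weighting reaches 0.3 of the module's maximum. The scientific question then
becomes statistical: **do muscles hosting an active TP carry higher
weighting coefficients when they are dominant in a module?** — tested with
mixed-effects / permutation contrasts, and guarded against palpation
misclassification by re-running the contrast under thousands of randomly
regenerated TP grids.

Raw recordings for this protocol are not publicly deposited, so `synreach`
pairs the complete analysis chain with a synthetic study generator whose
ground truth (three-module structure, directional tuning, tonic baseline,
TP labels, and an optional injected active-TP weighting effect) makes every
stage testable. The one piece of real data is the published palpation table
(15 subjects × 13 muscles), shipped as a plain-text fixture.

The package is aimed at motor-control and rehabilitation researchers who
want a tested, reproducible reference implementation of this pipeline —
EMG preprocessing, NMF synergy extraction, dimensionality selection,
cross-subject module matching, dominance labeling and the TP association
statistics — and at methodologists studying the statistical behavior of
such pipelines under a known generative model.

## Worked example

Simulate a 15-subject study with an injected active-TP effect
(`delta = 0.5` added to the weighting of every dominant muscle hosting an
active TP before EMG synthesis), run the full pipeline at the common
dimensionality k = 3, and test the association plus its robustness to
random TP grids:

```python
from synreach import pipeline, synthgen

config = synthgen.GenerativeConfig(seed=7, tp_effect_delta=0.5)
result = pipeline.run_study(config, engine="perm", n_perm=999, sweep=False,
                            force_k=3, n_grids=200, seed=7)

print("cross-subject NDP =", round(result.extraction.match.average_ndp, 3))
c = result.contrast.contrast("ACT", "NO", "DOMINANT")
print(f"ACT-NO (dominant): MD = {c['estimate']:.3f}, "
      f"95% CI [{c['ci_low']:.3f}, {c['ci_high']:.3f}], p = {c['p']:.4f}")
g = result.grid_null
print(f"random grids within CI: {g.n_within}/{g.n_grids}")
```

prints

```
cross-subject NDP = 0.98
ACT-NO (dominant): MD = 0.298, 95% CI [0.171, 0.433], p = 0.0010
random grids within CI: 1/200
```

Read: modules match across subjects almost perfectly (normalized dot
product 0.98); dominant muscles with an active TP carry weighting
coefficients 0.30 higher (on the unit-maximum scale) than dominant muscles
without a TP, a significant difference; and only 1 of 200 randomly
regenerated TP grids reproduces a difference inside that CI, so the
association is not an artifact of where the TP labels happen to sit.

The same pipeline is available from the shell:

```sh
synreach all --seed 7 --out report.json          # in-memory end to end
synreach simulate  --out study/                  # write a study to disk
synreach preprocess --study study/ --out pre/    # envelope matrices X
synreach extract    --inputs pre/ --out ext/     # NMF sweep + matching
synreach associate  --extracted ext/ --tp-table pre/tp_table.tsv \
                    --out assoc.json             # statistics + grid null
```

The bundled palpation table loads with
`tpstats.load_tp_table(tpstats.bundled_palpation_path())`; `tpstats.count_tp`
reproduces the published tally (13 active and 50 latent TPs over 195
examined muscles).

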