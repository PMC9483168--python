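# flimdr

Phasor-FLIM metabolic drug-response scoring for 2-D cultures, spheroids and
patient-derived tumor explants, with a synthetic TCSPC generator for validation.

## The problem

NAD(P)H is an autofluorescent metabolic cofactor whose fluorescence lifetime
differs between its free (short-lived, ~0.4 ns, glycolysis-associated) and
enzyme-bound (long-lived, ~3.4 ns, oxidative-metabolism-associated) states.
Time-correlated single-photon counting (TCSPC) FLIM records a per-pixel photon
arrival-time histogram; label-free imaging of the free/bound NAD(P)H balance
therefore reads out a cell's metabolic state. When a tumor responds to a
cytotoxic drug, its metabolism shifts toward the oxidative, bound-NAD(P)H-rich
phenotype of less proliferative cells — a shift this package detects,
quantifies and classifies, replicate images in, responder class out.

## The method

1. **Phasor transform.** Each pixel's decay histogram `I_k` over time bins with
   centers `t_k` maps to `g = Σ I_k cos(nωt_k)/ΣI_k`, `s = Σ I_k sin(nωt_k)/ΣI_k`
   at the laser angular frequency `ω = 2π f_rep` (harmonic `n`, default 1).
   Mono-exponential decays lie on the universal semicircle
   `(g−½)² + s² = ¼`; two-species mixtures lie on the chord between the two
   pure-species points. Pixels below a photon threshold (default 50) are masked;
   an optional reference acquisition of known lifetime corrects instrument
   phase and modulation.
2. **Free/bound fraction.** Each pixel's phasor is projected orthogonally onto
   the chord joining the free and bound NAD(P)H reference phasors; the
   projection parameter (clamped to [0, 1]) is the free fractional intensity
   `f_free`.
3. **Fractional distribution curve.** Per image, the valid pixels' `f_free`
   values are histogrammed into 125 uniform segments of [0, 1] and normalized
   to unit mass.
4. **%DR.** For one timepoint, the 6–12 replicate curves of the treated arm are
   compared with the control arm segment by segment using a two-sided
   pooled-variance Student's t-test (no multiple-testing correction);
   segments with p < 0.05 are significant, and

   `%DR = 100 × Σ_significant h_treated / Σ_all h_treated`

   on the treated mean curve.
5. **Final score and class.** Per-timepoint %DR values at 24/48/72 h are
   combined as a weighted average with weights 1/2/3 (72 h dominates as the
   standard time of metabolic adaptation), then stratified:
   NR (< 5), LR (5–20), MR (20–50), HR (≥ 50); NR maps to Non-Resp,
   everything else to Resp.

The `synthetic_flim` generator produces TCSPC stacks from wrapped
two-exponential mixtures with Poisson photon noise, pixel-level and
replicate-level variability, and a configurable treated-arm shift toward bound
NAD(P)H — with per-pixel ground truth retained for recovery tests.

## Worked example

```bash
$ flimdr run-demo --out demo_out --seed 0
responder: final %DR = 92.7 (HR)
non_responder: final %DR = 1.9 (NR)
```

The responder case simulates a treated arm shifted 0.2 toward bound NAD(P)H at
every timepoint (8 replicates/arm, 32×32 px, 10⁴ photons/px): nearly the whole
treated curve mass lies in significantly different segments, so the
per-timepoint %DRs (91.9, 93.5, 92.5 at 24/48/72 h in `responder/report.json`)
average to a final 92.7 %DR → High Responder. The flat case draws both arms
from the same distribution: only scattered false-positive segments reach
p < 0.05, giving a final 1.9 %DR → Non-Responder.

An end-to-end run on files instead of in-memory data:

```bash
flimdr simulate --out sim_case --shift 0.2 --seed 7        # TIFF stacks + manifest
flimdr score --manifest sim_case/manifest.yaml --out report
```

`report/report.json` holds the per-timepoint and final %DR and the class;
`report/score_72h.csv` holds the 125-segment table (control/treated mean
heights, p-values, significance).

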