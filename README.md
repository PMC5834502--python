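# thzcoag

Terahertz time-domain spectroscopy (THz-TDS) of blood coagulation, as a
reproducible analysis pipeline: a synthetic generator for fluidic-chamber
blood measurements, the iterative Fresnel-corrected extraction of the
complex refractive index, and the cohort statistics that quantify how
thrombus formation changes sub-THz absorption.

Sub-THz absorption of blood is dominated by liquid water's picosecond
relaxation dynamics.  When platelets initiate the coagulation cascade, the
resulting protein-solvation changes reshape the absorption spectrum: below
a *transparency frequency* f_t the coagulating blood absorbs less than
uncoagulated blood ("THz defect"), above it more ("THz excess"), and f_t
red-shifts with platelet count.  That makes low-frequency (200-270 GHz)
THz transmission a sensitive, label-free probe of early thrombus
formation.  This package lets you study the whole measurement-and-analysis
chain for that phenomenology at desk scale, with synthetic cohorts whose
effect structure is calibrated to the printed clinical anchors.

## What is inside

| layer | contents |
|---|---|
| `thzcoag.water` | double-Debye water permittivity, complex index n̄ = n + iκ |
| `thzcoag.chamber` | PE-windowed fluidic-chamber transfer model, Fresnel terms, optional first-order etalon echo |
| `thzcoag.instrument` / `thzcoag.cohort` | source pulse, noise model, hematology covariates, coagulation effect model, cohort synthesis |
| `thzcoag.extraction` | trace averaging, FFT conventions, Eqs for the first (κ₀, n₀) estimate and the fixed-point interface elimination, α = 2ωκ/c |
| `thzcoag.stats` | pooled t-tests with 95% CIs and significance stars, Pearson correlations, hematology filters, Δα/α spectra, transparency-frequency and PLT-stratified shift estimators |
| `thzcoag.pipeline` / `thzcoag.io` / `thzcoag.cli` | config (JSON-schema validated), simulate → extract → analyze → report, file dialects, provenance |
| `analysis/01..04_*.py` | narrative drivers writing tables under `results/` |

The core inversion: from the spectral ratio R(ω) = E_sample/E_ref of the
blood-filled to the empty chamber (thickness d),

    κ₀ = −(c/ωd)·ln|R|,       n₀ = 1 + (c/ωd)·Δφ,

then per frequency, with C(n̄) the ratio of the Fresnel interface terms,

    κ_{k+1} = −(c/ωd)·ln(|R|/|C(n̄_k)|),
    n_{k+1} = 1 + (c/ωd)·(Δφ − arg C(n̄_k)),

iterated until |Δn|, |Δκ| < 0.001, and α = 2ωκ/c in cm⁻¹.
See `docs/methods.md` for the full model and every default.

## Worked example

```python
from thzcoag.cohort import CohortConfig, synthesize_cohort
from thzcoag.pipeline import AnalysisSettings, analyze_cohort, extract_cohort

cohort = synthesize_cohort(CohortConfig(), seed=1)   # 29 early-coagulated + 28 uncoagulated
spectra = extract_cohort(cohort)                      # minute-average + inversion per subject
res = analyze_cohort(spectra, AnalysisSettings())

cmp = next(c for _, c in res["comparisons"] if abs(c.freq_thz - 0.27) < 0.01)
print(f"270 GHz: diff {cmp.mean_a - cmp.mean_b:+.1f} cm^-1, p = {cmp.p_value:.2g} {cmp.stars}")
d = res["deltas"]["early_coagulated"]
print(f"transparency frequency: {1e3 * d.transparency_freq_thz:.0f} GHz")
```

prints (seed 1):

```
270 GHz: diff -7.1 cm^-1, p = 2e-06 ***
transparency frequency: 705 GHz
```

i.e. early-coagulated blood absorbs ~7 cm⁻¹ *less* at 270 GHz than
uncoagulated blood (a highly significant group separation at n = 29 vs
28), while the fitted Δα/α line crosses zero near 0.7 THz for this
particular cohort draw — defect below, excess above.  Across replicate
cohorts the transparency frequency averages ≈ 0.68 THz, and stratifying
filtered early-coagulated subjects into 100-200 / 200-300 K/μL platelet
bins puts the crossing near 0.9 and 0.4 THz respectively — a ≈ −0.5 THz
red shift with higher platelet count.

The same chain runs from the shell:

```bash
thzcoag analyze --seed 1 --out results/pipeline   # simulate -> extract -> analyze
thzcoag report --out results/pipeline
thzcoag config-schema                             # JSON schema of every tunable
```

and step by step as the numbered scripts in `analysis/`.

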