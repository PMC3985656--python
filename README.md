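# g4ionx

Quantitative analysis of Na⁺/K⁺ cation exchange in intramolecular
G-quadruplexes (G4s), built around the NMR/CD characterization of the human
telomeric sequence Tel23, d[TAGGG(TTAGGG)₃].

G-rich telomeric DNA folds into four-stranded quadruplexes whose topology
and stability depend on the monovalent cation held between the stacked
G-tetrads. When K⁺ is titrated into the Na⁺-folded form, the spectra convert
rapidly — and the central question is whether that conversion proceeds
through global unfolding or through in-place ion replacement. `g4ionx`
implements the quantitative machinery needed to answer it from standard
NMR/CD observables:

- **Stepwise exchange equilibrium** — a three-state model (di-Na⁺ form *a* →
  mixed Na⁺·K⁺ form *b* → di-K⁺ form *c*) with species fractions

  ```
  fa = 1/D,   fb = K₁x/D,   fc = K₁K₂x²/D,   D = 1 + K₁x + K₁K₂x²
  ```

  fitted per residue to paired imino-intensity titrations, plus recovery of
  the unobserved intermediate by mass balance fb = 1 − fa − fc.
- **Kinetics** — mono- and bi-exponential fitting (variable projection,
  multi-start) for hydrogen–deuterium exchange (HDX) decays,
  hybridization-trap decays and real-time CD conversion traces; condition
  means, SDs and fold-stabilization ratios with propagated uncertainty.
- **NOE distances** — initial slopes of NOESY buildup series and r⁻⁶
  calibration against the thymine H6–CH3 reference (2.99 Å), grouped
  distance statistics by proton-pair class and Welch tests between cation
  conditions.
- **Topology inference** — G-tetrads as directed imino→aromatic NOE
  4-cycles, syn/anti glycosidic calls from intra-residue H1′–H8 distances,
  strand orientations by parity constraints, loop taxonomy
  (double-chain-reversal / lateral / diagonal) and a named fold label
  (propeller, basket, chair, hybrid-I/II, (2+2)).
- **CD melting** — baseline-subtracted derivative Tm extraction at 295 nm
  with a two-state sigmoid fit as cross-check.
- **Synthetic data** — seeded generators for every input above, with presets
  encoding the published Tel23 study conditions, so the entire pipeline runs
  and is tested without any experimental download.

See `docs/methods.md` for models, assumptions, defaults and limitations.

## Worked example

The `report` subcommand runs the full Tel23 walkthrough on synthetic data:

```bash
g4ionx report --seed 1 --out demo/
```

which prints (and writes to `demo/summary.json`):

```json
{
  "K1_per_M": 59.7,
  "K2_per_M": 2.7,
  "cd_tau_fast_s": 80.0,
  "cd_tau_slow_s": 930.0,
  "cd_fast_amplitude_percent": 89.0,
  "hdx_mean_tau_na_min": 14.0,
  "hdx_mean_tau_nak_min": 136.0,
  "hdx_fold_stabilization": 9.714,
  "hybridization_mean_tau_min": 127.0,
  "tm_k_form_C": 68.88,
  "topology_label": "hybrid-I (3+1)",
  "loops": ["double-chain-reversal", "lateral", "lateral"],
  "noe_h8_h1_mean_A": 5.069
}
```

Reading the numbers: the joint titration fit returns the stepwise constants
K₁ = 59.7 M⁻¹ and K₂ = 2.7 M⁻¹ — the first K⁺ binds ~22× more favorably
than the second, implying a populated mixed-cation intermediate. The 265 nm
CD conversion is biphasic (τ = 80 s carrying 89% of the amplitude, plus a
930 s minor phase). HDX puts the global unfolding time at 14 min in Na⁺ but
136 min once K⁺ is added — a ~10-fold kinetic stabilization, corroborated by
the 127 min hybridization-trap constant: conversion (~80 s) is far faster
than unfolding (minutes to hours), so the Na⁺/K⁺ exchange cannot proceed
through a globally unfolded state. The K⁺-form melt gives Tm ≈ 68.9 °C, the
NOE engine classifies the fold as hybrid-I (3+1) with one antiparallel tract
and a double-chain-reversal loop first, and the mean intra-tetrad H8–H1
distance is ≈5.1 Å.

Per-stage subcommands (`simulate`, `fit-titration`, `fit-kinetics`,
`noe-distances`, `infer-topology`, `melting`) operate on the same CSV /
peak-list formats; the library API (`g4ionx.fit_exchange`,
`g4ionx.fit_biexp`, `g4ionx.infer_topology`, …) exposes everything
programmatically.

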