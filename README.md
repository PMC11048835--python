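# quenchbind

Quantitative analysis of fluorescence-titration binding experiments on
protein–polyphenol systems (the bundled defaults describe bovine
lactoferrin titrated with chlorogenic acid), for researchers who need the
standard quenching-to-thermodynamics workflow as tested, scriptable code
rather than a spreadsheet:

1. **Inner-filter correction** — `F_cor = F_obs · 10^((A_ex d_ex + A_em d_em)/2)`
   removes attenuation by an absorbing titrant.
2. **Stern–Volmer quenching** — OLS of `F_0/F = 1 + K_sv[Q]`; the apparent
   bimolecular rate constant `K_q = K_sv/τ_0` (τ_0 = 10 ns by default) is
   compared against the 2.0×10¹⁰ L mol⁻¹ s⁻¹ diffusion limit to label the
   mechanism static or dynamic, with K_A/K_sv temperature trends reported as
   corroborating evidence.
3. **Double-logarithm binding fit** —
   `log₁₀((F_0−F)/F) = n·log₁₀K_A + n·log₁₀[Q]_free` with the
   ligand-depletion term `[Q]_free = [Q] − [P](F_0−F)/F_0`, yielding the
   binding constant K_A, site number n, and a qualitative strength band.
4. **Van't Hoff thermodynamics** — OLS of `log₁₀K_A` vs `1/T` gives
   ΔH = −2.303·R·slope and ΔS = 2.303·R·intercept; ΔG = ΔH − T·ΔS; the
   (ΔH, ΔS) sign pattern classifies the dominant force (electrostatic,
   hydrophobic, hydrogen-bond/van der Waals) and flags
   spontaneity/exothermicity.
5. **Functional-assay calculators** — Folin–Ciocalteu standard curve and
   grafting efficiency, DPPH scavenging, solubility, foam
   expansion/stability, EAI/ESI emulsification indices, and digestion
   bioaccessibility.
6. **Synthetic titration generator** — static-quenching forward model with
   known ground truth (van't Hoff-generated K_A(T), depletion solved
   self-consistently, Beer–Lambert inner-filter attenuation, multiplicative
   reading noise), so every stage is testable end to end.

## Worked example

Simulate a study — a 10 μM protein titrated at ligand molar ratios
0–10 and read at 290/300/310 K — then run the full pipeline:

```sh
quenchbind simulate --seed 11 --out sim/
quenchbind run --input sim/titration.csv --absorbance sim/absorbance.csv --out out/
```

which prints (tab-separated):

```
T (K)	K_sv (x10^4 L/mol)	K_q (x10^12 L/mol/s)	K_A (x10^4 L/mol)	n	dH (kJ/mol)	dS (J/mol/K)	dG (kJ/mol)
290	6.94	6.94	5.3	1.19	-1.37	85.7	-26.2
300	6.79	6.79	5.2	1.19	-1.37	85.7	-27.1
310	6.65	6.65	5.11	1.19	-1.37	85.7	-27.9
```

Reading the table: every apparent K_q is ~7×10¹² L mol⁻¹ s⁻¹, far above the
diffusion limit, and K_A falls with temperature — together diagnosing
*static* quenching (a ground-state complex). K_A ≈ 5×10⁴ L/mol with n ≈ 1.2
indicates intermediate binding at roughly one site. ΔH < 0 with ΔS > 0 is
the electrostatic signature, and ΔG < 0 at every temperature means binding
is spontaneous and exothermic. `out/report.json` carries the same numbers
with full provenance (validated against the schema from
`quenchbind.report_json_schema()`).

The same analysis is available as library calls (`load_titration`,
`correct_series`, `fit_stern_volmer`, `fit_double_log`, `fit_vant_hoff`,
`run_pipeline`) — see the module docstrings.

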