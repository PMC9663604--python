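# Packaged fixtures

CSV/JSON transcriptions of the source study's fully printed data tables,
at printed precision:

- `table1_diurnal.csv` — diurnal gas-exchange courses, 3 repeats x 13
  clock times (Photo, PARi, Tleaf, CO2S, Trmmol, Cond, Ci).
- `table2_light_response.csv` — light-response curves, 3 repeats
  (13/13/14 PAR levels) with the instrument `Fitted` column retained.
- `table4_co2_response.csv` — CO2-response curves, 3 repeats (12/12/13
  chamber-CO2 levels) with `Fitted` retained.
- `table5_slow_kinetics.csv` — slow-kinetics fluorescence block at
  PAR = 198 (no NPQ/qL columns; `FvFm` is the dark-adapted (Fm-Fo)/Fm).
- `table5_rlc.csv` — rapid light curves, 3 repeats x 13 actinic steps
  (dark step PAR = 0 included) with `Fitted` retained.
- `table3_reference.json` / `table6_reference.json` — the printed fitted
  parameters and derived quantities, used for test pinning and by
  `photoresponse reproduce-paper`.

`checksums.sha256` guards against silent edits; loading any fixture via
`reproduce-paper` verifies it.

Transcription was validated by recomputing every `Fitted` column from
the printed parameters: all values agree within print rounding except
the lowest CO2 row of repeat 3 (83.9, printed Fitted 0.323 vs model
0.258), an inconsistency in the source table itself.

Noise scale for the synthetic-data defaults: the residual SD of
Photo - Fitted in `table2_light_response.csv` is ~0.10 µmol m⁻² s⁻¹
(repeat 1: 0.098); the simulator default of 0.05 is the same order.
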