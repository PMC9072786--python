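# Parameter-bundle directory schema

A bundle is a directory with three CSV tables and one YAML config,
written by `crcsim.save_parameter_bundle` and read by
`crcsim.load_parameter_bundle` (or the `crcsim fixtures` subcommand).

## initial_prevalence.csv

State distribution at age 40 per sex; the four fractions must sum to 1.

| column            | type  | meaning                                  |
|-------------------|-------|------------------------------------------|
| sex               | str   | `male` or `female`                       |
| no_lesion         | float | fraction with no colorectal lesion       |
| naa               | float | fraction with non-advanced adenoma       |
| aa                | float | fraction with advanced adenoma           |
| preclinical_crc   | float | fraction with preclinical cancer         |

## transitions.csv

Annual forward-transition probabilities per sex and age band.  Bands
are closed-open `[age_lo, age_hi)` and must partition [40, 80) with no
gaps or overlaps.

| column                 | type  | meaning                                   |
|------------------------|-------|-------------------------------------------|
| sex                    | str   | `male` or `female`                        |
| age_lo, age_hi         | int   | band limits, `age_lo <= age < age_hi`     |
| p_norm_to_naa          | float | no lesion -> non-advanced adenoma          |
| p_naa_to_aa            | float | non-advanced -> advanced adenoma           |
| p_aa_to_preclin        | float | advanced adenoma -> preclinical cancer     |
| p_preclin_to_clinical  | float | preclinical -> symptom-detected cancer     |

## life_table.csv

One row per sex and single year of age, ages 40..80 inclusive; every
row must satisfy `0 <= p_crc <= p_all_cause <= 1`.

| column       | type  | meaning                                      |
|--------------|-------|----------------------------------------------|
| sex          | str   | `male` or `female`                           |
| age          | int   | single year of age                           |
| p_all_cause  | float | annual all-cause mortality probability       |
| p_crc        | float | annual colorectal-cancer mortality probability |

## config.yaml

```yaml
sex_ratio_at_entry: 0.5        # proportion male at age 40
crc_survival:
  q: [q1, q2, q3, q4, q5]      # annual cancer-death probabilities by
                               # year since diagnosis (unadjusted)
  s5_source: 0.622             # 5-y survival of the source population
  s5_target: 0.527             # 5-y survival of the modelled population
  screen_detected_hazard_multiplier: 0.7
tests:
  FIT:          {sensitivity_naa: ..., sensitivity_aa: ..., sensitivity_crc: ..., specificity: ...}
  SIGMOIDOSCOPY: {...}
  COLONOSCOPY:   {...}
```

Validation collects *all* violations and reports them together, naming
the offending sex/age rows and band gaps.
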