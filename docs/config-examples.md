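# Pipeline configuration (YAML)

`ramanresp run --config pipeline.yaml --out run/` expects four stage blocks
(`phantom`, `preprocess`, `segment`, `response`); a missing block fails
validation before any computation. All phantom fields are optional and
default to the values in `ramanresp.phantom.PhantomConfig`.

## Wild-type (full response)

```yaml
phantom:
  field_of_view: 45.0        # um per side
  pixel_size: 0.5            # um -> 90 x 90 pixels
  wavenumber_grid: [600.0, 3100.0, 2.0]   # cm^-1 (start, stop, step)
  mutation_profile: wildtype
  effect:
    droplet_retention: 0.5
    protein_band_gain: 1.12
    droplet_band_attenuation: 0.7
  seed: 1
preprocess:
  ch_region: [2850.0, 3000.0]
  despike_window: 7
  baseline_degree: 3
segment:
  k: 8
  min_droplet_size: 3
response:
  n_permutations: 199
n_cells: 4
seed: 1
```

## BRAF-like (small response)

Identical except:

```yaml
phantom:
  mutation_profile: braf_like   # effect scaled by 0.3
```

## KRAS-like (no response)

```yaml
phantom:
  mutation_profile: kras_like   # effect scaled by 0.0: control == treated
```

The standalone phantom config for `ramanresp simulate --config phantom.yaml`
is just the `phantom` block's content at top level.
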