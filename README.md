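# tag-elucidator

Structure elucidation of unusual short/long-chain triacylglycerides (TAGs)
from mass-spectrometric peak lists, plus the downstream quantification and
choice-assay statistics used alongside them.

The pipeline chains four evidence stages for a single precursor ion:

1. **Composition search** — invert an exact precursor m/z into candidate
   elemental compositions, and into acyl-chain multisets under the
   one-long-chain (16–18 C) plus two-short-chains (2–5 C) motif, at a
   configurable ppm tolerance (default 20 ppm).
2. **CID annotation** — predict the two loss channels per acyl (free-acid
   loss and metal-carboxylate loss) for alkali-metal adducts
   ([M+Li]+/[M+Na]+/[M+K]+), score candidates against an observed CID
   spectrum, and infer glycerol-backbone (sn) positions from relative loss
   abundances (sn-2 losses are suppressed; sn-1 vs sn-3 is never
   distinguished).
3. **OzID localization** — predict aldehyde/Criegee ion pairs for
   hypothesized n-x double-bond positions (aldehyde shift
   −x·CH₂ + O from the precursor; Criegee = aldehyde + O), localize double
   bonds from an observed OzID spectrum, and call cis/trans geometry from
   aldehyde:Criegee abundance ratios against user-calibrated references.
4. **Report** — one ranked, evidence-carrying JSON report per precursor,
   with ambiguity and conflict flags and the resolved config hash.

A seeded synthetic-data module generates ground-truth structures, spectra
with the qualitative abundance rules above, and multinomial choice-assay
counts; quantification helpers cover reference-peak normalization, TLC
band normalization, preference scores and exact tests.

## CLI

```sh
# simulate ground-truth TAGs and peak lists (CSV + ground_truth.json)
tag-elucidator simulate --seed 1 --n 5 --out-dir scratch/sim

# elucidate one precursor from a manifest (YAML/JSON with precursor_mz,
# adduct, and optional cid/ozid peak-list paths)
tag-elucidator elucidate manifest.yaml --out report.json

# normalize target peaks to a reference peak
tag-elucidator quantify peaks.csv --reference-mz 527.5 --target-mz 543.4

# preference scores + exact binomial p-values from a counts CSV
tag-elucidator choice-stats choices.csv
```

Peak lists are two-column CSV (`mz,intensity`) or minimal MGF (with
`PEPMASS`). Lipid structures use the shorthand grammar
`TG(18:1(n-9,cis)/5:1(n-2)/5:1(n-2))`. Exit codes: 0 success, 1 usage
error, 2 data error.

Tolerances and decision parameters are layered (defaults < YAML config
file < CLI flags); see `tag_elucidator.io.config.PipelineConfig` for the
full set and defaults.

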