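# External data layout

The geometry- and regression-reproduction acceptance tests (criteria 1 and
3 in `tests/test_acceptance.py`) measure published structure models and
performance values. Those files are third-party supplementary downloads and
are not redistributed with this repository; the tests fail with a pointer
here until the files are provided.

Expected layout:

```
data/external/
  supplementary_data_1/
    structure_07.pdb   # VEGFR1-VEGFR2 ECD complex with VEGFA165
    structure_09.pdb   # VEGFR2-VEGFR2 ECD complex
    structure_10.pdb   # TNFR1-TNFR1 ECD complex with TNF
    structure_11.pdb   # TNFR1-TNFR2 ECD complex with TNF
    structure_12.pdb   # TNFR2-TNFR2 ECD complex with TNF
    structure_13.pdb   # IL-10Ra homodimer ECD complex with IL-10
  vegf_features.csv    # produced by `recepstruct features` over the VEGF
                       # family manifest (design_id + six feature columns)
  vegf_performance.csv # design_id, os_meptr, fi, ntev_ecd, ntev_tmd,
                       # ctev_ecd, ctev_tmd, ligand — from the published
                       # source-data file
  tnf_features.csv
  tnf_performance.csv
```

Structure files use chain A/B for the two receptor chains; remaining chains
are the ligand. Feature tables are generated with:

```
recepstruct features --manifest <family_manifest.csv> --out <family>_features.csv
```

With these files present the acceptance tests run in seconds.
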