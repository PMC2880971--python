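# Case-study model files (not bundled)

The full-scale acceptance checks run on the published small-scale
*Escherichia coli* central-metabolism models used in the ethanol and
lycopene case studies:

- `ethanol.tsv`  — 47 internal metabolites × 60 reactions
- `lycopene.tsv` — 50 internal metabolites × 64 reactions (the ethanol
  network plus the non-mevalonate/lycopene biosynthesis reactions)

These model tables are distributed as journal supplementary material and
are not redistributed here.  To run the full-scale
checks, convert each table to the TSV dialect documented in
`emdesign.model_io` (one reaction per line:
`id<TAB>equation<TAB>reversible{0,1}<TAB>genes`, with `#substrate`,
`#product`, `#biomass` and `#mw` header directives; metabolites suffixed
`_ext` are external) and place the files in this directory.

Reaction standard Gibbs energies for the thermodynamic census go in
`../thermo/ethanol_dgr.csv` and `../thermo/lycopene_dgr.csv` as
`reaction,dGr_kcal_mol` CSV.
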