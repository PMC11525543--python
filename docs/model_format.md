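# Native model formats

## JSON dialect (`native-json`)

One JSON object per model, diffable and version-control friendly:

```json
{
 "organism_id": "autotroph",
 "metabolites": [
  {"id": "nh4_e", "name": "ammonium", "compartment": "extracellular",
   "elemental_formula": null, "charge": null, "molar_mass": 18.04}
 ],
 "reactions": [
  {"id": "EX_nh4", "name": "ammonium exchange",
   "stoichiometry": {"nh4_e": -1.0},
   "lower_bound": -1000.0, "upper_bound": 1000.0,
   "kind": "exchange", "pathway_tag": "", "evidence": ""}
 ],
 "biomass_reaction_id": "BIOMASS_auto",
 "biomass_composition": {"orgmat_e": 0.99975, "b12_e": 0.00025}
}
```

Field rules:

* `compartment` is `extracellular` or `cytosol`; by convention extracellular
  ids end in `_e`, cytosolic ids in `_c`.
* `elemental_formula` is either `null` or a map `element -> count`; a Hill
  string such as `"C2H7NO3S"` is also accepted on input.
* Stoichiometric coefficients are signed, negative = consumed. Exchange
  reactions touch exactly one extracellular metabolite with coefficient -1
  (export-positive: uptake appears as negative flux).
* `kind` is one of `internal`, `exchange`, `transport`, `biomass`; exactly
  one biomass reaction per model.
* `biomass_composition` maps lysable constituents (extracellular ids) to
  mass fractions summing to 1 ± 1e-9; these metabolites need `molar_mass`.
* Bounds are mmol gDW⁻¹ h⁻¹ and must satisfy `lower_bound <= upper_bound`.

`save_model`/`load_model` round-trip this dialect bit-identically.

## TSV dialect (`native-tsv`)

Three tab-separated files sharing one stem, for spreadsheet-based curation:

* `<stem>.tsv` — reaction table: `id, name, stoichiometry, lower_bound,
  upper_bound, kind, pathway_tag, evidence`, with stoichiometry encoded as
  `met:coef;met:coef` (sorted by metabolite id);
* `<stem>.metabolites.tsv` — metabolite table: `id, name, compartment,
  elemental_formula, charge, molar_mass` (formula in the same `el:count`
  token syntax, empty = absent);
* `<stem>.header.json` — organism id, biomass reaction id and biomass
  composition.

## SBML

`export_sbml` writes SBML Level 3 with the fbc flux-bounds package through
cobrapy/libsbml; reaction kinds, pathway tags and evidence notes travel in
SBML notes. `import_sbml` restores stoichiometry and bounds exactly;
biomass composition has no SBML representation and comes back empty.
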