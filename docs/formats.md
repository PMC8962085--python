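# File formats

All TSV dialects are tab-separated UTF-8 with `#`-prefixed comment lines;
JSON outputs are key-sorted.

## Knowledge-base snapshot

**JSON** — one document:

```json
{
  "date": "2020-02-26",
  "entries": [
    {"gene_symbol": "DLG4", "disease_id": "618793",
     "disease_name": "Intellectual developmental disorder 62",
     "inheritance": "AD", "registration": "omim_registered",
     "hpo_profile": ["HP:0000118"], "entry_date": "2020-02-26",
     "lof_mechanism": true, "missense_constrained": false}
  ],
  "assertions": [
    {"variant_key": "DLG4|NM_001365.4|c.1608-2A>G", "asserted_class": "LP",
     "source": "curated", "protein_residue": null,
     "assertion_date": "2020-02-26"}
  ],
  "frequencies": {"DLG4|NM_001365.4|c.1608-2A>G": 0.0}
}
```

**TSV** — a `##date<TAB>YYYY-MM-DD` line, then one section per record type.
Each section starts with a `#`-prefixed header naming its columns; data
rows repeat the record type in the first column:

```
##date	2020-02-26
#entry	gene_symbol	disease_id	disease_name	inheritance	registration	hpo_profile	entry_date
entry	DLG4	618793	IDD62	AD	omim_registered	HP:0000118;HP:0001250	2020-02-26
#assertion	variant_key	asserted_class	source	assertion_date
assertion	DLG4|NM_001365.4|c.1608-2A>G	LP	curated	2020-02-26
#frequency	variant_key	af
frequency	DLG4|NM_001365.4|c.1608-2A>G	0.0
```

Constraints enforced at load time: one entry per (gene, disease_id);
frequencies in [0, 1]; entry dates ≤ snapshot date; `registration` must be
`omim_registered` exactly when `disease_id` is a six-digit OMIM number;
`hpo_profile` non-empty. Inheritance accepts AD, AR, XL (also XD/XR) and
AD/AR.

## Patient variants

**TSV** columns (order free; extra columns ignored):
`patient_id  gene  zygosity  transcript  hgvs_c  [hgvs_p]  [allele_origin]`.
Zygosity: Het / Hom / Hemi. Allele origin: Unknown, Assumed de novo,
Trans phase, inherited_affected_parent, inherited_unaffected_parent,
maternal_mosaic.

The packaged report-table fixture additionally carries
`class  disease_name  disease_id  inheritance  moderate_criteria`
(the last only on VUS rows).

**VCF** — minimal VCF 4.x; mandatory INFO keys `GENE`, `TRANSCRIPT`,
`HGVSC`, optional `HGVSP`; zygosity from GT (0/1 het, 1/1 hom, haploid
hemi). Annotation itself (VEP-style) is upstream of this package.

## Ontology

OBO format, `is_a` edges only. Disease annotations come from a two-column
sidecar TSV: `disease_id<TAB>HP:...;HP:...`.

## Outputs

- Reports: JSON list (patient_id, category, reported_variants with roles
  and tiers, rule_citations, similarity_scores) and a plain-text
  narrative.
- Event log: append-only TSV
  `date  patient_id  variant_key  old_tier  new_tier  score  trigger`
  (`.` for missing).
- Review ledger: JSON list of (patient_id, variant_key, decision,
  decision_date, evidence_fingerprint).
- Run configuration: YAML mirroring `RunConfig` fields; round-trips
  unchanged.
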