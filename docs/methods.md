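# Methods

This note documents the models, rules and numerical choices behind
`retriage`, and what the synthetic experiments do and do not demonstrate.

## The problem being modelled

A clinical exome produces a set of candidate variants per patient. Each is
classified on the ACMG/AMP five-tier scale from structured evidence, the
patient's phenotype is compared against candidate disease profiles, and a
report is issued: positive, inconclusive, or negative. Undiagnosed cases
are then *reanalysed daily*: curated knowledge (gene–disease entries,
variant assertions, population frequencies) changes every day, and a case
that was negative in November can become diagnosable in February when its
gene is first tied to a disease. The package implements that whole loop
deterministically, so it can be tested and replayed.

## ACMG evidence combining

`evaluate_criteria` maps an `EvidenceFacts` record plus a gene–disease
entry to criterion assignments:

| criterion | condition | applied strength |
|---|---|---|
| PVS1 | frameshift / stop gain / canonical splice in a gene with a loss-of-function mechanism | very strong (moderate when NMD escape is predicted; unknown counts as very strong) |
| PS1 | same protein change previously asserted pathogenic | strong |
| PS2 | assumed de novo | strong |
| PM5 | different pathogenic change at the same residue | moderate |
| PM2 | absent from population databases, or below 1e-5 (dominant / X-linked) or 1e-4 (recessive) | **supporting** by default (`pm2_strength`) |
| PM3 | in trans with a P/LP allele in a recessive gene (phase known: homozygosity or confirmed segregation) | moderate |
| PM4 | in-frame indel | moderate |
| PP1 | observed co-segregation | supporting |
| PP3 / BP4 | in silico consensus | supporting |
| BA1 | allele frequency > 0.05 | stand-alone (short-circuits everything else) |
| BS1 | frequency above a per-disease maximum credible frequency (`bs1_af`) | strong |

`combine_criteria` implements the guideline combining table purely over
counts of applied strengths (pathogenic: very strong / strong / moderate /
supporting; benign: stand-alone / strong / supporting). Simultaneous
pathogenic-and-benign qualification, or neither, yields VUS. The table is
verified exhaustively against an independently written rule-pattern
evaluator over every multiset with ≤ 3 criteria per strength level, and
property-tested for monotonicity (adding pathogenic evidence never moves a
tier toward benign and vice versa, with conflict→VUS as the allowed fixed
point).

Three deliberate simplifications: the PVS1 decision tree is reduced to the
NMD three-way switch; reputable-source criteria (PP5/BP6) are excluded —
curated assertions feed PS1/PM5 instead; there is no Bayesian point-based
combining. `EvidenceFacts` distinguishes *unknown* frequency (no PM2) from
*consulted-and-absent* (PM2 applies): only evidence that was actually
looked up counts.

PM2's strength matters in one well-defined situation: a loss-of-function
variant whose only other evidence is rarity. At the default supporting
strength PVS1+PM2 combines to VUS (conservative); with
`pm2_strength: moderate` — the guideline-literal weighting — it combines
to LP. The new-entry reanalysis scenario in the test suite runs under the
guideline-literal setting because that is the behaviour clinical engines
exhibit for exactly this variant shape; both settings are first-class
configuration.

## Symptom similarity

The scorer is an asymmetric best-match average of Lin term similarity,
scaled to a 0–10 range:

    IC(t)      = −ln((n_t + 1) / (N + 1))        (add-one smoothing)
    lin(a, b)  = 2·IC(MICA(a,b)) / (IC(a) + IC(b)),  0 when both ICs are 0
    score(P,D) = 10 · mean_{t∈P} max_{d∈D} lin(t, d)

where `n_t` counts distinct diseases annotated to `t` or any descendant
and `N` is the corpus size. The direction is patient→disease: extra
profile terms the patient lacks do not penalize the score, missing patient
coverage does. A score ≥ 5 (`similarity_threshold`) means the mean
term-level similarity exceeds 0.5 and flags the disease for review.
Add-one smoothing keeps leaf ICs finite on small corpora and gives the
root IC 0 exactly, so terms informative about nothing contribute nothing.
Unknown terms in messy clinical input are dropped with a warning rather
than rejected; an empty patient set after dropping is an error.

The scorer is one pluggable function; Resnik/Jiang–Conrath variants can be
swapped in behind the same interface without touching triage.

## Reporting rules

Per implicated gene–disease entry, with "fit" = similarity ≥ 5 against the
entry's HPO profile (`assume_phenotype_fit` treats fit as satisfied when a
cohort arrives without HPO data, e.g. a transcribed report table):

1. **Positive** (registered entry, fit): dominant / X-linked — one het or
   hemi P/LP; recessive — hom P/LP, two P/LP potential compound hets, or
   P/LP + VUS carrying ≥ 2 moderate pathogenic criteria. Entries flagged
   digenic in their curated name are handled under the single-het rule:
   a digenic mechanism is causal with one het allele per locus, even when
   the formal inheritance column reads recessive.
2. **Inconclusive**: any VUS in a fitting registered entry (single
   dominant VUS, recessive P/LP + VUS with ≤ 1 moderate criterion,
   multiple VUS); P/LP in a literature-candidate entry (published, not in
   OMIM); P/LP in a registered entry whose fit is below threshold.
3. **Negative** otherwise.

Dual/AD-or-AR entries are evaluated under both arms and the more
conclusive category wins; all qualifying entries are reported, so dual
diagnoses are supported. The rules are order-independent (property-tested
under variant permutation) and categories partition any cohort.

The boundary case "P/LP + VUS with exactly one moderate criterion" is
routed to inconclusive: the positive arm explicitly demands two moderate
criteria, so anything below that bar cannot justify a molecular diagnosis.

## The daily loop

`diff_snapshots` keys entries on (gene, disease_id) and assertions on the
normalized variant key `GENE|TRANSCRIPT|c.DESC` (whitespace stripped, HGVS
byte-preserved otherwise — no 3'-shifting, since published tables mix
dialects; known published symbol variants are mapped to one key).
Any field change counts as a change. Frequency updates are *material* only
when they cross a criterion boundary (1e-5, 1e-4, 0.05 and any per-disease
BS1 cutoff); sub-boundary churn would re-trigger review daily for no
interpretive reason.

`daily_run` re-evaluates, for every non-positive case, only variants in
genes the delta touched (`full_scan` forces whole-cohort re-evaluation;
tests verify scoping loses nothing). An event is emitted when a variant
newly combines to P/LP, or is a VUS whose similarity score clears the
threshold under an evidence state not flagged before. The **evidence
fingerprint** — a stable hash of the matching assertion, the entry's
curated fields, the frequency's criterion band, and the patient's term
set — defines "a new change": an excluded variant stays suppressed while
its fingerprint is unchanged and re-surfaces exactly when it changes.
Confirmed events update the report through the ordinary triage rules;
in simulation mode events auto-confirm. Rerunning a day is a no-op.

Time-to-diagnosis is measured from the first report to the confirming
event, in 365.25-day years; per-day event counts are computed over days
with at least one event; means and SDs are sample statistics (ddof 1).

## The synthetic cohort

The generator emulates the *structure* of a reanalysis study, not human
genetics: a balanced 4-level toy ontology (156 terms), a 50-disease corpus
whose profiles live mostly in one top-level branch each (5–9 leaf terms),
and per-patient planted truths. A configurable fraction of patients
(default 0.7) carries a causal loss-of-function-style variant (frameshift,
stop gain, or canonical splice, drawn from templates) that classifies P/LP
once — and only once — its gene–disease entry exists; the rest carry a
common unresolved substitution in a gene the knowledge base may discover
as background noise. Default condition parameters: 2-year timeline with
enrollment over the first year; half of causal genes undiscovered at day 0
with discovery dates uniform over the timeline; background discovery rates
of 250 gene–disease entries and 9,200 variant assertions per year;
background phenotype sizes of 8.6 ± 4.6 terms; planted phenotypes are the
disease profile with optional drop/add noise (default none). Separate RNG
streams (ontology, cohort, noise, timeline) hang off one seed, so changing
one knob does not reshuffle the rest; timelines are yielded lazily as
cumulative daily snapshots.

Because discovery dates are known, `replay` is scored exactly: recall
(planted diagnoses recovered), anticipation (diagnoses before the enabling
knowledge exists — must be zero), delay per patient, and the
wave-structure effect (patients enrolled after a discovery are diagnosed
at initial triage, so a later enrollment wave has strictly smaller median
time-to-diagnosis).

What passing these replays shows: the loop's bookkeeping — eligibility,
delta scoping, event emission, suppression, report flipping — is exact.
What it does not show: performance on real exomes, where evidence is
noisy, phenotypes are incompletely recorded, ontologies are far deeper,
and classification disagreements between laboratories are common.
Cohort-scale published figures (diagnostic yields near 40%, ~2 reclassified
variants/day, mean reanalysis intervals around a year) depend on that real
cohort and are intentionally out of scope; the simulator reproduces the
qualitative behaviours, not those numbers.

## Degenerate inputs and tie-breaks

- Unparseable HGVS: variant kept, consequence `other`, warning logged.
- Insertions of unknown length and spans crossing exon–intron boundaries
  with unknown intron lengths: consequence `other` (never a guess).
- Intron offset 0 is rejected as malformed.
- Disease ranking ties break by disease_id ascending; report variant lists
  are deduplicated by (variant, disease).
- Multiple snapshots per day are rejected; a day with no snapshot is a
  no-op.
- JSON outputs are key-sorted; the event log is append-only TSV — byte
  identity under a fixed seed is a test.

## Fixture provenance

`fixtures/table2.tsv` transcribes a published 49-variant / 45-patient
reanalysis table (classes, zygosities, inheritance, registration status,
allele origins); the published outcome column is deliberately omitted, and
the per-VUS moderate-criteria counts required by the compound-het rule are
encoded explicitly since report tables do not print criteria. The toy
ontology/corpus fixtures are synthetic and sized for hand computation
(every expected similarity in the tests is derived in closed form from
their ICs).
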