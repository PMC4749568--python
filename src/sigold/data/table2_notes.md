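# Fixture notes: PDF immunogold counts in nuchal-organ sensory neurons

Gold-particle counts for the 35 nuchal-organ sensory neurons (r1–r20,
l1–l15) across the three whole-body-series sections labeled with the PDF
antibody (absolute section numbers 703, 723, 787).

Transcription caveats:

* The printed table renders each neuron's three per-layer counts as a
  run-on digit string; almost all split unambiguously into three
  single-digit (or one two-digit final) values. The `l14` cell ("1800")
  does not: it is transcribed here as (18, 0, 0) and carries an
  `ambiguous` note. Tests and worked examples exclude it from value
  assertions.
* Rows r15–r20 are printed collapsed as a single all-zero row and are
  expanded here to six all-zero rows.
* Counting neurons with any gold in this transcription gives 13 of 35,
  whereas the accompanying text reports 15 of 35 PDF-positive neurons.
  Whether that count used the >= 2-gold candidate rule or an any-gold rule
  is not stated, and the run-on rendering makes the discrepancy
  unresolvable from the printed table alone; the 15/35 figure is therefore
  documented here but never asserted.
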