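# Methods

## Scope and model

`vario-rna` turns the RNA branch of the Variation Ontology (VariO) into an
executable annotator. An annotation is an ordered, accession-unique set of
terms attached to one parsed variant description. Two sources of terms are
kept strictly apart:

- **rule-basis** terms are decidable from the variant string plus, at most,
  transcript geometry (CDS interval, sequence, intronic offset): variation
  classification and chemistry, frame consequence, splice-site class,
  non-coding size class;
- **metadata-basis** terms rest on experimental knowledge (variation
  origin, function/property effects, affected-RNA typing such as
  `microRNA` or `exon skipping`). The classifier validates these against
  the hierarchy and records their provenance, but never infers them. In
  particular, nonsense-mediated-decay outcome (`decayed RNA`) is not
  predicted.

Structure-effect terms (secondary/tertiary structure subtrees) are carried
as controlled vocabulary only, assignable via metadata.

## The term registry

The bundled registry (`data/rna_terms.tsv`) holds 151 RNA-related terms in
a rooted DAG with four category roots (variation type, function, property,
structure); maximum depth is 6, i.e. seven levels counting the roots as
level one. Depth is defined as `depth(child) = 1 + min(depth(parent))` and
not hard-coded.

The source text reuses three accessions for two names each (0308, 0468,
0502) and prints one five-digit accession (`VariO:00321`). No official OBO
release is vendored, so the registry resolves these with a
first-occurrence-wins convention: the first-quoted name keeps the printed
accession, the later name moves to a nearby unused accession, and every
such row is flagged `source=resolved` with the printed accession kept as a
`printed:` synonym. Two canonical/non-canonical splice siblings that are
implied but never quoted are flagged `source=inferred`. All resolutions are
data in the TSV, not code. `load_obo` accepts an official release (only
`id`, `name`, `is_a`, `is_obsolete` are consumed) and presents the same
query interface, so the bundled table is a fallback, not a fork.

## Coordinate conventions

Variant coordinates are 1-based, fully closed; insertions are anchored
between adjacent positions. `r.`/`c.` positions are treated as
CDS-relative (position 1 = first base of the AUG): every worked codon
number in the reference examples (318, 520, residues 260–280) is consistent
with that frame, and `r.3g>u` hits the initiation codon. Intronic offsets
are carried for `c.`/`g.` only; an `r.` description with an offset is
rejected, since a spliced molecule has no intronic positions. `t` is
normalised to `u` in `r.` strings; `c./g./m.` keep DNA letters, and
chemistry classification treats `t` as `u`. En-dash and minus glyphs in
negative offsets are accepted because published text prints them.

## Coding-effect rules and the hybrid-codon convention

Substitutions: initiation codon (codon 1) positionally; at the termination
codon, a stop→sense exchange is a termination codon change and stop→stop is
silent; elsewhere the reference codon decides silent/nonsense/missense.
Nonsense therefore only arises strictly before the natural stop.

Length-changing variants are in frame iff the net length change is
divisible by three; codon-boundary alignment is not required (a 6-nt
insertion is in-frame regardless of phase). For an in-frame deletion
starting at phase 2 or 3, the 5′ partial codon is reconstituted from the
flanks and assigned, by convention, to the flanking residue, so the deleted
residue range starts one codon later. The translate-and-diff oracle shows
this convention is exact for phase-1 deletions, and for phase-2/3 deletions
agrees exactly when the hybrid codon re-encodes the flanking residue
(tested as a biconditional); with uniformly random codons the hybrid codon
frequently changes the flank — those cases are protein-level delins rather
than clean deletions, counted but deliberately not asserted to zero.

## Splice-site and size classes

Donor (five-prime) sites are addressed by positive intronic offsets,
acceptors by negative ones; ±1/±2 are canonical (the GT/AG dinucleotides),
inferred from +5 being labelled non-canonical and −2 canonical in the
reference examples. Recursive-site and cis/trans distinctions are metadata.
Size classes read the two stated bounds strictly: `<200 nt` short,
`>10000 nt` very long, the closed interval [200, 10000] long.

## Synthetic generator and oracle

`generate_transcript(seed, cds_codons, utr5, utr3)` emits a random
transcript: random UTRs, `aug`, `cds_codons − 2` codons drawn uniformly
from the 61 sense codons (so no internal in-frame stop), a random stop.
Defaults (100 codons, 20/30-nt UTRs; test suite uses 200 codons) are
chosen as a compact but codon-diverse mRNA; uniform codon usage is a
deliberate simplification. The oracle applies the variant to the full
sequence, keeps the CDS start unless the initiation codon was hit,
translates both molecules and labels by direct comparison; for
non-substitutions the label is the frame consequence measured on the
molecule itself (a net-zero delins is still an in-frame indel). All
randomness flows through one explicitly seeded `numpy` generator.

What passing these tests shows — and does not: the rule engine agrees with
literal translation on synthetic mRNAs with ideal CDS structure. Real
transcripts add selenocysteine recoding, non-AUG starts, overlapping
reading frames and splice isoform ambiguity, none of which is modelled.

## Numerical and degenerate-input choices

No floating-point numerics are involved; all arithmetic is exact integer
coordinate math. Degenerate inputs are contracts, not crashes: zero or
negative positions, end-before-start intervals, identical-base
substitutions and protein-level (`p.`) input are parse errors; a variant
outside the CDS is `not_applicable`, while a codon-dependent label without
a reference codon raises an insufficient-context error. Translocation is
representable and classifiable (`RNA translocation`) but has no
single-variant string syntax, so the parser never produces it and
formatting one raises.

The in-frame fraction check for random deletion lengths 1–9 uses a
binomial tolerance of three standard errors at n = 3000 around p = 1/3.

## Test problem sizes

Property sweeps use 1000 seeded substitutions and 1000 length-changing
variants on a 200-codon transcript, 300 transcript-invariant seeds, 1500
deletions for the hybrid-codon census and 300 fuzzed round-trip examples —
sizes at which every distinct code path is exercised many times while the
whole suite stays in the seconds range.

## Known limitations

- The conflict table could not be cross-checked against an official OBO
  release; reassigned accessions (0297, 0467, 0503) are package-local
  choices, clearly flagged in the registry, and an official release loaded
  with `--obo` takes precedence at run time.
- No genome-to-transcript projection: `g.` variants are classified from
  their description only.
- Mitochondrial translation-code differences are ignored; `m.` variants
  are classified at RNA level only.
- The annotation lists the most specific rule term per branch plus its
  stated parent (e.g. `RNA deletion` + `in-frame deletion`), not the full
  ancestor closure; `ancestors()` provides the closure on demand.
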