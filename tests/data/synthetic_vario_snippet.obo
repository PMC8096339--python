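format-version: 1.2
ontology: vario-rna-snippet
! SYNTHETIC fixture: a hand-written OBO snippet mirroring a small part of the
! VariO RNA subtree, used to exercise the OBO loading path and check that the
! bundled registry and an OBO load agree on term names. It is not an official
! VariO release (none was obtainable in this environment).

[Term]
id: VariO:0306
name: RNA variation type

[Term]
id: VariO:0328
name: RNA variation classification
is_a: VariO:0306 ! RNA variation type

[Term]
id: VariO:0312
name: RNA substitution
is_a: VariO:0328 ! RNA variation classification

[Term]
id: VariO:0313
name: transition
is_a: VariO:0312 ! RNA substitution

[Term]
id: VariO:0315
name: purine transition
is_a: VariO:0313 ! transition

[Term]
id: VariO:0314
name: pyrimidine transition
is_a: VariO:0313 ! transition

[Term]
id: VariO:0316
name: transversion
is_a: VariO:0312 ! RNA substitution

[Term]
id: VariO:0319
name: RNA deletion
is_a: VariO:0328 ! RNA variation classification

[Term]
id: VariO:0320
name: in-frame deletion
is_a: VariO:0319 ! RNA deletion

[Term]
id: VariO:0321
name: out-of-frame deletion
is_a: VariO:0319 ! RNA deletion

[Term]
id: VariO:0999
name: obsolete RNA relic
is_obsolete: true
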