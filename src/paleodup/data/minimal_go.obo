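format-version: 1.2
ontology: minimal-go-fixture

[Term]
id: GO:0008150
name: biological_process

[Term]
id: GO:0003674
name: molecular_function

[Term]
id: GO:0065007
name: biological regulation
is_a: GO:0008150 ! biological_process

[Term]
id: GO:0050789
name: regulation of biological process
is_a: GO:0065007 ! biological regulation

[Term]
id: GO:0003700
name: DNA-binding transcription factor activity
is_a: GO:0003674 ! molecular_function

[Term]
id: GO:0006355
name: regulation of DNA-templated transcription
is_a: GO:0050789 ! regulation of biological process

[Term]
id: GO:0009058
name: biosynthetic process
is_a: GO:0008150 ! biological_process

[Term]
id: GO:0016070
name: RNA metabolic process
is_a: GO:0008150 ! biological_process
relationship: part_of GO:0009058 ! biosynthetic process
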