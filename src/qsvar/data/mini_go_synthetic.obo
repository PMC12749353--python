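format-version: 1.2
ontology: qsvar/mini-go-synthetic
remark: Synthetic miniature ontology for tests and examples. Hand-written
remark: GO-style DAG reproducing the familiar cellular-component path from
remark: mitochondrial inner membrane up to mitochondrion, plus a small
remark: molecular-function branch; NOT an excerpt of any go.obo release.

[Term]
id: GO:0005575
name: cellular_component
namespace: cellular_component

[Term]
id: GO:0043226
name: organelle
namespace: cellular_component
is_a: GO:0005575

[Term]
id: GO:0005739
name: mitochondrion
namespace: cellular_component
is_a: GO:0043226

[Term]
id: GO:0005740
name: mitochondrial envelope
namespace: cellular_component
relationship: part_of GO:0005739

[Term]
id: GO:0031966
name: mitochondrial membrane
namespace: cellular_component
relationship: part_of GO:0005740

[Term]
id: GO:0005743
name: mitochondrial inner membrane
namespace: cellular_component
is_a: GO:0031966

[Term]
id: GO:0005829
name: cytosol
namespace: cellular_component
is_a: GO:0005575

[Term]
id: GO:0003674
name: molecular_function
namespace: molecular_function

[Term]
id: GO:0003824
name: catalytic activity
namespace: molecular_function
is_a: GO:0003674

[Term]
id: GO:0016829
name: lyase activity
namespace: molecular_function
is_a: GO:0003824

[Term]
id: GO:0000000
name: obsolete placeholder activity
namespace: molecular_function
is_obsolete: true
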