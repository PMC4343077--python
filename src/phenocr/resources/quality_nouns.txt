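# Nouns (normalized form) that act as the quality/abnormality head of a
# phenotype phrase rather than as an anatomical entity.  Used to decide
# whether the shared tail of a coordination is a succeeding qualifier
# ("otic and renal malformations") or an entity shared by conjoined
# qualifiers ("short and broad fingers").
abnormality
anomaly
malformation
defect
deformity
hypoplasia
aplasia
dysplasia
hyperplasia
hypertrophy
atrophy
agenesis
absence
deficiency
synostosis
fusion
degeneration
dysfunction
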