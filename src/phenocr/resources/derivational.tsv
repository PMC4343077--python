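# surface <TAB> normal_form
# Adjective -> noun derivational variants collapsed to one normal form.
# Extend freely; both columns are matched after case folding.
hypoplastic	hypoplasia
aplastic	aplasia
dysplastic	dysplasia
hyperplastic	hyperplasia
hypertrophic	hypertrophy
atrophic	atrophy
sclerotic	sclerosis
stenotic	stenosis
cystic	cyst
fused	fusion
absent	absence
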