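# Function words dropped from token signatures: the six prepositions
# commonly embedded in ontology labels, plus articles, plus the filler
# quantifier/connector words that HPO labels and free-text mentions use
# interchangeably ("synostosis involving the carpal bones" vs
# "synostosis of some carpal bones").
in
of
to
by
from
with
the
a
an
some
involving
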