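# plural <TAB> singular
vertebrae	vertebra
feet	foot
teeth	tooth
phalanges	phalanx
metaphyses	metaphysis
epiphyses	epiphysis
diaphyses	diaphysis
synostoses	synostosis
stenoses	stenosis
scolioses	scoliosis
ganglia	ganglion
nuclei	nucleus
foramina	foramen
septa	septum
cortices	cortex
calices	calix
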