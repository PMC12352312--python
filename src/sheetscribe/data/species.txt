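# Fixture specific-epithet reference list (demo scale)
# Note: sertulata precedes serrulata; both are valid epithets and list
# order breaks similarity ties.
acicularis
alpina
angustifolia
australis
baueri
brevifolia
capillaris
cinerea
collina
cordata
dealbata
denticulata
elliptica
ericifolia
filiformis
glabra
glauca
gracilis
grandiflora
hirsuta
humilis
juncea
lanceolata
lanigera
latifolia
linearis
longifolia
macrantha
microphylla
montana
myrtifolia
nutans
obcordata
obtusifolia
occidentalis
ovata
paludosa
paniculata
parviflora
pauciflora
pilosa
procumbens
pubescens
quadrifida
ramosissima
repens
rosmarinifolia
scoparia
sertulata
serrulata
sisymbriifolium
spinescens
squarrosa
stricta
tenuifolia
tomentosa
torulosa
verna
villosa
viminalis
virgata
vulgaris
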