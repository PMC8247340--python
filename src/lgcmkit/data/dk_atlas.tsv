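# Desikan-Killiany cortical parcels and subcortical segmentation labels,
# grouped into eight bilateral composites: frontal, temporal (incl.
# amygdala and hippocampus), parietal, occipital, insula, cingulate,
# central (basal ganglia and thalamus), brainstem.  Editable: region<TAB>lobe.
superiorfrontal	frontal
rostralmiddlefrontal	frontal
caudalmiddlefrontal	frontal
parsopercularis	frontal
parstriangularis	frontal
parsorbitalis	frontal
lateralorbitofrontal	frontal
medialorbitofrontal	frontal
precentral	frontal
paracentral	frontal
frontalpole	frontal
superiortemporal	temporal
middletemporal	temporal
inferiortemporal	temporal
bankssts	temporal
fusiform	temporal
transversetemporal	temporal
entorhinal	temporal
temporalpole	temporal
parahippocampal	temporal
hippocampus	temporal
amygdala	temporal
superiorparietal	parietal
inferiorparietal	parietal
supramarginal	parietal
postcentral	parietal
precuneus	parietal
lateraloccipital	occipital
lingual	occipital
cuneus	occipital
pericalcarine	occipital
insula	insula
rostralanteriorcingulate	cingulate
caudalanteriorcingulate	cingulate
posteriorcingulate	cingulate
isthmuscingulate	cingulate
thalamus	central
caudate	central
putamen	central
pallidum	central
accumbens	central
brainstem	brainstem
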