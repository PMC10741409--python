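Bankssts L
Bankssts R
Caudal anterior cingulate L
Caudal anterior cingulate R
Caudal middle frontal L
Caudal middle frontal R
Cuneus L
Cuneus R
Entorhinal L
Entorhinal R
Frontal pole L
Frontal pole R
Fusiform L
Fusiform R
Inferior parietal L
Inferior parietal R
Inferior temporal L
Inferior temporal R
Insula L
Insula R
Isthmus cingulate L
Isthmus cingulate R
Lateral occipital L
Lateral occipital R
Lateral orbitofrontal L
Lateral orbitofrontal R
Lingual L
Lingual R
Medial orbitofrontal L
Medial orbitofrontal R
Middle temporal L
Middle temporal R
Paracentral L
Paracentral R
Parahippocampal L
Parahippocampal R
Pars opercularis L
Pars opercularis R
Pars orbitalis L
Pars orbitalis R
Pars triangularis L
Pars triangularis R
Pericalcarine L
Pericalcarine R
Postcentral L
Postcentral R
Posterior cingulate L
Posterior cingulate R
Precentral L
Precentral R
Precuneus L
Precuneus R
Rostral anterior cingulate L
Rostral anterior cingulate R
Rostral middle frontal L
Rostral middle frontal R
Superior frontal L
Superior frontal R
Superior parietal L
Superior parietal R
Superior temporal L
Superior temporal R
Supramarginal L
Supramarginal R
Temporal pole L
Temporal pole R
Transverse temporal L
Transverse temporal R
Thalamus L
Thalamus R
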