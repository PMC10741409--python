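region	rsn
Precuneus L	DMN
Precuneus R	DMN
Posterior cingulate L	DMN
Posterior cingulate R	DMN
Isthmus cingulate L	DMN
Isthmus cingulate R	DMN
Medial orbitofrontal L	DMN
Medial orbitofrontal R	DMN
Lateral orbitofrontal L	DMN
Lateral orbitofrontal R	DMN
Inferior temporal L	DAN
Inferior temporal R	DAN
Pars opercularis L	DAN
Pars opercularis R	DAN
Caudal anterior cingulate L	DAN
Caudal anterior cingulate R	DAN
Rostral anterior cingulate L	DAN
Rostral anterior cingulate R	DAN
Pars triangularis L	DAN
Pars triangularis R	DAN
Middle temporal L	DAN
Middle temporal R	DAN
Lateral occipital L	VIS
Lateral occipital R	VIS
Cuneus L	VIS
Cuneus R	VIS
Pericalcarine L	VIS
Pericalcarine R	VIS
Lingual L	VIS
Lingual R	VIS
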