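fine_label	merged_group
Ribosomes	Ribosomes
Cytosol	Cytosol
Nucleus	Nucleus
Nuclear envelope	Nucleus
Nucleoplasm	Nucleus
Chromatin	Nucleus
Nucleoli fibrillar center	Nucleus
Nuclear speckles	Nucleus
Nuclear bodies	Nucleus
Nucleoli	Nucleus
Cell membrane	Cell membrane
Microfilaments (Actin)	Microfilaments
Intermediate filaments (Keratin, filaments)	Microfilaments
Microtubules	Microfilaments
Mitochondria	Mitochondria
Endoplasmic reticulum	Endoplasmic reticulum
Extracellular	Extracellular
Cell-ECM junctions	Cell ECM junctions
Golgi apparatus	Golgi apparatus
Proteasome	Proteasome
Melanosomes	Other vesicles
Endosomes	Other vesicles
Outer segments	Other vesicles
Lipid droplets	Other vesicles
Cilia	Cilia, centrosome
Centrosome	Cilia, centrosome
Microtubule organising centre	Cilia, centrosome
Midbody	Cilia, centrosome
Mitotic spindle	Cilia, centrosome
Cell-cell-junctions	Cell cell junctions
Lysosomes	Lysosomes
Peroxisomes	Peroxisomes
Focal adhesion sites	Focal adhesion sites
Cell cortex	Cell Cortex
UNKNOWN	UNKNOWN
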