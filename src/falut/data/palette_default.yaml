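# Default anchor palette for the normative FA look-up table.
#
# Colors are chosen so that dense white matter (corpus-callosum range)
# renders red through yellow with rising FA, deep gray matter renders in
# blues, and cortical gray in greens. Edit freely and pass via
# `falut build-lut --palette`. Labels map to [R, G, B] in 0-255.
DOMAIN_MIN: [0, 0, 0]
BG_HALF_PILOW: [0, 0, 96]
BG_PILOW: [0, 0, 255]
BG_MEAN: [0, 255, 255]
GM_MEAN: [0, 200, 0]
GM_PIUP: [128, 128, 0]
CCF_PILOW: [255, 0, 0]
CCF_PIUP: [255, 128, 0]
CCROI_MEAN: [255, 255, 0]
DOMAIN_MAX: [255, 255, 255]
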