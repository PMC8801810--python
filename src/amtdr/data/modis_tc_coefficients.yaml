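# Tasseled-cap transformation coefficients for MODIS 7-band surface
# reflectance (Lobser & Cohen 2007, derived from MODIS NBAR data).
# Band order follows the MODIS land-band convention:
#   1 red (620-670 nm), 2 NIR (841-876 nm), 3 blue (459-479 nm),
#   4 green (545-565 nm), 5 NIR2 (1230-1250 nm), 6 SWIR1 (1628-1652 nm),
#   7 SWIR2 (2105-2155 nm)
# Swap this file to use another sensor's coefficient set.
version: lobser-cohen-2007
band_order: [red, nir, blue, green, nir2, swir1, swir2]
brightness: [0.4395, 0.5945, 0.2460, 0.3918, 0.3506, 0.2136, 0.2678]
greenness: [-0.4064, 0.5129, -0.2744, -0.2893, 0.4882, -0.0036, -0.4169]
wetness: [0.1147, 0.2489, 0.2408, 0.3132, -0.3122, -0.6416, -0.5087]
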