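# Bundled default optical-constant library (wavelength in nm, n/k dimensionless).
# Lines starting with '#' are comments; 'provenance <id>:' lines attach a source note.
# Coverage 330-700 nm so that +/- 2 FWHM LED bands around the 390 and 630 nm
# lines remain inside the no-extrapolation range.
# provenance air: identity medium, n = 1, k = 0 by definition.
# provenance silver: literature dispersion for evaporated Ag films (Johnson & Christy-type values), interpolated to round wavelengths; near-UV edge values approximate.
# provenance copper: literature dispersion for evaporated Cu films (Johnson & Christy-type values), interpolated to round wavelengths.
# provenance chromium: literature dispersion for sputtered Cr films (handbook values), interpolated to round wavelengths.
# provenance silicon: literature dispersion for crystalline Si at room temperature (ellipsometric handbook values), interpolated to round wavelengths.
# provenance polycarbonate_tape: handbook refractive index of bisphenol-A polycarbonate film; transparent in the visible (k = 0).
# provenance carbon_tape: SYNTHETIC placeholder for black double-sided conductive carbon adhesive tape, modelled as a strongly absorbing amorphous-carbon-like medium; not a measured value.
# provenance resin: SYNTHETIC placeholder for cured epoxy embedding resin (weakly absorbing dielectric); not a measured value.
# provenance stained_tissue: SYNTHETIC placeholder for resin-embedded heavy-metal-stained (OsO4) neuropil: resin-like index with substantial stain absorption; not a measured value.
# provenance stained_cell: SYNTHETIC placeholder for stained cell body/nucleus regions: like stained_tissue but with roughly double the stain density, hence higher extinction; not a measured value.
# provenance stained_tissue_post: SYNTHETIC placeholder for poststained (uranyl acetate / lead citrate) neuropil: stained_tissue with increased extinction; not a measured value.
# provenance stained_cell_post: SYNTHETIC placeholder for poststained cell regions: stained_cell with increased extinction; not a measured value.
material_id,wavelength_nm,n,k
air,330,1.0,0.0
air,700,1.0,0.0
silver,330,0.250,0.900
silver,360,0.070,1.340
silver,380,0.050,1.670
silver,400,0.050,1.930
silver,420,0.040,2.140
silver,450,0.040,2.420
silver,470,0.050,2.550
silver,500,0.050,2.870
silver,550,0.060,3.320
silver,600,0.060,3.770
silver,630,0.050,4.100
silver,650,0.030,4.270
silver,700,0.040,4.600
copper,330,1.340,1.560
copper,380,1.330,1.700
copper,400,1.260,1.950
copper,420,1.180,2.210
copper,450,1.170,2.360
copper,500,1.130,2.560
copper,550,0.830,2.600
copper,600,0.400,2.950
copper,630,0.240,3.340
copper,650,0.210,3.490
copper,700,0.210,4.050
chromium,330,1.550,2.510
chromium,380,1.850,2.700
chromium,400,1.990,2.810
chromium,450,2.300,3.050
chromium,500,2.640,3.240
chromium,550,2.940,3.310
chromium,600,3.170,3.300
chromium,650,3.300,3.300
chromium,700,3.330,3.300
silicon,330,5.200,2.900
silicon,360,6.000,1.200
silicon,380,6.050,0.600
silicon,400,5.570,0.390
silicon,420,5.120,0.270
silicon,450,4.680,0.150
silicon,500,4.290,0.072
silicon,550,4.080,0.040
silicon,600,3.940,0.025
silicon,650,3.850,0.016
silicon,700,3.780,0.011
polycarbonate_tape,330,1.640,0.0
polycarbonate_tape,380,1.618,0.0
polycarbonate_tape,400,1.610,0.0
polycarbonate_tape,450,1.597,0.0
polycarbonate_tape,500,1.589,0.0
polycarbonate_tape,550,1.583,0.0
polycarbonate_tape,600,1.579,0.0
polycarbonate_tape,650,1.576,0.0
polycarbonate_tape,700,1.574,0.0
carbon_tape,330,1.900,0.770
carbon_tape,450,2.000,0.800
carbon_tape,550,2.050,0.820
carbon_tape,700,2.120,0.860
resin,330,1.550,0.004
resin,450,1.540,0.004
resin,550,1.536,0.003
resin,700,1.532,0.003
stained_tissue,330,1.560,0.100
stained_tissue,450,1.553,0.100
stained_tissue,550,1.548,0.100
stained_tissue,700,1.541,0.100
stained_cell,330,1.580,0.220
stained_cell,450,1.573,0.220
stained_cell,550,1.568,0.220
stained_cell,700,1.561,0.220
stained_tissue_post,330,1.565,0.140
stained_tissue_post,450,1.558,0.140
stained_tissue_post,550,1.553,0.140
stained_tissue_post,700,1.546,0.140
stained_cell_post,330,1.585,0.300
stained_cell_post,450,1.578,0.300
stained_cell_post,550,1.573,0.300
stained_cell_post,700,1.566,0.300
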