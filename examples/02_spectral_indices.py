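"""Evaluate the multispectral indices on healthy vs chlorotic leaf spectra.

Band reflectances come from the package's declared leaf/soil endmember
spectra.  Chlorosis raises red (670 nm) and lowers NIR (840 nm) leaf
reflectance, so every red/NIR contrast index (NDVI, SAVI, OSAVI, RDVI, EVI)
drops; the soil spectrum sits near NDVI ~ 0.1.
"""

from canopyvi import CAMERA_WAVELENGTHS, leaf_soil_reflectance, spectral_index

for label, material, chl in (("healthy leaf", "leaf", 0.0),
                             ("chlorotic leaf", "leaf", 1.0),
                             ("bare soil", "soil", 0.0)):
    bands = {wl: leaf_soil_reflectance(wl, material, chl)
             for wl in CAMERA_WAVELENGTHS}
    ndvi = spectral_index("ndvi", bands)
    savi = spectral_index("savi", bands, L=0.5)
    osavi = spectral_index("osavi", bands)
    pri = spectral_index("pri", bands)
    tcari_osavi = spectral_index("tcari_osavi", bands)
    print(f"{label:15s} NDVI={ndvi:6.3f}  SAVI(L=0.5)={savi:6.3f}  "
          f"OSAVI={osavi:6.3f}  PRI={pri:6.3f}  TCARI/OSAVI={tcari_osavi:6.3f}")

print("\nNDVI drops from healthy to chlorotic leaf; soil stays near zero —")
print("the contrast that lets red/NIR indices track canopy cover and vigor.")
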