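"""The five-plex marker panel and its fluorophore assignment.

Cycle order: NDUFB8 (Opal 520), TOMM20 (Opal 570), MTCO1 (Opal 620),
pan-cytokeratin (Opal 690), DAPI counterstain. An autofluorescence
component rides along in every spectral library under ``AF_NAME``.
"""

AF_NAME = "AF"

#: marker column stem -> fluorophore carrying it
MARKER_TO_FLUOR = {
    "ndufb8": "Opal520",
    "tomm20": "Opal570",
    "mtco1": "Opal620",
    "ck": "Opal690",
    "dapi": "DAPI",
}

FLUOR_TO_MARKER = {v: k for k, v in MARKER_TO_FLUOR.items()}

#: library order: DAPI first, then Opals by wavelength
FLUOROPHORES = ("DAPI", "Opal520", "Opal570", "Opal620", "Opal690")

#: markers that enter the Z-score analysis
MITO_MARKERS = ("ndufb8", "mtco1", "tomm20")

#: CellTable OD columns, in canonical CSV order
OD_COLUMNS = ("od_ndufb8", "od_mtco1", "od_tomm20", "od_ck", "od_dapi")
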