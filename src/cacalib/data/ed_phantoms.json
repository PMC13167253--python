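{
  "comment": "Digital electron-density phantom geometry and nominal insert HU at the calcium-scoring (CSCT) effective energy. Insert HU values are editable configuration defaults for the simulator, not measured reference data. Lengths in mm.",
  "insert_radius_mm": 15.0,
  "body_hu": 30.0,
  "air_hu": -1000.0,
  "insert_hu_csct": {
    "adipose": -70.0,
    "breast": -35.0,
    "muscle": 44.0,
    "liver": 54.0,
    "cortical_bone": 1500.0,
    "HA200": 220.0,
    "HA800": 855.0,
    "HA1000": 1050.0,
    "HA1250": 1280.0,
    "lung_inhale": -810.0,
    "lung_exhale": -500.0
  },
  "core_inserts": ["adipose", "breast", "muscle", "liver", "cortical_bone",
                   "HA200", "HA800", "HA1000", "HA1250"],
  "core_ring_radius_mm": 57.0,
  "outer_inserts": ["lung_inhale", "lung_exhale", "adipose", "breast",
                    "muscle", "liver", "HA200", "HA800"],
  "outer_ring_axes_mm": [115.0, 105.0],
  "variants": {
    "ED1": {"body_axes_mm": [180.0, 180.0]},
    "ED2": {"body_axes_mm": [230.0, 230.0]},
    "ED3": {"body_axes_mm": [280.0, 280.0]},
    "ED4": {"body_axes_mm": [320.0, 270.0]}
  }
}
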