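# Example configuration: color thresholds, segmentation geometry, calibration.
# Every value shown is the package default; override what your staining batch
# or scanner requires.  Load with `omsbseg --config` or omsbseg.load_config().
calibration:
  microns_per_pixel: 0.5
color:
  white_min_value: 0.85        # brightness floor for unstained (white) pixels
  white_max_saturation: 0.15   # saturation ceiling for white
  hue_ranges:                  # degrees; [low, high), low > high wraps at 360
    erythrocyte_yellow: [40, 70]
    collagen_blue: [190, 260]
    elastic_purple: [260, 320]
    red_pink: [320, 40]
  priority: [elastic_purple, collagen_blue, erythrocyte_yellow, red_pink]
segmentation:
  min_enclosed_area: 500       # px; smallest interior a lamina ring may enclose
  closing_radius: 3            # px; bridges broken elastic laminae
  max_thickness: 25.0          # px; rejects compact purple blobs (nuclei, foam cells)
  min_rbc_pixels: 10           # px of yellow needed to call a white area lumen
  allow_single_lamina: false   # zero-width media fallback for grazing sections
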