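# Default run configuration.
# Paths set to null fall back to the constants embedded in the package.
nuclide_file: null
organ_model_file: null
injected_activity_kbq: 740
rounding_decimals: 1
seed: 12345
censor_day: 160
rbe: 4.0
# "undetermined" deaths are events by default (matches how the emulated
# study tabulates them); set false to censor them instead.
undetermined_is_event: true
# Normal ranges are configuration, not code: replace with the intervals of
# your own reference, and keep the citation field honest.
normal_ranges:
  alat:
    lower: 0.0
    upper: 50.0
    units: IU/L
    citation: "C57BL/6 mouse reference interval, implementer-chosen from published clinical-chemistry ranges"
  asat:
    lower: 0.0
    upper: 150.0
    units: IU/L
    citation: "C57BL/6 mouse reference interval, implementer-chosen from published clinical-chemistry ranges"
  creatinine:
    lower: 0.0
    upper: 0.5
    units: mg/dL
    citation: "C57BL/6 mouse reference interval, implementer-chosen from published clinical-chemistry ranges"
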