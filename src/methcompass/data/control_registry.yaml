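# BeadArray control-metric registry: 17 assay-step quality checks.
#
# Each metric is a ratio aggregate(numerator) / aggregate(denominator), passed
# when value >= threshold. BACKGROUND resolves to the sample's mean
# extension-green intensity. A +1 denominator offset is applied when the
# denominator aggregate would otherwise be 0. Thresholds follow Illumina's
# BeadArray Controls Reporter defaults and are meant to be edited: the
# restoration metric in particular has a documented alternative threshold of 1
# for FFPE workflows (default 0 never fails a nonnegative ratio).
metrics:
  - name: restoration
    numerator: {control_type: restoration, channel: green, aggregate: mean}
    denominator: BACKGROUND
    threshold: 0.0
  - name: staining green
    numerator: {control_type: biotin_staining_high, channel: green, aggregate: mean}
    denominator: BACKGROUND
    threshold: 5.0
  - name: staining red
    numerator: {control_type: dnp_staining_high, channel: red, aggregate: mean}
    denominator: BACKGROUND
    threshold: 5.0
  - name: extension green
    numerator: {control_type: extension_cg, channel: green, aggregate: min}
    denominator: {control_type: extension_at, channel: green, aggregate: max}
    threshold: 5.0
  - name: extension red
    numerator: {control_type: extension_at, channel: red, aggregate: min}
    denominator: {control_type: extension_cg, channel: red, aggregate: max}
    threshold: 5.0
  - name: hybridization high/medium
    numerator: {control_type: hybridization_high, channel: green, aggregate: mean}
    denominator: {control_type: hybridization_medium, channel: green, aggregate: mean}
    threshold: 1.0
  - name: hybridization medium/low
    numerator: {control_type: hybridization_medium, channel: green, aggregate: mean}
    denominator: {control_type: hybridization_low, channel: green, aggregate: mean}
    threshold: 1.0
  - name: target removal 1
    numerator: BACKGROUND
    denominator: {control_type: target_removal_1, channel: green, aggregate: mean}
    threshold: 1.0
  - name: target removal 2
    numerator: BACKGROUND
    denominator: {control_type: target_removal_2, channel: green, aggregate: mean}
    threshold: 1.0
  - name: bisulfite conversion I green
    numerator: {control_type: bisulfite_I_converted_green, channel: green, aggregate: min}
    denominator: {control_type: bisulfite_I_unconverted_green, channel: green, aggregate: max}
    threshold: 1.0
  - name: bisulfite conversion I red
    numerator: {control_type: bisulfite_I_converted_red, channel: red, aggregate: min}
    denominator: {control_type: bisulfite_I_unconverted_red, channel: red, aggregate: max}
    threshold: 1.0
  - name: bisulfite conversion II
    numerator: {control_type: bisulfite_II, channel: red, aggregate: min}
    denominator: {control_type: bisulfite_II, channel: green, aggregate: max}
    threshold: 1.0
  - name: specificity I green
    numerator: {control_type: specificity_I_pm_green, channel: green, aggregate: min}
    denominator: {control_type: specificity_I_mm_green, channel: green, aggregate: max}
    threshold: 1.0
  - name: specificity I red
    numerator: {control_type: specificity_I_pm_red, channel: red, aggregate: min}
    denominator: {control_type: specificity_I_mm_red, channel: red, aggregate: max}
    threshold: 1.0
  - name: specificity II
    numerator: {control_type: specificity_II, channel: red, aggregate: min}
    denominator: {control_type: specificity_II, channel: green, aggregate: max}
    threshold: 1.0
  - name: non-polymorphic green
    numerator: {control_type: nonpolymorphic_cg, channel: green, aggregate: min}
    denominator: {control_type: nonpolymorphic_at, channel: green, aggregate: max}
    threshold: 5.0
  - name: non-polymorphic red
    numerator: {control_type: nonpolymorphic_at, channel: red, aggregate: min}
    denominator: {control_type: nonpolymorphic_cg, channel: red, aggregate: max}
    threshold: 5.0
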