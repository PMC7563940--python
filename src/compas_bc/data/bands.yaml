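# Five ER/PR/HER2/Ki-67 subtype groups with their TVDT bands, ordered
# fastest (V, triple-negative) to slowest (I, luminal A).
#
# tvdt_pt_range / tvdt_mts_range: closed integer-day bands.
# tvdt_pt_display: the range as printed in the published summary table
#   (differs from the model range only for band V: 80-135 vs 10-135).
# mean_tvdt_mts_range: half the display range, floored (metastases may
#   grow up to ~2.2x faster than the primary tumour).
# screening_interval_months: the summary-table interval;
# screening_interval_narrative_months: the prose recommendation, which
#   differs only for band I (9 vs 12 months).
bands:
  - band_id: V
    label: Triple-negative
    receptor_rule: "HR(-)/HER2(-), Ki-67 >= 14%"
    tvdt_pt_range: [10, 135]
    tvdt_pt_display: [80, 135]
    tvdt_mts_range: [10, 135]
    mean_tvdt_mts_range: [40, 67]
    growth_class: rapid
    prognosis_table_label: Poor
    prognosis_app_label: unfavorable
    screening_interval_months: 3
    screening_interval_narrative_months: 3
  - band_id: IV
    label: HER2-positive
    receptor_rule: "HR(-)/HER2(+), Ki-67 >= 14%"
    tvdt_pt_range: [136, 165]
    tvdt_pt_display: [136, 165]
    tvdt_mts_range: [136, 165]
    mean_tvdt_mts_range: [68, 82]
    growth_class: intermediate
    prognosis_table_label: Intermediate
    prognosis_app_label: mid-favorable
    screening_interval_months: 5
    screening_interval_narrative_months: 5
  - band_id: III
    label: Luminal B (HER2-negative)
    receptor_rule: "HR(+)/HER2(-), Ki-67 >= 14%"
    tvdt_pt_range: [166, 195]
    tvdt_pt_display: [166, 195]
    tvdt_mts_range: [166, 195]
    mean_tvdt_mts_range: [83, 97]
    growth_class: intermediate
    prognosis_table_label: Intermediate
    prognosis_app_label: mid-favorable
    screening_interval_months: 6
    screening_interval_narrative_months: 6
  - band_id: II
    label: Luminal B (HER2-positive)
    receptor_rule: "HR(+)/HER2(+), Ki-67 >= 14%"
    tvdt_pt_range: [196, 230]
    tvdt_pt_display: [196, 230]
    tvdt_mts_range: [196, 230]
    mean_tvdt_mts_range: [98, 115]
    growth_class: slow
    prognosis_table_label: Intermediate
    prognosis_app_label: mid-favorable
    screening_interval_months: 8
    screening_interval_narrative_months: 8
  - band_id: I
    label: Luminal A
    receptor_rule: "HR(+)/HER2(-), Ki-67 < 14%"
    tvdt_pt_range: [231, 270]
    tvdt_pt_display: [231, 270]
    tvdt_mts_range: [231, 270]
    mean_tvdt_mts_range: [116, 135]
    growth_class: very slow
    prognosis_table_label: Good
    prognosis_app_label: favorable
    screening_interval_months: 12
    screening_interval_narrative_months: 9
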