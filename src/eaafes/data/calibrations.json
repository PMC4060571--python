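{
  "schema_version": 1,
  "description": "Per-subject stimulation-current limits (mA): flexor = biceps, extensor = triceps; i_min = contraction threshold, i_max = pain-free maximum.",
  "subjects": {
    "A": {"schema_version": 1, "subject_id": "A", "flexor": {"i_max_ma": 15.5, "i_min_ma": 6.5}, "extensor": {"i_max_ma": 11.5, "i_min_ma": 4.0}},
    "B": {"schema_version": 1, "subject_id": "B", "flexor": {"i_max_ma": 11.5, "i_min_ma": 2.5}, "extensor": {"i_max_ma": 11.0, "i_min_ma": 5.0}},
    "C": {"schema_version": 1, "subject_id": "C", "flexor": {"i_max_ma": 11.5, "i_min_ma": 7.0}, "extensor": {"i_max_ma": 15.0, "i_min_ma": 8.0}},
    "D": {"schema_version": 1, "subject_id": "D", "flexor": {"i_max_ma": 12.0, "i_min_ma": 4.5}, "extensor": {"i_max_ma": 10.0, "i_min_ma": 6.0}},
    "E": {"schema_version": 1, "subject_id": "E", "flexor": {"i_max_ma": 14.0, "i_min_ma": 6.0}, "extensor": {"i_max_ma": 13.0, "i_min_ma": 6.0}},
    "F": {"schema_version": 1, "subject_id": "F", "flexor": {"i_max_ma": 12.0, "i_min_ma": 3.5}, "extensor": {"i_max_ma": 14.0, "i_min_ma": 8.0}}
  }
}
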