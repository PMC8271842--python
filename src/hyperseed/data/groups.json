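{
  "description": "Default adulteration benchmark: 13 groups over 4 seed varieties. 'target' is the 1-based variety index treated as the pure (positive) class; 'counts' are seeds drawn per variety.",
  "varieties": ["variety_1", "variety_2", "variety_3", "variety_4"],
  "groups": [
    {"group_id": 1,  "target": 1, "counts": [72, 24, 24, 24]},
    {"group_id": 2,  "target": 1, "counts": [72, 12, 12, 12]},
    {"group_id": 3,  "target": 1, "counts": [72, 6, 6, 6]},
    {"group_id": 4,  "target": 1, "counts": [72, 3, 3, 3]},
    {"group_id": 5,  "target": 1, "counts": [72, 24, 12, 6]},
    {"group_id": 6,  "target": 1, "counts": [72, 12, 24, 6]},
    {"group_id": 7,  "target": 1, "counts": [72, 6, 12, 24]},
    {"group_id": 8,  "target": 1, "counts": [72, 36, 0, 0]},
    {"group_id": 9,  "target": 1, "counts": [72, 0, 36, 0]},
    {"group_id": 10, "target": 1, "counts": [72, 0, 0, 36]},
    {"group_id": 11, "target": 2, "counts": [12, 72, 12, 12]},
    {"group_id": 12, "target": 3, "counts": [12, 12, 72, 12]},
    {"group_id": 13, "target": 4, "counts": [12, 12, 12, 72]}
  ]
}
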