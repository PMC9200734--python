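{
  "units": "cm",
  "subject": {
    "id": "example-001",
    "age_years": 52,
    "sex": "M",
    "bsa_m2": 1.95
  },
  "linear": {
    "ivs_cm": 1.0,
    "lvid_cm": 4.0,
    "pwt_cm": 1.0
  },
  "sax": {
    "a1_cm2": 28.2743,
    "a2_cm2": 12.5664,
    "level": "chordae"
  },
  "long_axis": {
    "a_cm": 4.8,
    "d_cm": 3.2
  },
  "disc_stack": {
    "semi_axes": [
      [
        2.0,
        2.0
      ],
      [
        2.0,
        2.0
      ],
      [
        2.0,
        2.0
      ],
      [
        2.0,
        2.0
      ],
      [
        2.0,
        2.0
      ],
      [
        2.0,
        2.0
      ],
      [
        2.0,
        2.0
      ],
      [
        2.0,
        2.0
      ],
      [
        2.0,
        2.0
      ],
      [
        2.0,
        2.0
      ],
      [
        2.0,
        2.0
      ],
      [
        2.0,
        2.0
      ],
      [
        2.0,
        2.0
      ],
      [
        2.0,
        2.0
      ],
      [
        2.0,
        2.0
      ],
      [
        2.0,
        2.0
      ],
      [
        2.0,
        2.0
      ],
      [
        2.0,
        2.0
      ],
      [
        2.0,
        2.0
      ],
      [
        2.0,
        2.0
      ],
      [
        2.0,
        2.0
      ],
      [
        2.0,
        2.0
      ],
      [
        2.0,
        2.0
      ],
      [
        2.0,
        2.0
      ],
      [
        2.0,
        2.0
      ],
      [
        2.0,
        2.0
      ],
      [
        2.0,
        2.0
      ],
      [
        2.0,
        2.0
      ],
      [
        2.0,
        2.0
      ],
      [
        2.0,
        2.0
      ]
    ],
    "length_4ch_cm": 8.0,
    "length_2ch_cm": 8.0
  }
}
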