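{
  "segments": [
    [
      [
        -5.0,
        0.0
      ],
      [
        5.0,
        0.0
      ]
    ],
    [
      [
        -5.0,
        0.0
      ],
      [
        -5.0,
        3.0
      ]
    ],
    [
      [
        -5.0,
        -3.0
      ],
      [
        -5.0,
        0.0
      ]
    ],
    [
      [
        5.0,
        0.0
      ],
      [
        5.0,
        3.0
      ]
    ],
    [
      [
        5.0,
        -3.0
      ],
      [
        5.0,
        0.0
      ]
    ],
    [
      [
        -8.0,
        3.0
      ],
      [
        -5.0,
        3.0
      ]
    ],
    [
      [
        -8.0,
        -3.0
      ],
      [
        -5.0,
        -3.0
      ]
    ],
    [
      [
        5.0,
        3.0
      ],
      [
        8.0,
        3.0
      ]
    ],
    [
      [
        5.0,
        -3.0
      ],
      [
        8.0,
        -3.0
      ]
    ]
  ],
  "reward_points": {
    "R1": [
      -8.0,
      3.0
    ],
    "R2": [
      -8.0,
      -3.0
    ],
    "R3": [
      8.0,
      3.0
    ],
    "R4": [
      8.0,
      -3.0
    ]
  },
  "choice_junction": [
    5.0,
    0.0
  ],
  "guided_junction": [
    -5.0,
    0.0
  ]
}
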