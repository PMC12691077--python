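[
  {
    "category": "LU",
    "description": "Next to the hind leg of the cow, where the hind leg connects to the RU, the RU is not visible when the LU is visible",
    "is_roi": true
  },
  {
    "category": "AA",
    "description": "Located at the top of the RU, above the hindquarters, adjacent to the stifle",
    "is_roi": true
  },
  {
    "category": "RU",
    "description": "From the rear of the cow, it can be observed located below the AA region, adjacent to the hind legs, and connected to the LU at the lowest point",
    "is_roi": false
  },
  {
    "category": "hind_legs",
    "description": "Next to the LU, RU, and AA",
    "is_roi": false
  },
  {
    "category": "hind_quarters",
    "description": "Including the AA, upper side of the tail, and entire hindquarters",
    "is_roi": false
  }
]
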