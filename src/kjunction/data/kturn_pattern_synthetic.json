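{
  "translation_tol": 4.0,
  "rotation_tol": 25.0,
  "provenance": [
    "synthetic canonical k-turn geometry: NC-helix segment kinked ~115 deg about the base-pair normal of the C-helix reference segment (approximating the tight ~60 deg included inter-axis angle of the kink) with additional twist/tilt components (rotation vector (30, 15, 115) deg in the axis/hbond/normal triad) and displaced (7.0, 3.0, 2.0) A in the reference frame; ideal coordinates, not derived from any deposited structure"
  ],
  "entries": [
    {
      "translation": [7.0, 3.0, 2.0],
      "rotvec_deg": [30.0, 15.0, 115.0]
    }
  ]
}
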