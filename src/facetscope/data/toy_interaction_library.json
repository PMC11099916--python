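{
  "comment": "SYNTHETIC toy interaction-field library for tests and demos. Geometries are chemically plausible hydrogen-bond / hydrophobic lobes; the numbers are NOT derived from the CSD, IsoStar or any structural database.",
  "probes": [
    {"name": "uncharged NH nitrogen", "exclusion_radius": 1.5},
    {"name": "carbonyl oxygen", "exclusion_radius": 1.5},
    {"name": "water oxygen", "exclusion_radius": 1.4},
    {"name": "aromatic CH carbon", "exclusion_radius": 1.7},
    {"name": "charged NH nitrogen", "exclusion_radius": 1.5}
  ],
  "rules": [
    {"group": "uncharged carboxylic acid", "probe": "uncharged NH nitrogen",
     "anchor_atom": 1, "direction_from": 0, "distance": 2.9, "half_angle": 60,
     "peak": 80.0, "width": 0.5,
     "comment": "donor probe toward the carbonyl O lone pairs"},
    {"group": "uncharged carboxylic acid", "probe": "carbonyl oxygen",
     "anchor_atom": 3, "direction_from": 2, "distance": 1.9, "half_angle": 45,
     "peak": 100.0, "width": 0.5,
     "comment": "acceptor probe along the O-H vector"},
    {"group": "uncharged carboxylic acid", "probe": "water oxygen",
     "anchor_atom": 3, "direction_from": 2, "distance": 1.9, "half_angle": 60,
     "peak": 110.0, "width": 0.6,
     "comment": "water accepts from the hydroxyl"},
    {"group": "uncharged carboxylic acid", "probe": "water oxygen",
     "anchor_atom": 1, "direction_from": 0, "distance": 2.9, "half_angle": 60,
     "peak": 90.0, "width": 0.6,
     "comment": "water donates to the carbonyl"},
    {"group": "uncharged carboxylic acid", "probe": "charged NH nitrogen",
     "anchor_atom": 1, "direction_from": 0, "distance": 2.8, "half_angle": 60,
     "peak": 95.0, "width": 0.5},
    {"group": "methyl", "probe": "aromatic CH carbon",
     "anchor_atom": 0, "direction_from": null, "distance": 3.8, "half_angle": 80,
     "peak": 30.0, "width": 0.8,
     "comment": "diffuse hydrophobic contact above alkyl carbons"}
  ]
}
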