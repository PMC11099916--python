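{
  "comment": "Default surface functional-group query library. Patterns are SMARTS over molecules with explicit hydrogens. Larger groups do not suppress contained smaller ones.",
  "groups": [
    {
      "name": "methyl",
      "smarts": "[CX4H3]"
    },
    {
      "name": "i-propyl",
      "smarts": "[CX4H3][CX4H1]([CX4H3])[#6]"
    },
    {
      "name": "aliphatic-aromatic methylene",
      "smarts": "[CX4H2](c)[C;!c]"
    },
    {
      "name": "tertiary C-H",
      "smarts": "[CX4H1]"
    },
    {
      "name": "uncharged carboxylic acid",
      "smarts": "[CX3](=[OX1])[OX2H1][H]"
    }
  ]
}
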