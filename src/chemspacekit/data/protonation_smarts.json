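{
  "comment": "SMARTS patterns defining acidic and basic heavy atoms; counted atoms are the unique atom indices matched by any pattern. Editable configuration.",
  "acidic": [
    "[CX3](=O)[OX2H1]",
    "[CX3](=O)[OX1-]",
    "[SX4](=O)(=O)[OX2H1,OX1-]",
    "[SX3](=O)[OX2H1,OX1-]",
    "[PX4](=O)([OX2H1,OX1-])",
    "c1nnn[nH]1",
    "[OX2H][c]"
  ],
  "basic": [
    "[NX3;H2,H1,H0;+0;!$(N=*);!$(N[a]);!$(NC=[O,S,N]);!$(NS(=O)=O)]",
    "[NX3][CX3]=[NX2]",
    "[NX2;+0;!$(N=C=O)]=[CX3]",
    "[n;X2;+0;!$([n][#1])]"
  ]
}
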