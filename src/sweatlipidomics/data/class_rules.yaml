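# Per-class chemistry and MRM rules for the pseudotargeted lipid panel.
#
# kind: ester   -> elemental formula = backbone + n_chains ester-linked acyl
#                  chains; the chains jointly contribute C(n) H(2n-2d-2k) O(k)
#                  for total carbons n, total double bonds d and k = n_chains.
#                  With ether: true, one ester linkage is replaced by an
#                  alkyl/alkenyl ether (net +2 H, -1 O); O-/P- subtypes are
#                  not distinguished (all double bonds counted in d).
# kind: sphingo -> formula = long-chain base (dM:k -> C(M) H(2M+3-2k) N O2)
#                  + amide-linked N-acyl chain (C(n) H(2n-2d-2) O)
#                  + head_addition.
#
# product rules:
#   fragment     -> charged fragment of fixed formula; m/z = mass +/- proton
#   neutral_loss -> product = precursor - monoisotopic mass of `formula`
#   pseudo       -> product = precursor (pseudo-MRM)
#   lcb_fragment -> dehydrated long-chain-base cation, [LCB + H - 2 H2O]+
#
# enumerate blocks define the default theoretical panel (carbon/double-bond
# ranges are inclusive). Sphingolipid classes iterate the long-chain bases
# seen in skin-surface lipids and vary the N-acyl chain.
classes:
  CE:
    name: cholesteryl esters
    kind: ester
    backbone: {C: 27, H: 46, O: 1}
    n_chains: 1
    polarity: positive
    adduct: "[M+NH4]+"
    product: {rule: fragment, formula: {C: 27, H: 44}}   # cholestadienyl cation 369.3516
    enumerate: {carbons: [12, 24], double_bonds: [0, 6]}
  Cer:
    name: ceramides
    kind: sphingo
    head_addition: {}
    polarity: positive
    adduct: "[M+H]+"
    product: {rule: lcb_fragment}
    enumerate:
      long_chain_bases: ["d16:0", "d16:1", "d18:0", "d18:1", "d20:1"]
      n_acyl_carbons: [12, 28]
      n_acyl_double_bonds: [0, 3]
  HexCer:
    name: hexosylceramides
    kind: sphingo
    head_addition: {C: 6, H: 10, O: 5}
    polarity: positive
    adduct: "[M+H]+"
    product: {rule: lcb_fragment}
    enumerate:
      long_chain_bases: ["d16:0", "d16:1", "d18:0", "d18:1", "d20:1"]
      n_acyl_carbons: [12, 28]
      n_acyl_double_bonds: [0, 3]
  LPC:
    name: lysophosphatidylcholines
    kind: ester
    backbone: {C: 8, H: 20, N: 1, O: 6, P: 1}
    n_chains: 1
    polarity: positive
    adduct: "[M+H]+"
    product: {rule: fragment, formula: {C: 5, H: 14, N: 1, O: 4, P: 1}}  # phosphocholine 184.0733
    enumerate: {carbons: [12, 24], double_bonds: [0, 5]}
  PC:
    name: phosphatidylcholines
    kind: ester
    backbone: {C: 8, H: 20, N: 1, O: 6, P: 1}
    n_chains: 2
    polarity: positive
    adduct: "[M+H]+"
    product: {rule: fragment, formula: {C: 5, H: 14, N: 1, O: 4, P: 1}}
    enumerate: {carbons: [26, 48], double_bonds: [0, 11]}
  PCO:
    name: ether/plasmalogen phosphatidylcholines
    kind: ester
    backbone: {C: 8, H: 20, N: 1, O: 6, P: 1}
    n_chains: 2
    ether: true
    polarity: positive
    adduct: "[M+H]+"
    product: {rule: fragment, formula: {C: 5, H: 14, N: 1, O: 4, P: 1}}
    enumerate: {carbons: [26, 48], double_bonds: [0, 11]}
  LPE:
    name: lysophosphatidylethanolamines
    kind: ester
    backbone: {C: 5, H: 14, N: 1, O: 6, P: 1}
    n_chains: 1
    polarity: positive
    adduct: "[M+H]+"
    product: {rule: neutral_loss, formula: {C: 2, H: 8, N: 1, O: 4, P: 1}}  # phosphoethanolamine 141.0191
    enumerate: {carbons: [12, 24], double_bonds: [0, 5]}
  PE:
    name: phosphatidylethanolamines
    kind: ester
    backbone: {C: 5, H: 14, N: 1, O: 6, P: 1}
    n_chains: 2
    polarity: positive
    adduct: "[M+H]+"
    product: {rule: neutral_loss, formula: {C: 2, H: 8, N: 1, O: 4, P: 1}}
    enumerate: {carbons: [26, 48], double_bonds: [0, 11]}
  PEO:
    name: ether/plasmalogen phosphatidylethanolamines
    kind: ester
    backbone: {C: 5, H: 14, N: 1, O: 6, P: 1}
    n_chains: 2
    ether: true
    polarity: positive
    adduct: "[M+H]+"
    product: {rule: neutral_loss, formula: {C: 2, H: 8, N: 1, O: 4, P: 1}}
    enumerate: {carbons: [26, 48], double_bonds: [0, 11]}
  PI:
    name: phosphatidylinositols
    kind: ester
    backbone: {C: 9, H: 19, O: 11, P: 1}
    n_chains: 2
    polarity: negative
    adduct: "[M-H]-"
    product: {rule: fragment, formula: {C: 6, H: 11, O: 8, P: 1}}  # dehydrated inositol phosphate 241.0119
    enumerate: {carbons: [26, 48], double_bonds: [0, 11]}
  PS:
    name: phosphatidylserines
    kind: ester
    backbone: {C: 6, H: 14, N: 1, O: 8, P: 1}
    n_chains: 2
    polarity: negative
    adduct: "[M-H]-"
    product: {rule: neutral_loss, formula: {C: 3, H: 5, N: 1, O: 2}}  # serine - H2O, 87.0320
    enumerate: {carbons: [26, 48], double_bonds: [0, 11]}
  SM:
    name: sphingomyelins
    kind: sphingo
    head_addition: {C: 5, H: 12, N: 1, O: 3, P: 1}
    polarity: positive
    adduct: "[M+H]+"
    product: {rule: fragment, formula: {C: 5, H: 14, N: 1, O: 4, P: 1}}
    enumerate:
      long_chain_bases: ["d16:0", "d16:1", "d18:0", "d18:1", "d20:1"]
      n_acyl_carbons: [12, 28]
      n_acyl_double_bonds: [0, 3]
  DG:
    name: diacylglycerols
    kind: ester
    backbone: {C: 3, H: 8, O: 3}
    n_chains: 2
    polarity: positive
    adduct: "[M+NH4]+"
    product: {rule: neutral_loss, formula: {N: 1, H: 5, O: 1}}  # NH3 + H2O -> [M+H-H2O]+
    enumerate: {carbons: [24, 44], double_bonds: [0, 8]}
  TG:
    name: triacylglycerols
    kind: ester
    backbone: {C: 3, H: 8, O: 3}
    n_chains: 3
    polarity: positive
    adduct: "[M+NH4]+"
    product: {rule: neutral_loss, formula: {N: 1, H: 3}}  # NH3 -> [M+H]+
    enumerate: {carbons: [36, 66], double_bonds: [0, 13]}
  FA:
    name: free fatty acids
    kind: ester
    backbone: {H: 2, O: 1}
    n_chains: 1
    polarity: negative
    adduct: "[M-H]-"
    product: {rule: pseudo}
    enumerate: {carbons: [10, 26], double_bonds: [0, 6]}
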