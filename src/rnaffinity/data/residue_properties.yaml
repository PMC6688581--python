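# Per-amino-acid property table, version 1.
#
# mass: average molecular weight of the free amino acid, Da.
# hbond: hydrogen-bonding capacity = side-chain donor+acceptor site count
#        plus 2 backbone sites (amide NH donor + carbonyl O acceptor).
# classes: physicochemical memberships used by the residue-class features.
#          hydrophilic and hydrophobic are mutually exclusive by construction
#          (hydrophilic = complement of the hydrophobic set among the 20).
version: 1
mass:
  A: 89.09
  R: 174.20
  N: 132.12
  D: 133.10
  C: 121.16
  E: 147.13
  Q: 146.15
  G: 75.07
  H: 155.15
  I: 131.17
  L: 131.17
  K: 146.19
  M: 149.21
  F: 165.19
  P: 115.13
  S: 105.09
  T: 119.12
  W: 204.23
  Y: 181.19
  V: 117.15
hbond:
  A: 2
  R: 8
  N: 6
  D: 6
  C: 3
  E: 6
  Q: 6
  G: 2
  H: 5
  I: 2
  L: 2
  K: 5
  M: 2
  F: 2
  P: 1
  S: 5
  T: 5
  W: 3
  Y: 5
  V: 2
classes:
  hydrophobic: [A, V, L, I, M, F, W, C]
  hydrophilic: [R, K, D, E, N, Q, H, S, T, Y, G, P]
  aromatic: [F, W, Y, H]
  positively_charged: [K, R, H]
  charged: [D, E, K, R, H]
  polar: [S, T, N, Q, Y, C, H]
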