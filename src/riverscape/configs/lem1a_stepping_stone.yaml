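# Seven-bioregion stepping-stone LEM (single slice, binary adjacency).
#
# Bioregions of tropical South America: B = Brazilian Shield, G = Guiana
# Shield, L = La Plata, N = Negro, O = Orinoco, T = Trans-Andean,
# W = Western Amazon.  The adjacency below is a SYNTHETIC reconstruction of
# plausible modern drainage contacts (Casiquiare: N-O; Rupununi: G-O;
# Izozog: L-W; Sub-Andean foreland: T-O/T-W; Amazon mainstem: W-B/W-N),
# shipped as a documented example, not a verbatim copy of any published
# supplementary matrix.
name: LEM1a
regions:
  - {code: B, name: Brazilian Shield}
  - {code: G, name: Guiana Shield}
  - {code: L, name: La Plata}
  - {code: N, name: Negro}
  - {code: O, name: Orinoco}
  - {code: T, name: Trans-Andean}
  - {code: W, name: Western Amazon}
adjacency:
  - [0, 0, 1, 0, 0, 0, 1]   # B
  - [0, 0, 0, 1, 1, 0, 0]   # G
  - [1, 0, 0, 0, 0, 0, 1]   # L
  - [0, 1, 0, 0, 1, 0, 1]   # N
  - [0, 1, 0, 1, 0, 1, 1]   # O
  - [0, 0, 0, 0, 1, 0, 1]   # T
  - [1, 0, 1, 1, 1, 1, 0]   # W
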