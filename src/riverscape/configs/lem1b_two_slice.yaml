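# Seven-bioregion two-time-slice paleogeographic LEM.
#
# Slice 1 (pre-10 Ma, start clamped to the root age): Pebas-era,
# Caribbean-draining connectivity — strong N-O-W exchange, Trans-Andean
# contact via the Caribbean outlet, weak or absent links to the Brazilian
# Shield and La Plata.  Slice 2 (10-0 Ma): modern transcontinental-Amazon
# connectivity (Amazon-Caribbean, Amazon-Orinoco, Amazon-Parana contacts
# opened).  Multipliers are a SYNTHETIC reconstruction of the scenario
# described in the literature, shipped as a documented example; weak
# corridors are down-weighted to 0.1 rather than closed entirely.
name: LEM1b
regions:
  - {code: B, name: Brazilian Shield}
  - {code: G, name: Guiana Shield}
  - {code: L, name: La Plata}
  - {code: N, name: Negro}
  - {code: O, name: Orinoco}
  - {code: T, name: Trans-Andean}
  - {code: W, name: Western Amazon}
slices:
  - start_age: inf
    end_age: 10
    matrix:
      - [0.0, 0.0, 0.1, 0.1, 0.0, 0.0, 0.1]   # B
      - [0.0, 0.0, 0.0, 1.0, 1.0, 0.0, 0.0]   # G
      - [0.1, 0.0, 0.0, 0.0, 0.0, 0.0, 0.1]   # L
      - [0.1, 1.0, 0.0, 0.0, 1.0, 0.0, 1.0]   # N
      - [0.0, 1.0, 0.0, 1.0, 0.0, 1.0, 1.0]   # O
      - [0.0, 0.0, 0.0, 0.0, 1.0, 0.0, 1.0]   # T
      - [0.1, 0.0, 0.1, 1.0, 1.0, 1.0, 0.0]   # W
  - start_age: 10
    end_age: 0
    matrix:
      - [0.0, 0.0, 1.0, 0.0, 0.0, 0.0, 1.0]   # B
      - [0.0, 0.0, 0.0, 1.0, 1.0, 0.0, 0.0]   # G
      - [1.0, 0.0, 0.0, 0.0, 0.0, 0.0, 1.0]   # L
      - [0.0, 1.0, 0.0, 0.0, 1.0, 0.0, 1.0]   # N
      - [0.0, 1.0, 0.0, 1.0, 0.0, 1.0, 1.0]   # O
      - [0.0, 0.0, 0.0, 0.0, 1.0, 0.0, 1.0]   # T
      - [1.0, 0.0, 1.0, 1.0, 1.0, 1.0, 0.0]   # W
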