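slab:
  z_lo: 3.0
  z_hi: 7.0
monomers:
- cavity:
    shape: prism
    vertices:
    - - 4.0
      - 4.0
    - - 8.0
      - 4.0
    - - 8.0
      - 8.0
    - - 4.0
      - 8.0
    z_lo: 3.0
    z_hi: 7.0
  channels:
  - label: I
    interior:
      shape: prism
      vertices:
      - - 3.0
        - 5.5
      - - 4.0
        - 5.5
      - - 4.0
        - 6.5
      - - 3.0
        - 6.5
      z_lo: 4.0
      z_hi: 6.0
    inner_gate:
      point:
      - 4.0
      - 6.0
      - 5.0
      normal:
      - 1.0
      - 0.0
      - 0.0
    outer_gate:
      point:
      - 3.0
      - 6.0
      - 5.0
      normal:
      - -1.0
      - 0.0
      - 0.0
  - label: II
    interior:
      shape: prism
      vertices:
      - - 4.75
        - 3.0
      - - 5.75
        - 3.0
      - - 5.75
        - 4.0
      - - 4.75
        - 4.0
      z_lo: 4.0
      z_hi: 6.0
    inner_gate:
      point:
      - 5.25
      - 4.0
      - 5.0
      normal:
      - 0.0
      - 1.0
      - 0.0
    outer_gate:
      point:
      - 5.25
      - 3.0
      - 5.0
      normal:
      - 0.0
      - -1.0
      - 0.0
  - label: III
    interior:
      shape: prism
      vertices:
      - - 6.25
        - 3.0
      - - 7.25
        - 3.0
      - - 7.25
        - 4.0
      - - 6.25
        - 4.0
      z_lo: 4.0
      z_hi: 6.0
    inner_gate:
      point:
      - 6.75
      - 4.0
      - 5.0
      normal:
      - 0.0
      - 1.0
      - 0.0
    outer_gate:
      point:
      - 6.75
      - 3.0
      - 5.0
      normal:
      - 0.0
      - -1.0
      - 0.0
  site:
    shape: spheres
    centers:
    - - 6.0
      - 6.0
      - 5.5
    radii:
    - 0.5
  footprint:
    shape: prism
    vertices:
    - - 3.5
      - 3.5
    - - 8.5
      - 3.5
    - - 8.5
      - 8.5
    - - 3.5
      - 8.5
    z_lo: 3.0
    z_hi: 7.0
- cavity:
    shape: prism
    vertices:
    - - 16.0
      - 4.0
    - - 20.0
      - 4.0
    - - 20.0
      - 8.0
    - - 16.0
      - 8.0
    z_lo: 3.0
    z_hi: 7.0
  channels:
  - label: I
    interior:
      shape: prism
      vertices:
      - - 20.0
        - 5.5
      - - 21.0
        - 5.5
      - - 21.0
        - 6.5
      - - 20.0
        - 6.5
      z_lo: 4.0
      z_hi: 6.0
    inner_gate:
      point:
      - 20.0
      - 6.0
      - 5.0
      normal:
      - -1.0
      - 0.0
      - 0.0
    outer_gate:
      point:
      - 21.0
      - 6.0
      - 5.0
      normal:
      - 1.0
      - 0.0
      - 0.0
  - label: II
    interior:
      shape: prism
      vertices:
      - - 18.25
        - 3.0
      - - 19.25
        - 3.0
      - - 19.25
        - 4.0
      - - 18.25
        - 4.0
      z_lo: 4.0
      z_hi: 6.0
    inner_gate:
      point:
      - 18.75
      - 4.0
      - 5.0
      normal:
      - 0.0
      - 1.0
      - 0.0
    outer_gate:
      point:
      - 18.75
      - 3.0
      - 5.0
      normal:
      - 0.0
      - -1.0
      - 0.0
  - label: III
    interior:
      shape: prism
      vertices:
      - - 16.75
        - 3.0
      - - 17.75
        - 3.0
      - - 17.75
        - 4.0
      - - 16.75
        - 4.0
      z_lo: 4.0
      z_hi: 6.0
    inner_gate:
      point:
      - 17.25
      - 4.0
      - 5.0
      normal:
      - 0.0
      - 1.0
      - 0.0
    outer_gate:
      point:
      - 17.25
      - 3.0
      - 5.0
      normal:
      - 0.0
      - -1.0
      - 0.0
  site:
    shape: spheres
    centers:
    - - 18.0
      - 6.0
      - 5.5
    radii:
    - 0.5
  footprint:
    shape: prism
    vertices:
    - - 15.5
      - 3.5
    - - 20.5
      - 3.5
    - - 20.5
      - 8.5
    - - 15.5
      - 8.5
    z_lo: 3.0
    z_hi: 7.0
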