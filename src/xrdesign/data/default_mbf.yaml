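schema: xrdesign-model/1
name: default_mbf
conservation_threshold: 0.9
mean_length: 54.0
total_length_range:
- 34
- 74
elements:
- name: S5
  kind: linker
  length:
  - 4
  - 6
  mask: AAUANN
- name: PK1a
  kind: pseudoknot
  length:
  - 2
  - 2
  partner: PK1b
  pk_layer: 1
  mask: AG
- name: J5
  kind: linker
  length:
  - 1
  - 2
  mask: AN
- name: P1a
  kind: helix
  length:
  - 3
  - 3
  partner: P1b
  mask: GCG
- name: J12
  kind: linker
  length:
  - 0
  - 1
  mask: N
- name: P2a
  kind: helix
  length:
  - 0
  - 3
  partner: P2b
  mask: CNN
- name: L2
  kind: loop
  length:
  - 3
  - 6
  mask: NNNNNN
- name: P2b
  kind: helix
  length:
  - 0
  - 3
  partner: P2a
  mask: NNG
- name: J23
  kind: linker
  length:
  - 1
  - 1
  mask: N
- name: P3a
  kind: helix
  length:
  - 3
  - 7
  partner: P3b
  mask: GNNNNNN
- name: L3a
  kind: loop
  length:
  - 1
  - 3
  mask: NNN
- name: PK2a
  kind: pseudoknot
  length:
  - 3
  - 8
  partner: PK2b
  pk_layer: 2
  mask: NNNNNNNN
- name: L3b
  kind: loop
  length:
  - 0
  - 1
  mask: N
- name: P3b
  kind: helix
  length:
  - 3
  - 7
  partner: P3a
  mask: NNNNNNC
- name: PK1b
  kind: pseudoknot
  length:
  - 2
  - 2
  partner: PK1a
  pk_layer: 1
  mask: CU
- name: J31
  kind: linker
  length:
  - 0
  - 1
  mask: N
- name: P1b
  kind: helix
  length:
  - 3
  - 3
  partner: P1a
  mask: CGC
- name: J1pk
  kind: linker
  length:
  - 2
  - 5
  mask: NNNNN
- name: PK2b
  kind: pseudoknot
  length:
  - 3
  - 8
  partner: PK2a
  pk_layer: 2
  mask: NNNNNNNN
- name: S3
  kind: linker
  length:
  - 0
  - 2
  mask: NN
correlations:
- elements:
  - P3a
  - L3a
  rho: -0.9
  window: 1.0
base_triples:
- - S5
  - 2
  - P1a
  - 0
  - P1b
  - 2
  - BT1
- - J5
  - 0
  - P3a
  - 0
  - P3b
  - 6
  - BT2
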