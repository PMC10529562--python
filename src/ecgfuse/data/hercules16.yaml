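# 16-class beat scheme used for the unified multi-database corpus.
# Superclasses that subsume retained subclasses (e.g. the bundle branch
# block code B, parent of L and R) are excluded, as are non-beat
# annotation codes (rhythm changes, noise, artifacts).
# class_id is fixed; code is the conventional single-character WFDB
# beat mnemonic. Editable: supply your own file to build_class_map.
scheme: hercules16
classes:
  - {id: 0,  code: "N", abbr: NB,   name: Normal beat}
  - {id: 1,  code: "f", abbr: FPNB, name: Fusion of paced and normal beat}
  - {id: 2,  code: "e", abbr: AEB,  name: Atrial escape beat}
  - {id: 3,  code: "/", abbr: PB,   name: Paced beat}
  - {id: 4,  code: "j", abbr: NEB,  name: Nodal (junctional) escape beat}
  - {id: 5,  code: "n", abbr: SEB,  name: Supraventricular escape beat}
  - {id: 6,  code: "L", abbr: LBBB, name: Left bundle branch block beat}
  - {id: 7,  code: "R", abbr: RBBB, name: Right bundle branch block beat}
  - {id: 8,  code: "S", abbr: SP,   name: Supraventricular premature beat}
  - {id: 9,  code: "A", abbr: APB,  name: Atrial premature beat}
  - {id: 10, code: "J", abbr: NPB,  name: Nodal (junctional) premature beat}
  - {id: 11, code: "a", abbr: AAPB, name: Aberrated atrial premature beat}
  - {id: 12, code: "V", abbr: PVC,  name: Premature ventricular contraction}
  - {id: 13, code: "E", abbr: VEB,  name: Ventricular escape beat}
  - {id: 14, code: "F", abbr: FVNB, name: Fusion of ventricular and normal beat}
  - {id: 15, code: "Q", abbr: UB,   name: Unclassifiable beat}
excluded_codes: ["B", "P", "r", "+", "~", "|", "\"", "?", "!", "x", "[", "]", "(", ")"]
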