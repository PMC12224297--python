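# Default regulator subclass ruleset.
#
# Rules are evaluated in priority order (lower first); the first rule whose
# required/forbidden/exact constraints hold wins. `exact: true` means the
# protein's domain set must equal the matched required set ("solely" those
# domains; duplicate copies of a required domain are fine).
#
# The four SARP subclasses follow the published domain definitions. The
# remaining subclasses (marked `editable: true`) are domain-level stand-ins
# for a manually curated combination table and are intended to be replaced
# by the user's own curation when mining real genomes.
rules:
  - name: SARP_large
    family: SARP
    priority: 10
    required_any:
      - [Trans_reg_C, BTAD, TPR_10]
      - [Trans_reg_C, BTAD, TPR_12]
    forbidden: []
    exact: false

  - name: SARP_LAL
    family: SARP
    priority: 20
    required_any:
      - [Trans_reg_C, BTAD, AAA_16]
      - [Trans_reg_C, BTAD, AAA_22]
    forbidden: [TPR_10, TPR_12]
    exact: false

  - name: SARP_medium
    family: SARP
    priority: 30
    required_any:
      - [Trans_reg_C, BTAD, NB-ARC]
    forbidden: [TPR_10, TPR_12, AAA_16, AAA_22]
    exact: false

  - name: SARP_small
    family: SARP
    priority: 40
    required_any:
      - [Trans_reg_C, BTAD]
    forbidden: []
    exact: true

  - name: PAS_LuxR_large
    family: LuxR
    priority: 50
    required_any:
      - [GerE, PAS, PAS_4]
    forbidden: [Trans_reg_C, BTAD]
    exact: false
    editable: true

  - name: PAS_LuxR_small
    family: LuxR
    priority: 60
    required_any:
      - [GerE, PAS]
    forbidden: [Trans_reg_C, BTAD]
    exact: true
    editable: true

  - name: LuxR_AAA_16
    family: LuxR
    priority: 70
    required_any:
      - [GerE, AAA_16]
    forbidden: [Trans_reg_C, BTAD, PAS]
    exact: false
    editable: true

  - name: LitR
    family: LuxR
    priority: 80
    required_any:
      - [GerE]
    forbidden: []
    exact: true
    editable: true

  - name: ScbR
    family: TetR
    priority: 90
    required_any:
      - [TetR_N, GBL_bind]
    forbidden: []
    exact: false
    editable: true

  - name: TetR_C_33
    family: TetR
    priority: 100
    required_any:
      - [TetR_C_33]
    forbidden: []
    exact: true
    editable: true

  - name: XRE
    family: XRE
    priority: 110
    required_any:
      - [HTH_3]
    forbidden: []
    exact: true
    editable: true

  - name: NrdR
    family: NrdR
    priority: 120
    required_any:
      - [ATP-cone]
    forbidden: []
    exact: false
    editable: true

  - name: LexA
    family: LexA
    priority: 130
    required_any:
      - [LexA_DNA_bind, Peptidase_S24]
    forbidden: []
    exact: false
    editable: true
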