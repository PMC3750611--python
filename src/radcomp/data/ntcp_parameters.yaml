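# Built-in NTCP parameter library, version 1.
#
# One record per published model/parameter combination.  Fields:
#   model    : LKB | RS
#   organ    : controlled organ label (see radcomp.dvh.ORGAN_LABELS)
#   endpoint : toxicity endpoint, verbatim text
#   source   : citation label of the parameterization
#   variant  : disambiguates multiple rows from the same source ("" if unique)
#   params   : n/D50/m for LKB, gamma/D50/s for RS (D50 in Gy)
#   note     : volume-convention or organ-handling remark ("" if none)
#   dose_engine_basis : dose algorithm class the parameters were fitted
#                       against, where stated (EPL or CS), else ""
schema_version: 1
parameter_sets:
  # ---- heart: 6 sets --------------------------------------------------
  - model: LKB
    organ: heart
    endpoint: pericarditis
    source: Emami/Burman
    variant: ""
    params: {n: 0.35, D50: 48.00, m: 0.10}
    note: whole heart
    dose_engine_basis: ""
  - model: LKB
    organ: heart
    endpoint: pericarditis
    source: Martel
    variant: ""
    params: {n: 0.636, D50: 50.60, m: 0.13}
    note: pericard (1cm thick shell)
    dose_engine_basis: ""
  - model: RS
    organ: heart
    endpoint: pericarditis
    source: Emami/Agren-Cronqvist
    variant: ""
    params: {gamma: 3.0, D50: 49.20, s: 0.2}
    note: whole heart
    dose_engine_basis: ""
  - model: RS
    organ: heart
    endpoint: excess cardiac mortality
    source: Gagliardi
    variant: ""
    params: {gamma: 1.28, D50: 52.40, s: 1.00}
    note: whole heart
    dose_engine_basis: ""
  - model: RS
    organ: heart
    endpoint: excess cardiac mortality
    source: Eriksson
    variant: a
    params: {gamma: 0.93, D50: 63.30, s: 1.00}
    note: whole heart
    dose_engine_basis: ""
  - model: RS
    organ: heart
    endpoint: excess cardiac mortality
    source: Eriksson
    variant: b
    params: {gamma: 0.96, D50: 70.30, s: 1.00}
    note: whole heart
    dose_engine_basis: ""
  # ---- lung: 8 sets ---------------------------------------------------
  - model: LKB
    organ: lung
    endpoint: pneumonitis
    source: Emami/Burman
    variant: ""
    params: {n: 0.87, D50: 24.50, m: 0.18}
    note: ""
    dose_engine_basis: ""
  - model: LKB
    organ: lung
    endpoint: pneumonitis
    source: Kwa
    variant: ""
    params: {n: 1.00, D50: 30.50, m: 0.30}
    note: ""
    dose_engine_basis: ""
  - model: LKB
    organ: lung
    endpoint: pneumonitis
    source: Seppenwoolde
    variant: ""
    params: {n: 0.99, D50: 30.80, m: 0.37}
    note: ""
    dose_engine_basis: ""
  - model: LKB
    organ: lung
    endpoint: pneumonitis
    source: De Jaeger
    variant: EPL
    params: {n: 1.00, D50: 34.10, m: 0.45}
    note: parameters derived from equivalent-pathlength dose calculations
    dose_engine_basis: EPL
  - model: LKB
    organ: lung
    endpoint: pneumonitis
    source: De Jaeger
    variant: CS
    params: {n: 1.00, D50: 29.20, m: 0.45}
    note: parameters derived from convolution-superposition dose calculations
    dose_engine_basis: CS
  - model: RS
    organ: lung
    endpoint: pneumonitis
    source: Emami/Agren-Cronqvist
    variant: ""
    params: {gamma: 2.10, D50: 24.50, s: 0.0061}
    note: ""
    dose_engine_basis: ""
  - model: RS
    organ: lung
    endpoint: pneumonitis
    source: Seppenwoolde
    variant: ""
    params: {gamma: 0.900, D50: 34.00, s: 0.060}
    note: ""
    dose_engine_basis: ""
  - model: RS
    organ: lung
    endpoint: pneumonitis
    source: Gagliardi
    variant: ""
    params: {gamma: 0.966, D50: 30.10, s: 0.012}
    note: lungs were considered as separate organs
    dose_engine_basis: ""
  # ---- parotid glands: 3 sets ----------------------------------------
  - model: LKB
    organ: parotid
    endpoint: total xerostomia
    source: Emami/Burman
    variant: ""
    params: {n: 0.70, D50: 46.00, m: 0.18}
    note: total xerostomia
    dose_engine_basis: ""
  - model: LKB
    organ: parotid
    endpoint: 25% xerostomia
    source: Eisbruch
    variant: ""
    params: {n: 1.00, D50: 28.40, m: 0.18}
    note: 25% xerostomia at 1 year
    dose_engine_basis: ""
  - model: LKB
    organ: parotid
    endpoint: 25% xerostomia
    source: Roesink
    variant: ""
    params: {n: 1.00, D50: 39.00, m: 0.45}
    note: 25% xerostomia at 1 year
    dose_engine_basis: ""
  # ---- rectum: 7 sets -------------------------------------------------
  - model: LKB
    organ: rectum
    endpoint: late rectal bleeding
    source: Rancati
    variant: a
    params: {n: 0.23, D50: 81.90, m: 0.19}
    note: solid rectum including filling
    dose_engine_basis: ""
  - model: LKB
    organ: rectum
    endpoint: late rectal bleeding
    source: Rancati
    variant: b
    params: {n: 0.06, D50: 78.60, m: 0.06}
    note: solid rectum including filling
    dose_engine_basis: ""
  - model: LKB
    organ: rectum
    endpoint: late rectal bleeding
    source: Tucker
    variant: ""
    params: {n: 0.08, D50: 78.00, m: 0.14}
    note: solid rectum including filling
    dose_engine_basis: ""
  - model: LKB
    organ: rectum
    endpoint: late rectal bleeding
    source: Peeters
    variant: ""
    params: {n: 0.13, D50: 80.70, m: 0.14}
    note: rectal wall
    dose_engine_basis: ""
  - model: LKB
    organ: rectum
    endpoint: late rectal bleeding
    source: Soehn
    variant: ""
    params: {n: 0.08, D50: 78.40, m: 0.11}
    note: rectal wall
    dose_engine_basis: ""
  - model: LKB
    organ: rectum
    endpoint: late rectal bleeding
    source: Rancati
    variant: c
    params: {n: 0.085, D50: 97.70, m: 0.27}
    note: solid rectum including filling
    dose_engine_basis: ""
  - model: RS
    organ: rectum
    endpoint: late rectal bleeding
    source: Rancati
    variant: ""
    params: {gamma: 1.69, D50: 83.10, s: 0.49}
    note: solid rectum including filling
    dose_engine_basis: ""
  # ---- femoral heads: 1 set -------------------------------------------
  - model: LKB
    organ: femoral_head
    endpoint: necrosis
    source: Emami/Burman
    variant: ""
    params: {n: 0.25, D50: 65.00, m: 0.12}
    note: ""
    dose_engine_basis: ""
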