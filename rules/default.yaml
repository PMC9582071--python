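# Default sequence-name standardization rules.
#
# Ordered list, first match wins; the terminal catch-all (empty `when`)
# guarantees every sequence gets a weighting token. Condition values:
# scalar = equality, list = any-of, mapping with ge/gt/le/lt = numeric range.
# Times in milliseconds, angles in degrees, b-values in s/mm^2.
#
# Diffusion is checked before inversion recovery before relaxation-based
# rules so DWI/FLAIR assignments stay unambiguous. TI windows are wide enough
# to cover both 1.5 T and 3 T conventions.
options:
  include_dimensionality: true
  include_contrast: true
rules:
  - name: diffusion
    when: {max_b_value: {gt: 50}}
    token: DWI
  - name: flair
    when: {inversion_recovery: true, ti_ms: {ge: 1800, le: 2800}}
    token: FLAIR
  - name: stir
    when: {inversion_recovery: true, ti_ms: {ge: 120, le: 300}}
    token: STIR
  - name: t1-spin-echo
    when: {technique: [SE, TSE], tr_ms: {lt: 800}, te_ms: {lt: 30}}
    token: T1
  - name: t2
    when: {tr_ms: {gt: 2000}, te_ms: {gt: 80}}
    token: T2
  - name: pd
    when: {tr_ms: {gt: 2000}, te_ms: {lt: 30}}
    token: PD
  - name: t1-gradient-echo
    when: {technique: [GRE, bSSFP], flip_deg: {gt: 50}, tr_ms: {lt: 800}}
    token: T1
  - name: catch-all
    when: {}
    token: OTHER
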