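# Revised 32-item HIV Stigma Scale: four subscales of unique items,
# 4-point Likert codes (1 completely disagree .. 4 completely agree).
# Items 8 and 21 are reverse scored.
subscales:
  personalized_stigma:
    - item18
    - item24
    - item26
    - item28
    - item29
    - item32
    - item33
    - item35
    - item36
    - item38
    - item39
  disclosure_concerns:
    - item01
    - item04
    - item06
    - item17
    - item21
    - item22
    - item25
    - item37
  public_attitudes:
    - item05
    - item09
    - item10
    - item14
    - item16
    - item20
  negative_self_image:
    - item02
    - item03
    - item07
    - item08
    - item12
    - item15
    - item23
reverse_items:
  - item08
  - item21
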