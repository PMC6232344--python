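# Declared ingredient manifest of the eight-ingredient Liangxue Tongyu
# prescription: code, species, and pharmacological role class.
ingredients:
  - code: PR
    species: Paeonia lactiflora Pall.
    role_class: heat-clearing
  - code: RO
    species: Rheum officinale Baill.
    role_class: blood-activating
  - code: RG
    species: Rehmannia glutinosa (Gaertn.) Li-bosch.
    role_class: blood-activating
  - code: PN
    species: Panax notoginseng (Burk.) F. H. Chen ex C. Chow.
    role_class: blood-activating
  - code: PS
    species: Paeonia suffruticosa Andr.
    role_class: heat-clearing
  - code: AT
    species: Acorus tatarinowii Schott.
    role_class: resuscitation
  - code: BB
    species: Bubalus bubalis Linnaeus.
    role_class: animal
  - code: PA
    species: Pheretima aspergillum (E. Perrier)
    role_class: animal
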