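# Organ -> time-activity-curve model assignment.
# Washout-only organs get a monoexponential; organs that accumulate free
# astatine by dehalogenation (rise then fall) get the biexponential.
monoexp:
  - blood
  - flat bone
  - flat_bone
  - femur
  - muscle
  - liver
  - kidneys
  - kidney
  - lungs
  - lung
  - spleen
  - brain
  - heart
biexp:
  - intestine
  - gut
  - skin
  - stomach
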