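# Bundled case definition: four rheumatoid-arthritis biologics vs the
# cardiac-failure preferred-term family.  The event list is an editable
# stand-in for a MedDRA PT set (MedDRA itself is licensed); substitute
# your own terms for other analyses.
drugs:
  abatacept: [abatacept, Orencia]
  adalimumab: [adalimumab, Humira, Amjevita, Cyltezo]
  tocilizumab: [tocilizumab, Actemra, RoActemra]
  etanercept: [etanercept, Enbrel, Erelzi]
event_terms:
  - heart failure
  - fail cardiac
  - insufficient cardiac
  - cardiac insufficiency
  - cardiac failure
  - weak heart
allowed_roles: [PS, SS]
indication_terms:
  - rheumatoid arthritis
match_mode: exact
event_match_mode: exact
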