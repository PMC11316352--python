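# Default functional marker panel: named gene groups used for the
# presence/absence matrices, pigmentation calls and ecotype contrasts.
nitrogen:
  - narB
  - nirA
  - nrtA
  - nrtB
  - nrtC
  - amt
  - urea_transport
sulfur:
  - cysH
  - sat
  - cysC
  - cysI
ROS:
  - katE
  - sod1
pigment:
  - cpeA
  - cpeB
motility_chemotaxis:
  - pilA
  - cheB
  - cheR
cold:
  - treS
  - otsA
  - otsB
humic:
  - mlhB
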