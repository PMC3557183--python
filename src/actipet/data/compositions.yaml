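# Raw elemental mass fractions (unit fractions of total tissue mass) for the
# bundled reference tissues.  Only the positron-emitter parents C, N, O are
# carried; hydrogen and trace elements are irrelevant to activation imaging
# and renormalizing over C+N+O (the "hydrogen-adjusted" convention) removes
# them anyway.  Renormalized, these reproduce the standard adjusted values:
# adipose 67.7% C / 0.8% N / 31.5% O, bladder contents 4% C / 1.7% N / 94% O.
adipose_adult2:
  C: 0.598
  N: 0.007
  O: 0.278
urinary_bladder_filled:
  C: 0.035
  N: 0.015
  O: 0.830
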