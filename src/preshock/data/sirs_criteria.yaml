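# Systemic Inflammatory Response Syndrome (SIRS) criteria, Sepsis-2 consensus.
# Each criterion contributes 1 to the SIRS count (0-4) when met on the
# current carried-forward value. Missing inputs do not count.
# version: 1
temperature:            # degrees C
  high: 38.0
  low: 36.0
heart_rate:             # beats/min
  high: 90.0
respiratory:            # either branch satisfies the criterion
  respiratory_rate_high: 20.0   # breaths/min
  paco2_low: 32.0               # mmHg
wbc:                    # x10^3 / uL
  high: 12.0
  low: 4.0
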