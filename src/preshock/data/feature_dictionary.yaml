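# Default feature dictionary: raw item codes -> canonical feature names with
# units and physiological plausibility bounds. Values outside [lower_bound,
# upper_bound] are rejected on load. This default uses canonical names as item
# codes; real deployments map site-specific item codes here instead.
# Bounds are deliberately permissive screens against artifactual entries, not
# reference ranges; they are editable configuration.
lactate:          {feature: lactate,          unit: mmol/L,     lower_bound: 0.0,  upper_bound: 30.0}
gcs:              {feature: gcs,              unit: points,     lower_bound: 3.0,  upper_bound: 15.0}
heart_rate:       {feature: heart_rate,       unit: bpm,        lower_bound: 10.0, upper_bound: 300.0}
map:              {feature: map,              unit: mmHg,       lower_bound: 10.0, upper_bound: 250.0}
pao2:             {feature: pao2,             unit: mmHg,       lower_bound: 10.0, upper_bound: 700.0}
fio2:             {feature: fio2,             unit: fraction,   lower_bound: 0.21, upper_bound: 1.0}
respiratory_rate: {feature: respiratory_rate, unit: breaths/min, lower_bound: 0.0, upper_bound: 80.0}
temperature:      {feature: temperature,      unit: degC,       lower_bound: 25.0, upper_bound: 45.0}
wbc:              {feature: wbc,              unit: 1e3/uL,     lower_bound: 0.0,  upper_bound: 200.0}
platelets:        {feature: platelets,        unit: 1e3/uL,     lower_bound: 0.0,  upper_bound: 2000.0}
bilirubin:        {feature: bilirubin,        unit: mg/dL,      lower_bound: 0.0,  upper_bound: 60.0}
creatinine:       {feature: creatinine,       unit: mg/dL,      lower_bound: 0.0,  upper_bound: 30.0}
bun:              {feature: bun,              unit: mg/dL,      lower_bound: 0.0,  upper_bound: 300.0}
paco2:            {feature: paco2,            unit: mmHg,       lower_bound: 5.0,  upper_bound: 150.0}
urine_output:     {feature: urine_output,     unit: mL,         lower_bound: 0.0,  upper_bound: 5000.0}
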