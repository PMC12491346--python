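# Single-strategy decision tree: [18F]FET PET performed after a routine MRI
# suspicious for tumor relapse, 22 pretreated pediatric CNS tumor lesions
# (one PET scan per lesion).
model: model2
label: "[18F]FET PET after suspicious routine MRI (22 lesions)"

nodes:
  N1: {value: 10/22, sd: 0.08, psa_mean: 0.46}   # P(rated relapse | PET)
  N2: {value: 9/10,  sd: 0.04, psa_mean: 0.90}   # P(confirmed relapse | rated relapse)
  N3: {value: 9/12,  sd: 0.04, psa_mean: 0.75}   # P(confirmed TRC | rated TRC)

dsa:
  N1: {delta: 0.15}
  N2: {delta: 0.075}
  N3: {delta: 0.075}

costs:
  cohort: {n_lesions: 22, n_scans: 22}
  modalities:
    pet:
      - {code: "1",      label: "Patient consultation",           amount_eur: "10.72"}
      - {code: "75",     label: "Report on diagnostic findings",  amount_eur: "17.43"}
      - {code: "253",    label: "Intravenous injection",          amount_eur: "9.38"}
      - {code: "5430",   label: "Scintigraphy of the brain",      amount_eur: "125.91"}
      - {code: "5489",   label: "PET with quantitative analysis", amount_eur: "786.89"}
      - {code: "tracer", label: "[18F]FET tracer production",     amount_eur: "616.00"}
  strategies:
    pet: {label: "[18F]FET PET", modalities: [pet]}

psa:
  cost_cv: 0.5
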