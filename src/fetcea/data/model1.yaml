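# Two-strategy decision tree: simultaneous [18F]FET PET + MRI vs MRI alone
# for identifying treatment-related changes in 83 pretreated pediatric CNS
# tumor lesions (92 PET+MRI scan pairs).
#
# Node values are the exact count ratios of the 83-lesion cohort; psa_mean
# carries the rounded percentage used by the Monte Carlo analysis.  One-way
# sensitivity intervals are value +/- delta (0.15 for SD-0.08 nodes, 0.075
# for SD-0.04 nodes, taken from adult-glioma cost-effectiveness studies).
model: model1
label: "[18F]FET PET + MRI vs MRI alone (83 pretreated lesions, 92 scans)"

nodes:
  N1: {value: 54/83, sd: 0.08, psa_mean: 0.65}   # P(rated relapse | PET+MRI)
  N2: {value: 68/83, sd: 0.08, psa_mean: 0.82}   # P(rated relapse | MRI alone)
  N3: {value: 54/54, sd: 0.04, psa_mean: 1.00}   # P(confirmed relapse | PET+MRI rated relapse)
  N4: {value: 21/29, sd: 0.04, psa_mean: 0.72}   # P(confirmed TRC | PET+MRI rated TRC)
  N5: {value: 57/68, sd: 0.04, psa_mean: 0.84}   # P(confirmed relapse | MRI rated relapse)
  N6: {value: 10/15, sd: 0.04, psa_mean: 0.67}   # P(confirmed TRC | MRI rated TRC)

dsa:
  N1: {delta: 0.15}
  N2: {delta: 0.15}
  N3: {delta: 0.075}   # upper endpoint exceeds 1: theoretical, flagged not clamped
  N4: {delta: 0.075}
  N5: {delta: 0.075}
  N6: {delta: 0.075}

costs:
  cohort: {n_lesions: 83, n_scans: 92}
  modalities:
    pet:
      - {code: "1",      label: "Patient consultation",                       amount_eur: "10.72"}
      - {code: "75",     label: "Report on diagnostic findings",              amount_eur: "17.43"}
      - {code: "253",    label: "Intravenous injection",                      amount_eur: "9.38"}
      - {code: "5430",   label: "Scintigraphy of the brain",                  amount_eur: "125.91"}
      - {code: "5489",   label: "PET with quantitative analysis",             amount_eur: "786.89"}
      - {code: "tracer", label: "[18F]FET tracer production",                 amount_eur: "616.00"}
    mri:
      - {code: "1",      label: "Patient consultation",                       amount_eur: "10.72"}
      - {code: "5",      label: "Physical examination",                       amount_eur: "10.72"}
      - {code: "75",     label: "Report on diagnostic findings",              amount_eur: "17.43"}
      - {code: "346",    label: "High-pressure intravenous injection",        amount_eur: "40.23"}
      - {code: "3051",   label: "Surcharge for perfusion imaging",            amount_eur: "75.19"}
      - {code: "5700",   label: "MRI with 3D and ADC reconstruction",         amount_eur: "641.16"}
      - {code: "5731",   label: "Additional MRI series with 3D and ADC rec.", amount_eur: "145.72"}
      - {code: "5733",   label: "Surcharge for computer analysis",            amount_eur: "46.63"}
  strategies:
    combined:  {label: "[18F]FET PET + MRI", modalities: [pet, mri]}
    reference: {label: "MRI alone",          modalities: [mri]}

psa:
  cost_cv: 0.5
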