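# Base-case parameterisation: Dutch ER-positive/HER2-negative stage II/III
# breast cancer, MRI response-guided vs conventional neoadjuvant
# chemotherapy.  Probabilities carry beta pseudo-counts (alpha/beta), costs
# carry gamma mean/se (2013 Euros); `mean` is the deterministic base-case
# value used by the cohort model.

monitoring:
  true_favourable:   {mean: 0.53, se: 0.04}
  true_unfavourable: {mean: 0.24, se: 0.05}
  false_favourable:  {mean: 0.17, se: 0.07}
  false_unfavourable: {mean: 0.07, se: 0.09}

toxicity:
  probabilities:
    vomiting:
      ac3: {mean: 0.05, alpha: 5, beta: 98}
      dc3: {mean: 0.24, alpha: 24, beta: 77}
    hfs:
      dc3: {mean: 0.22, alpha: 23, beta: 80}
    neutropenia:
      ac3: {mean: 0.85, alpha: 86, beta: 15}
      dc3: {mean: 0.72, alpha: 74, beta: 29}
    desquamation:
      dc3: {mean: 0.05, alpha: 5, beta: 98}
    chf:
      ac3: {mean: 0.002, alpha: 1, beta: 359}
      ac6: {mean: 0.017, ess: 360}   # 1.7% per text; beta matched at n=360
    aml_mds:
      ac3: {mean: 0.003, alpha: 12, beta: 4471}
      ac6: {mean: 0.005, alpha: 12, beta: 2372}
  utilities:
    vomiting:     {mean: 0.52, alpha: 17, beta: 16}
    neutropenia:  {mean: 0.53, alpha: 557, beta: 488}
    hfs:          {mean: 0.50, alpha: 12, beta: 12}
    desquamation: {mean: 0.59, alpha: 1041, beta: 721}
    chf:          {mean: 0.55, family: beta}        # average grade III/IV
    aml_mds:      {mean: 0.26, alpha: 500, beta: 1423}
  costs:
    vomiting:     {mean: 92, se: 23, family: gamma}
    neutropenia:  {mean: 14397, se: 425, family: gamma}
    chf:          {mean: 18225, se: 4556, family: gamma}
    aml_mds:      {mean: 112946, se: 28236, family: gamma}
    hfs:          {mean: 0, family: fixed}          # exempt of costs
    desquamation: {mean: 0, family: fixed}          # exempt of costs

transitions:
  relapse_false:                      # falsely classified RG subgroups
    - {mean: 0.14, alpha: 4,  beta: 24}
    - {mean: 0.29, alpha: 8,  beta: 20}
    - {mean: 0.47, alpha: 13, beta: 15}
    - {mean: 0.44, alpha: 12, beta: 16}
    - {mean: 0.40, alpha: 11, beta: 17}
  relapse_conventional: [0.03, 0.06, 0.08, 0.05, 0.04]
  bc_death_false:                     # by years since relapse
    - 0.0
    - {mean: 0.04, alpha: 5,  beta: 109}
    - {mean: 0.12, alpha: 14, beta: 100}
    - {mean: 0.06, alpha: 7,  beta: 107}
    - {mean: 0.19, alpha: 22, beta: 92}
  bc_death_conventional: [0.0, 0.06, 0.19, 0.09, 0.28]
  hr_rfs:  {mean: 0.50, se: 0.20}     # truncated normal on (0, inf)
  hr_bcss: {mean: 0.64, se: 0.13}     # normal

utilities:
  chemotherapy: {mean: 0.62, alpha: 94, beta: 58}
  dfs:          {mean: 0.80, alpha: 196, beta: 49}
  relapse:      {mean: 0.73, family: beta}          # avg loco-regional/metastatic
  anxiety:      {mean: 0.68, alpha: 40, beta: 19}
  aml_mds:      {mean: 0.26, alpha: 500, beta: 1423}

costs:
  regimen_6xac:           # total 9279
    doxorubicin:      {mean: 1306, se: 326}
    cyclophosphamide: {mean: 239, se: 60}
    pegfilgrastim:    {mean: 5096, se: 1274}
    pharmacy:         {mean: 267, se: 67}
    day_care:         {mean: 1718, se: 430}
    oncologist:       {mean: 653, se: 163}
  regimen_acdc:           # total 9975 (printed 9974; component rounding)
    doxorubicin:      {mean: 653, se: 163}
    cyclophosphamide: {mean: 120, se: 30}
    pegfilgrastim:    {mean: 2548, se: 637}
    docetaxel:        {mean: 3195, se: 799}
    capecitabine:     {mean: 821, se: 205}
    pharmacy:         {mean: 267, se: 67}
    day_care:         {mean: 1718, se: 430}
    oncologist:       {mean: 653, se: 163}
  monitoring:             # total 215 per scan
    hospital: {mean: 163, se: 41}
    fees:     {mean: 52, se: 13}
  confirm_incidental: {mean: 149, se: 37}
  dfs_annual:             # total 2872 per year disease free
    in_out_patient: {mean: 2793, se: 563}
    drugs:          {mean: 79, se: 20}
  relapse_local:          # total 14833; relapse episode = avg(local,distant) = 16125
    in_out_patient: {mean: 12497, se: 1692}
    drugs:          {mean: 2336, se: 584}
  relapse_distant:        # total 17417
    in_out_patient: {mean: 11645, se: 1346}
    drugs:          {mean: 5772, se: 1443}
  bc_death: {mean: 8296, se: 2074}

screening:
  renal:              {alpha: 0.45, beta: 5.54}     # mean 0.0751
  gadolinium_allergy: {mean: 0.0003, alpha: 0.08, beta: 29}
  ferrous_parts:      {alpha: 0.26, beta: 4.21}     # mean 0.0582 (not 0.58)
  claustrophobia:     {alpha: 0.02, beta: 0.94}     # mean 0.0208
  nsf:                {mean: 0.0003, family: fixed}
  incidental:         {alpha: 270, beta: 1265}      # mean 270/1535 = 0.1759
  malignant_incidental: {alpha: 55, beta: 215}      # 55 of 270 -> mean 0.2037
  ats:                {mean: 0.26, family: fixed}
  exclusion_components: [renal, ferrous_parts, claustrophobia]

uptake_current: 0.042
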