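# Differentiated thyroid cancer (DTC) recurrence cohort schema, version 1.
# 16 categorical clinical features plus the binary recurrence label.
# Level lists are ordered; one-hot column order follows this file exactly.
version: 1
target:
  name: Recurred
  levels: ["No", "Yes"]          # "Yes" = recurrence = positive class
features:
  Age group: ["<40", "40-60", ">60"]
  Gender: [F, M]
  Smoking: ["No", "Yes"]
  Hx Smoking: ["No", "Yes"]
  Hx Radiotherapy: ["No", "Yes"]
  Thyroid Function:
    - Euthyroid
    - Clinical Hyperthyroidism
    - Clinical Hypothyroidism
    - Subclinical Hyperthyroidism
    - Subclinical Hypothyroidism
  Physical Examination:
    - Normal
    - Single nodular goiter-left
    - Single nodular goiter-right
    - Multinodular goiter
    - Diffuse goiter
  Adenopathy: ["No", Right, Left, Bilateral, Posterior, Extensive]
  Pathology:
    - Papillary Carcinoma
    - Micro Papillary Carcinoma
    - Follicular Carcinoma
    - Hurthle Cell Carcinoma
  Focality: [Uni-Focal, Multi-Focal]
  Risk: [Low, Intermediate, High]
  T: [T1a, T1b, T2, T3a, T3b, T4]
  N: [N0, N1]
  M: [M0, M1]
  Stage: [I, II, III, IVA, IVB]
  Response: [Excellent, Indeterminate, Incomplete]
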