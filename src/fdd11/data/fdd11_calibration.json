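{
  "schema_version": 1,
  "instrument": "FDD11",
  "provenance": "Published FDD11 calibration: item thresholds and standard errors from the final pooled Model Disability Survey Partial Credit Model fit (11 countries, 2014-2019); 0-100 scale anchors from the published sum-score conversion table; disability-level cut-offs = mean-SD, mean, mean+SD of the transformed score in the pooled sample.",
  "items": [
    {
      "id": "Q01",
      "label": "difficulty seeing",
      "max_category": 3,
      "thresholds": [-0.4, -0.04, 0.2],
      "threshold_ses": [0.01, 0.02, 0.02],
      "location": -0.08,
      "recode": [0, 1, 2, 3, 3]
    },
    {
      "id": "Q02",
      "label": "difficulty hearing",
      "max_category": 2,
      "thresholds": [0.66, 1.74],
      "threshold_ses": [0.01, 0.03],
      "location": 1.2,
      "recode": [0, 1, 1, 2, 2]
    },
    {
      "id": "Q03",
      "label": "difficulty walking or climbing steps",
      "max_category": 3,
      "thresholds": [-0.11, 0.18, 0.45],
      "threshold_ses": [0.01, 0.02, 0.03],
      "location": 0.17,
      "recode": [0, 1, 2, 3, 3]
    },
    {
      "id": "Q04",
      "label": "difficulty remembering or concentrating",
      "max_category": 3,
      "thresholds": [-0.57, 0.7, 1.01],
      "threshold_ses": [0.01, 0.02, 0.03],
      "location": 0.38,
      "recode": [0, 1, 2, 3, 3]
    },
    {
      "id": "Q05",
      "label": "difficulty with self-care",
      "max_category": 2,
      "thresholds": [0.83, 1.69],
      "threshold_ses": [0.01, 0.03],
      "location": 1.26,
      "recode": [0, 1, 1, 2, 2]
    },
    {
      "id": "Q06",
      "label": "difficulty sleeping",
      "max_category": 2,
      "thresholds": [-0.44, 0.79],
      "threshold_ses": [0.01, 0.02],
      "location": 0.18,
      "recode": [0, 1, 1, 2, 2]
    },
    {
      "id": "Q07",
      "label": "difficulty with household tasks",
      "max_category": 2,
      "thresholds": [-0.26, 0.87],
      "threshold_ses": [0.01, 0.02],
      "location": 0.31,
      "recode": [0, 1, 1, 2, 2]
    },
    {
      "id": "Q08",
      "label": "difficulty joining community activities",
      "max_category": 2,
      "thresholds": [-0.41, 0.71],
      "threshold_ses": [0.01, 0.02],
      "location": 0.15,
      "recode": [0, 1, 1, 2, 2]
    },
    {
      "id": "Q09",
      "label": "sad/depressed + worried/anxious (emotion testlet)",
      "max_category": 4,
      "thresholds": [-1.45, -0.04, 1.04, 1.19],
      "threshold_ses": [0.01, 0.01, 0.02, 0.04],
      "location": 0.18,
      "recode": [0, 1, 1, 2, 2, 3, 3, 4, 4]
    },
    {
      "id": "Q10",
      "label": "difficulty getting along with close people",
      "max_category": 3,
      "thresholds": [0.38, 0.43, 0.69],
      "threshold_ses": [0.01, 0.02, 0.03],
      "location": 0.5,
      "recode": [0, 1, 2, 3, 3]
    },
    {
      "id": "Q11",
      "label": "bodily aches or pains",
      "max_category": 4,
      "thresholds": [-1.48, -0.67, 0.33, 0.58],
      "threshold_ses": [0.01, 0.01, 0.02, 0.03],
      "location": -0.31,
      "recode": [0, 1, 2, 3, 4]
    }
  ],
  "anchors": {"theta_min": -3.71, "theta_max": 4.18},
  "cutoffs": {"c1": 4.3, "c2": 22.6, "c3": 40.8},
  "levels": ["No", "Mild", "Moderate", "Severe"]
}
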