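{
  "_comment": "Index cases carrying the planted panel variants. Family structures are synthetic reconstructions consistent with each patient's published eligibility flags (expected_criteria); per-relative detail is not public.",
  "patients": [
    {
      "patient_id": "HPC177",
      "age_at_dx": 62,
      "relatives": [
        {"degree": "first", "cancer_type": "prostate", "age_at_dx": 58},
        {"degree": "first", "cancer_type": "prostate", "age_at_dx": 59},
        {"degree": "first", "cancer_type": "prostate", "age_at_dx": 63},
        {"degree": "first", "cancer_type": "prostate", "age_at_dx": 66},
        {"degree": "first", "cancer_type": "prostate", "age_at_dx": 68}
      ],
      "second_primaries": [],
      "expected_criteria": ["A1", "A2"]
    },
    {
      "patient_id": "HPC395",
      "age_at_dx": 63,
      "relatives": [
        {"degree": "first", "cancer_type": "breast", "age_at_dx": 52},
        {"degree": "second", "cancer_type": "breast", "age_at_dx": 38},
        {"degree": "second", "cancer_type": "breast", "age_at_dx": 44}
      ],
      "second_primaries": [],
      "expected_criteria": ["B3"]
    },
    {
      "patient_id": "HPC447",
      "age_at_dx": 59,
      "relatives": [
        {"degree": "first", "cancer_type": "bilateral breast", "age_at_dx": 62},
        {"degree": "second", "cancer_type": "abdominal", "age_at_dx": 42},
        {"degree": "second", "cancer_type": "lung", "age_at_dx": 70},
        {"degree": "second", "cancer_type": "gastric", "age_at_dx": 75},
        {"degree": "second", "cancer_type": "leukemia", "age_at_dx": 65}
      ],
      "second_primaries": [],
      "expected_criteria": ["B3"]
    },
    {
      "patient_id": "HPC150",
      "age_at_dx": 64,
      "relatives": [
        {"degree": "first", "cancer_type": "prostate", "age_at_dx": 60},
        {"degree": "first", "cancer_type": "prostate", "age_at_dx": 67}
      ],
      "second_primaries": [],
      "expected_criteria": ["A2"]
    },
    {
      "patient_id": "HPC186",
      "age_at_dx": 50,
      "relatives": [
        {"degree": "first", "cancer_type": "lymphoma", "age_at_dx": 54},
        {"degree": "first", "cancer_type": "sarcoma", "age_at_dx": 53},
        {"degree": "first", "cancer_type": "gynecological", "age_at_dx": 56}
      ],
      "second_primaries": ["bladder"],
      "ihc_results": {"MSH6": true},
      "expected_criteria": ["B1", "B2"]
    },
    {
      "patient_id": "HPC421",
      "age_at_dx": 64,
      "relatives": [
        {"degree": "first", "cancer_type": "lung", "age_at_dx": 76}
      ],
      "second_primaries": ["urothelial"],
      "expected_criteria": ["B2"]
    },
    {
      "patient_id": "HPC455",
      "age_at_dx": 54,
      "relatives": [
        {"degree": "second", "cancer_type": "lung", "age_at_dx": 72}
      ],
      "second_primaries": ["multiple myeloma"],
      "expected_criteria": ["B2"]
    },
    {
      "patient_id": "HPC238",
      "age_at_dx": 58,
      "relatives": [
        {"degree": "first", "cancer_type": "prostate", "age_at_dx": 60},
        {"degree": "first", "cancer_type": "prostate", "age_at_dx": 57},
        {"degree": "first", "cancer_type": "prostate", "age_at_dx": 64}
      ],
      "second_primaries": [],
      "expected_criteria": ["A1", "A2", "A3"]
    },
    {
      "patient_id": "HPC167",
      "age_at_dx": 65,
      "relatives": [
        {"degree": "first", "cancer_type": "lung", "age_at_dx": 66}
      ],
      "second_primaries": ["kidney"],
      "expected_criteria": ["B2"]
    },
    {
      "patient_id": "HPC400",
      "age_at_dx": 52,
      "relatives": [
        {"degree": "first", "cancer_type": "lung", "age_at_dx": 55},
        {"degree": "second", "cancer_type": "ovarian", "age_at_dx": 54},
        {"degree": "second", "cancer_type": "pancreatic", "age_at_dx": 58}
      ],
      "second_primaries": [],
      "expected_criteria": ["B1"]
    },
    {
      "patient_id": "HPC20",
      "age_at_dx": 53,
      "relatives": [
        {"degree": "first", "cancer_type": "lymphoma", "age_at_dx": 52},
        {"degree": "first", "cancer_type": "uterine", "age_at_dx": 55},
        {"degree": "second", "cancer_type": "liver", "age_at_dx": 60}
      ],
      "second_primaries": [],
      "expected_criteria": ["B1"]
    },
    {
      "patient_id": "HPC3",
      "age_at_dx": 59,
      "relatives": [
        {"degree": "second", "cancer_type": "prostate", "age_at_dx": 63},
        {"degree": "second", "cancer_type": "prostate", "age_at_dx": 68}
      ],
      "second_primaries": [],
      "expected_criteria": ["A3"]
    },
    {
      "patient_id": "HPC332",
      "age_at_dx": 54,
      "relatives": [
        {"degree": "first", "cancer_type": "prostate", "age_at_dx": 61},
        {"degree": "second", "cancer_type": "prostate", "age_at_dx": 58},
        {"degree": "first", "cancer_type": "pancreatic", "age_at_dx": 53}
      ],
      "second_primaries": [],
      "ihc_results": {"MSH6": true},
      "expected_criteria": ["A3", "B1"]
    },
    {
      "patient_id": "HPC118",
      "age_at_dx": 63,
      "relatives": [
        {"degree": "first", "cancer_type": "prostate", "age_at_dx": 59},
        {"degree": "first", "cancer_type": "prostate", "age_at_dx": 65}
      ],
      "second_primaries": [],
      "expected_criteria": ["A2"]
    },
    {
      "patient_id": "HPC188",
      "age_at_dx": 64,
      "relatives": [
        {"degree": "first", "cancer_type": "prostate", "age_at_dx": 54},
        {"degree": "first", "cancer_type": "prostate", "age_at_dx": 62},
        {"degree": "first", "cancer_type": "prostate", "age_at_dx": 65}
      ],
      "second_primaries": [],
      "expected_criteria": ["A1", "A2"]
    },
    {
      "patient_id": "HPC289",
      "age_at_dx": 49,
      "relatives": [
        {"degree": "first", "cancer_type": "breast", "age_at_dx": 42},
        {"degree": "first", "cancer_type": "breast", "age_at_dx": 47},
        {"degree": "second", "cancer_type": "colon", "age_at_dx": 50}
      ],
      "second_primaries": [],
      "expected_criteria": ["B1", "B3"]
    },
    {
      "patient_id": "HPC89",
      "age_at_dx": 55,
      "relatives": [
        {"degree": "first", "cancer_type": "lung", "age_at_dx": 68}
      ],
      "second_primaries": ["melanoma"],
      "expected_criteria": ["B2"]
    },
    {
      "patient_id": "HPC371",
      "age_at_dx": 62,
      "relatives": [
        {"degree": "first", "cancer_type": "colon", "age_at_dx": 48},
        {"degree": "first", "cancer_type": "gastric", "age_at_dx": 58}
      ],
      "second_primaries": [],
      "ihc_results": {"MSH2": true},
      "expected_criteria": ["B3"]
    },
    {
      "patient_id": "HPC394",
      "age_at_dx": 62,
      "relatives": [
        {"degree": "first", "cancer_type": "prostate", "age_at_dx": 58},
        {"degree": "first", "cancer_type": "prostate", "age_at_dx": 63},
        {"degree": "first", "cancer_type": "prostate", "age_at_dx": 66}
      ],
      "second_primaries": ["sarcoma"],
      "expected_criteria": ["A1", "A2", "B2"]
    }
  ]
}
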