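{
  "_comment": "Carrier counts of the planted variants in the two control panels, keyed by chrom:pos:ref:alt. Variants absent from a map have zero observed carriers. Counts for variants whose control screen results are public only at the panel level are set to zero.",
  "panels": [
    {
      "label": "healthy_controls",
      "n_individuals": 710,
      "carriers": {
        "11:108121787:G:A": 2,
        "11:108178699:G:A": 2
      }
    },
    {
      "label": "non_prostate_cancer_cases",
      "n_individuals": 504,
      "carriers": {
        "11:108114835:C:T": 1,
        "22:29115474:G:T": 1,
        "17:56798156:ACTGACTGACT:A": 2,
        "3:10109003:T:C": 1,
        "17:59885899:T:C": 1,
        "22:29107994:G:T": 1,
        "11:108121787:G:A": 6,
        "11:108178699:G:A": 3
      }
    }
  ]
}
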