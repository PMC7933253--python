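{
 "mode": "synthetic",
 "seed": 17,
 "alpha": 0.05,
 "divisions": ["SCP"],
 "cohort": {
  "n_subjects": 6,
  "duration_s": 10.0,
  "conditions": ["Rest", "StoryM", "Motort", "Wrkmem"]
 }
}
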