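# radiopharmaceutical: MDP-99mTc
# columns: mGy/MBq per anchor age (mSv/MBq for the effective row)
organ,age_1,age_5,age_10,age_15,age_adult,source
bone_surfaces,0.3465,0.189,0.1197,0.0819,0.063,adult anchor: compiled ICRP-series value; pediatric anchors: age-scaled estimates (verify against the primary publication before clinical use)
red_marrow,0.0506,0.0276,0.01748,0.01196,0.0092,adult anchor: compiled ICRP-series value; pediatric anchors: age-scaled estimates (verify against the primary publication before clinical use)
urinary_bladder,0.192,0.1152,0.0816,0.0624,0.048,adult anchor: compiled ICRP-series value; pediatric anchors: age-scaled estimates (verify against the primary publication before clinical use)
kidneys,0.04015,0.0219,0.01387,0.00949,0.0073,adult anchor: compiled ICRP-series value; pediatric anchors: age-scaled estimates (verify against the primary publication before clinical use)
effective,0.0285,0.01596,0.01083,0.00741,0.0057,adult anchor: compiled ICRP-series value; pediatric anchors: age-scaled estimates (verify against the primary publication before clinical use)
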