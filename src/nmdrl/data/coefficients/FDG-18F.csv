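# radiopharmaceutical: FDG-18F
# columns: mGy/MBq per anchor age (mSv/MBq for the effective row)
organ,age_1,age_5,age_10,age_15,age_adult,source
urinary_bladder,0.52,0.312,0.221,0.169,0.13,adult anchor: compiled ICRP-series value; pediatric anchors: age-scaled estimates (verify against the primary publication before clinical use)
heart_wall,0.3685,0.201,0.1273,0.0871,0.067,adult anchor: compiled ICRP-series value; pediatric anchors: age-scaled estimates (verify against the primary publication before clinical use)
brain,0.154,0.084,0.0532,0.0364,0.028,adult anchor: compiled ICRP-series value; pediatric anchors: age-scaled estimates (verify against the primary publication before clinical use)
liver,0.1155,0.063,0.0399,0.0273,0.021,adult anchor: compiled ICRP-series value; pediatric anchors: age-scaled estimates (verify against the primary publication before clinical use)
kidneys,0.0935,0.051,0.0323,0.0221,0.017,adult anchor: compiled ICRP-series value; pediatric anchors: age-scaled estimates (verify against the primary publication before clinical use)
uterus,0.099,0.054,0.0342,0.0234,0.018,adult anchor: compiled ICRP-series value; pediatric anchors: age-scaled estimates (verify against the primary publication before clinical use)
effective,0.095,0.0532,0.0361,0.0247,0.019,adult anchor: compiled ICRP-series value; pediatric anchors: age-scaled estimates (verify against the primary publication before clinical use)
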