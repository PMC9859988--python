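# radiopharmaceutical: DMSA-99mTc
# columns: mGy/MBq per anchor age (mSv/MBq for the effective row)
organ,age_1,age_5,age_10,age_15,age_adult,source
kidneys,0.99,0.54,0.342,0.234,0.18,adult anchor: compiled ICRP-series value; pediatric anchors: age-scaled estimates (verify against the primary publication before clinical use)
urinary_bladder,0.072,0.0432,0.0306,0.0234,0.018,adult anchor: compiled ICRP-series value; pediatric anchors: age-scaled estimates (verify against the primary publication before clinical use)
liver,0.04675,0.0255,0.01615,0.01105,0.0085,adult anchor: compiled ICRP-series value; pediatric anchors: age-scaled estimates (verify against the primary publication before clinical use)
spleen,0.0715,0.039,0.0247,0.0169,0.013,adult anchor: compiled ICRP-series value; pediatric anchors: age-scaled estimates (verify against the primary publication before clinical use)
red_marrow,0.02145,0.0117,0.00741,0.00507,0.0039,adult anchor: compiled ICRP-series value; pediatric anchors: age-scaled estimates (verify against the primary publication before clinical use)
effective,0.044,0.02464,0.01672,0.01144,0.0088,adult anchor: compiled ICRP-series value; pediatric anchors: age-scaled estimates (verify against the primary publication before clinical use)
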