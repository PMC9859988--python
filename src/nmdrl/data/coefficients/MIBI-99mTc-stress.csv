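# radiopharmaceutical: MIBI-99mTc-stress
# columns: mGy/MBq per anchor age (mSv/MBq for the effective row)
organ,age_1,age_5,age_10,age_15,age_adult,source
liver,0.0506,0.0276,0.01748,0.01196,0.0092,adult anchor: compiled ICRP-series value; pediatric anchors: age-scaled estimates (verify against the primary publication before clinical use)
kidneys,0.1815,0.099,0.0627,0.0429,0.033,adult anchor: compiled ICRP-series value; pediatric anchors: age-scaled estimates (verify against the primary publication before clinical use)
urinary_bladder,0.0392,0.02352,0.01666,0.01274,0.0098,adult anchor: compiled ICRP-series value; pediatric anchors: age-scaled estimates (verify against the primary publication before clinical use)
thyroid,0.0308,0.01584,0.00968,0.00616,0.0044,adult anchor: compiled ICRP-series value; pediatric anchors: age-scaled estimates (verify against the primary publication before clinical use)
gallbladder_wall,0.1815,0.099,0.0627,0.0429,0.033,adult anchor: compiled ICRP-series value; pediatric anchors: age-scaled estimates (verify against the primary publication before clinical use)
heart_wall,0.0396,0.0216,0.01368,0.00936,0.0072,adult anchor: compiled ICRP-series value; pediatric anchors: age-scaled estimates (verify against the primary publication before clinical use)
pancreas,0.03795,0.0207,0.01311,0.00897,0.0069,adult anchor: compiled ICRP-series value; pediatric anchors: age-scaled estimates (verify against the primary publication before clinical use)
spleen,0.0319,0.0174,0.01102,0.00754,0.0058,adult anchor: compiled ICRP-series value; pediatric anchors: age-scaled estimates (verify against the primary publication before clinical use)
effective,0.0395,0.02212,0.01501,0.01027,0.0079,adult anchor: compiled ICRP-series value; pediatric anchors: age-scaled estimates (verify against the primary publication before clinical use)
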