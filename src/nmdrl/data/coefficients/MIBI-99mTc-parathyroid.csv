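# radiopharmaceutical: MIBI-99mTc-parathyroid
# columns: mGy/MBq per anchor age (mSv/MBq for the effective row)
organ,age_1,age_5,age_10,age_15,age_adult,source
liver,0.0605,0.033,0.0209,0.0143,0.011,adult anchor: compiled ICRP-series value; pediatric anchors: age-scaled estimates (verify against the primary publication before clinical use)
kidneys,0.198,0.108,0.0684,0.0468,0.036,adult anchor: compiled ICRP-series value; pediatric anchors: age-scaled estimates (verify against the primary publication before clinical use)
urinary_bladder,0.044,0.0264,0.0187,0.0143,0.011,adult anchor: compiled ICRP-series value; pediatric anchors: age-scaled estimates (verify against the primary publication before clinical use)
thyroid,0.0371,0.01908,0.01166,0.00742,0.0053,adult anchor: compiled ICRP-series value; pediatric anchors: age-scaled estimates (verify against the primary publication before clinical use)
gallbladder_wall,0.2145,0.117,0.0741,0.0507,0.039,adult anchor: compiled ICRP-series value; pediatric anchors: age-scaled estimates (verify against the primary publication before clinical use)
heart_wall,0.03465,0.0189,0.01197,0.00819,0.0063,adult anchor: compiled ICRP-series value; pediatric anchors: age-scaled estimates (verify against the primary publication before clinical use)
pancreas,0.04235,0.0231,0.01463,0.01001,0.0077,adult anchor: compiled ICRP-series value; pediatric anchors: age-scaled estimates (verify against the primary publication before clinical use)
spleen,0.03575,0.0195,0.01235,0.00845,0.0065,adult anchor: compiled ICRP-series value; pediatric anchors: age-scaled estimates (verify against the primary publication before clinical use)
effective,0.045,0.0252,0.0171,0.0117,0.009,adult anchor: compiled ICRP-series value; pediatric anchors: age-scaled estimates (verify against the primary publication before clinical use)
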