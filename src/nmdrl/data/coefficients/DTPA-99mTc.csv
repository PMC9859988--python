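# radiopharmaceutical: DTPA-99mTc
# columns: mGy/MBq per anchor age (mSv/MBq for the effective row)
organ,age_1,age_5,age_10,age_15,age_adult,source
urinary_bladder,0.248,0.1488,0.1054,0.0806,0.062,adult anchor: compiled ICRP-series value; pediatric anchors: age-scaled estimates (verify against the primary publication before clinical use)
kidneys,0.0242,0.0132,0.00836,0.00572,0.0044,adult anchor: compiled ICRP-series value; pediatric anchors: age-scaled estimates (verify against the primary publication before clinical use)
uterus,0.04345,0.0237,0.01501,0.01027,0.0079,adult anchor: compiled ICRP-series value; pediatric anchors: age-scaled estimates (verify against the primary publication before clinical use)
red_marrow,0.01595,0.0087,0.00551,0.00377,0.0029,adult anchor: compiled ICRP-series value; pediatric anchors: age-scaled estimates (verify against the primary publication before clinical use)
effective,0.0245,0.01372,0.00931,0.00637,0.0049,adult anchor: compiled ICRP-series value; pediatric anchors: age-scaled estimates (verify against the primary publication before clinical use)
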