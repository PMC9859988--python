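# Risk-model parameters: excess relative risk (ERR, beta per Sv) and excess
# absolute risk (EAR, beta per 10^4 person-years per Sv) for the solid-tumor
# preferred model beta*D*exp(gamma*e_star)*(a/60)^eta.
# kidney and salivary_gland use the residual "other solid cancer" grouping.
# thyroid and leukemia rows are simplified to the same functional form (the
# committee's special breast/thyroid and linear-quadratic leukemia models are
# out of scope here); their source strings say so.
site,sex,model,beta,gamma,eta,units,source
stomach,male,ERR,0.21,-0.30,-1.4,per Sv,BEIR VII Table 12-2 (incidence)
stomach,female,ERR,0.48,-0.30,-1.4,per Sv,BEIR VII Table 12-2 (incidence)
colon,male,ERR,0.63,-0.30,-1.4,per Sv,BEIR VII Table 12-2 (incidence)
colon,female,ERR,0.43,-0.30,-1.4,per Sv,BEIR VII Table 12-2 (incidence)
liver,male,ERR,0.32,-0.30,-1.4,per Sv,BEIR VII Table 12-2 (incidence)
liver,female,ERR,0.32,-0.30,-1.4,per Sv,BEIR VII Table 12-2 (incidence)
lung,male,ERR,0.32,-0.30,-1.4,per Sv,BEIR VII Table 12-2 (incidence)
lung,female,ERR,1.40,-0.30,-1.4,per Sv,BEIR VII Table 12-2 (incidence)
bladder,male,ERR,0.50,-0.30,-1.4,per Sv,BEIR VII Table 12-2 (incidence)
bladder,female,ERR,1.65,-0.30,-1.4,per Sv,BEIR VII Table 12-2 (incidence)
prostate,male,ERR,0.12,-0.30,-1.4,per Sv,BEIR VII Table 12-2 (incidence)
uterus,female,ERR,0.055,-0.30,-1.4,per Sv,BEIR VII Table 12-2 (incidence)
ovary,female,ERR,0.38,-0.30,-1.4,per Sv,BEIR VII Table 12-2 (incidence)
kidney,male,ERR,0.27,-0.30,-1.4,per Sv,BEIR VII "other solid" grouping (incidence)
kidney,female,ERR,0.45,-0.30,-1.4,per Sv,BEIR VII "other solid" grouping (incidence)
salivary_gland,male,ERR,0.27,-0.30,-1.4,per Sv,BEIR VII "other solid" grouping (incidence)
salivary_gland,female,ERR,0.45,-0.30,-1.4,per Sv,BEIR VII "other solid" grouping (incidence)
thyroid,male,ERR,0.53,-0.30,-1.4,per Sv,simplified: linear coefficient per BEIR VII pooled thyroid analysis cast into the solid-tumor form
thyroid,female,ERR,1.05,-0.30,-1.4,per Sv,simplified: linear coefficient per BEIR VII pooled thyroid analysis cast into the solid-tumor form
leukemia,male,ERR,1.1,-0.30,-1.4,per Sv,simplified: linear term of the BEIR VII leukemia model cast into the solid-tumor form
leukemia,female,ERR,1.2,-0.30,-1.4,per Sv,simplified: linear term of the BEIR VII leukemia model cast into the solid-tumor form
stomach,male,EAR,4.9,-0.41,2.8,per 1e4 PY per Sv,BEIR VII Table 12-2 (incidence)
stomach,female,EAR,4.9,-0.41,2.8,per 1e4 PY per Sv,BEIR VII Table 12-2 (incidence)
colon,male,EAR,3.2,-0.41,2.8,per 1e4 PY per Sv,BEIR VII Table 12-2 (incidence)
colon,female,EAR,1.6,-0.41,2.8,per 1e4 PY per Sv,BEIR VII Table 12-2 (incidence)
liver,male,EAR,2.2,-0.41,2.8,per 1e4 PY per Sv,BEIR VII Table 12-2 (incidence)
liver,female,EAR,1.0,-0.41,2.8,per 1e4 PY per Sv,BEIR VII Table 12-2 (incidence)
lung,male,EAR,2.3,-0.41,5.2,per 1e4 PY per Sv,BEIR VII Table 12-2 (incidence)
lung,female,EAR,3.4,-0.41,5.2,per 1e4 PY per Sv,BEIR VII Table 12-2 (incidence)
bladder,male,EAR,1.2,-0.41,2.8,per 1e4 PY per Sv,BEIR VII Table 12-2 (incidence)
bladder,female,EAR,0.75,-0.41,2.8,per 1e4 PY per Sv,BEIR VII Table 12-2 (incidence)
prostate,male,EAR,0.11,-0.41,2.8,per 1e4 PY per Sv,BEIR VII Table 12-2 (incidence)
uterus,female,EAR,1.2,-0.41,2.8,per 1e4 PY per Sv,BEIR VII Table 12-2 (incidence)
ovary,female,EAR,0.70,-0.41,2.8,per 1e4 PY per Sv,BEIR VII Table 12-2 (incidence)
kidney,male,EAR,6.2,-0.41,2.8,per 1e4 PY per Sv,BEIR VII "other solid" grouping (incidence)
kidney,female,EAR,4.8,-0.41,2.8,per 1e4 PY per Sv,BEIR VII "other solid" grouping (incidence)
salivary_gland,male,EAR,6.2,-0.41,2.8,per 1e4 PY per Sv,BEIR VII "other solid" grouping (incidence)
salivary_gland,female,EAR,4.8,-0.41,2.8,per 1e4 PY per Sv,BEIR VII "other solid" grouping (incidence)
leukemia,male,EAR,1.62,-0.41,2.8,per 1e4 PY per Sv,simplified: linear term of the BEIR VII leukemia model cast into the solid-tumor form
leukemia,female,EAR,0.93,-0.41,2.8,per 1e4 PY per Sv,simplified: linear term of the BEIR VII leukemia model cast into the solid-tumor form
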