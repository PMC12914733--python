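key,value,ci_lo,ci_hi,units,description
newborn_total_cd4_blood,2215.23,2023.43,2407.03,cells/uL,meta-analytic newborn (0-0.25 y) total CD4 blood concentration
newborn_memory_cd4_blood,393.33,316.85,469.82,cells/uL,meta-analytic newborn (0-0.25 y) total memory (CD45RO+) CD4 blood concentration
total_t_count_blood,8.0e9,,,cells,literature estimate of total T cells in blood
total_t_count_lymphoid,3.6e11,,,cells,literature estimate of total T cells in lymphoid organs
total_t_count_git,1.7e10,,,cells,literature estimate of total T cells in the gastro-intestinal tract
total_t_count_lung,1.3e10,,,cells,literature estimate of total T cells in lungs
cd4_cd8_ratio_blood,2.0,,,-,CD4:CD8 ratio in blood
cd4_cd8_ratio_lymphoid,2.0,,,-,CD4:CD8 ratio in lymphoid tissue
cd4_cd8_ratio_git,1.0,,,-,CD4:CD8 ratio in the gastro-intestinal tract
cd4_cd8_ratio_lung,1.0,,,-,CD4:CD8 ratio in lungs
predicted_max_cd4_blood,5.09e9,4.85e9,5.33e9,cells,reference-analysis predicted maximum CD4 count in blood
predicted_max_cd4_lymphoid,2.02e11,1.91e11,2.12e11,cells,reference-analysis predicted maximum CD4 count in lymphoid organs
predicted_max_cd4_git,8.25e9,7.84e9,8.65e9,cells,reference-analysis predicted maximum CD4 count in the gastro-intestinal tract
predicted_max_cd4_lung,4.14e9,3.78e9,4.58e9,cells,reference-analysis predicted maximum CD4 count in lungs
lamN4_age70,0.0012,,,1/d,calibrated naive CD4 proliferation rate at 70 years
lamN4_age23,0.0007,,,1/d,calibrated naive CD4 proliferation rate at 23 years
aic_feedback_model,4753.23,,,-,reference-analysis AIC of the cell-count-feedback model
aic_age_model,4862.35,,,-,reference-analysis AIC of the age-function model
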