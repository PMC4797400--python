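# Published organ absorbed-dose coefficients (Gy/MBq) for the Lu-177-labeled
# anti-hK2 antibody in LNCaP-xenografted mice, derived from two biokinetic
# datasets (an In-111-labeled surrogate study, and the Lu-177 study itself).
# Used as reference inputs for dose-table and therapy-planning calculations.
region,self_gy_per_mbq_in111,total_gy_per_mbq_in111,self_gy_per_mbq_lu177,total_gy_per_mbq_lu177
tumor,2.2,2.3,4.8,4.9
submandibular,1.9,2.0,5.6,5.6
blood,1.3,1.3,1.2,1.3
marrow,0.40,0.47,0.38,0.45
liver,0.63,0.66,1.56,1.59
heart,0.47,0.66,0.56,0.74
lung,0.41,0.54,0.59,0.71
spleen,0.67,0.71,1.9,1.9
kidney,0.50,0.53,0.50,0.54
gi_tract,0.30,0.35,0.35,0.44
bone,0.13,0.27,0.18,0.30
brain,0.017,0.040,0.019,0.041
testes,0.24,0.28,0.31,0.35
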