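case_id,true_diagnosis,diffuse_astrocytoma,anaplastic_astrocytoma,gbm_tumor_cell_area,gbm_necrosis_area,gbm_microvascular_proliferation_area
case_13,diffuse_astrocytoma,5025,3,0,9,0
case_14,diffuse_astrocytoma,216,0,22,60,1
case_15,anaplastic_astrocytoma,0,0,146,0,0
case_17,diffuse_astrocytoma,5280,0,0,9,0
case_22,diffuse_astrocytoma,530,0,0,1,2
case_25,diffuse_astrocytoma,1,449,16,8,2
case_27,anaplastic_astrocytoma,0,28,220,0,0
case_29,anaplastic_astrocytoma,0,296,323,0,1
case_38,diffuse_astrocytoma,6,0,0,367,0
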