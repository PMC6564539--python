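roi	lobe
lh_G_and_S_frontomargin	frontal
lh_G_and_S_occipital_inf	occipital
lh_G_and_S_paracentral	frontal
lh_G_and_S_subcentral	frontal
lh_G_and_S_transv_frontopol	frontal
lh_G_and_S_cingul-Ant	limbic
lh_G_and_S_cingul-Mid-Ant	limbic
lh_G_and_S_cingul-Mid-Post	limbic
lh_G_cingul-Post-dorsal	limbic
lh_G_cingul-Post-ventral	limbic
lh_G_cuneus	occipital
lh_G_front_inf-Opercular	frontal
lh_G_front_inf-Orbital	frontal
lh_G_front_inf-Triangul	frontal
lh_G_front_middle	frontal
lh_G_front_sup	frontal
lh_G_Ins_lg_and_S_cent_ins	insula
lh_G_insular_short	insula
lh_G_occipital_middle	occipital
lh_G_occipital_sup	occipital
lh_G_oc-temp_lat-fusifor	temporal
lh_G_oc-temp_med-Lingual	occipital
lh_G_oc-temp_med-Parahip	limbic
lh_G_orbital	frontal
lh_G_pariet_inf-Angular	parietal
lh_G_pariet_inf-Supramar	parietal
lh_G_parietal_sup	parietal
lh_G_postcentral	parietal
lh_G_precentral	frontal
lh_G_precuneus	parietal
lh_G_rectus	frontal
lh_G_subcallosal	limbic
lh_G_temp_sup-G_T_transv	temporal
lh_G_temp_sup-Lateral	temporal
lh_G_temp_sup-Plan_polar	temporal
lh_G_temp_sup-Plan_tempo	temporal
lh_G_temporal_inf	temporal
lh_G_temporal_middle	temporal
lh_Lat_Fis-ant-Horizont	frontal
lh_Lat_Fis-ant-Vertical	frontal
lh_Lat_Fis-post	temporal
lh_Pole_occipital	occipital
lh_Pole_temporal	temporal
lh_S_calcarine	occipital
lh_S_central	frontal
lh_S_cingul-Marginalis	limbic
lh_S_circular_insula_ant	insula
lh_S_circular_insula_inf	insula
lh_S_circular_insula_sup	insula
lh_S_collat_transv_ant	temporal
lh_S_collat_transv_post	occipital
lh_S_front_inf	frontal
lh_S_front_middle	frontal
lh_S_front_sup	frontal
lh_S_interm_prim-Jensen	parietal
lh_S_intrapariet_and_P_trans	parietal
lh_S_oc_middle_and_Lunatus	occipital
lh_S_oc_sup_and_transversal	occipital
lh_S_occipital_ant	occipital
lh_S_oc-temp_lat	temporal
lh_S_oc-temp_med_and_Lingual	temporal
lh_S_orbital_lateral	frontal
lh_S_orbital_med-olfact	frontal
lh_S_orbital-H_Shaped	frontal
lh_S_parieto_occipital	occipital
lh_S_pericallosal	limbic
lh_S_postcentral	parietal
lh_S_precentral-inf-part	frontal
lh_S_precentral-sup-part	frontal
lh_S_suborbital	frontal
lh_S_subparietal	parietal
lh_S_temporal_inf	temporal
lh_S_temporal_sup	temporal
lh_S_temporal_transverse	temporal
rh_G_and_S_frontomargin	frontal
rh_G_and_S_occipital_inf	occipital
rh_G_and_S_paracentral	frontal
rh_G_and_S_subcentral	frontal
rh_G_and_S_transv_frontopol	frontal
rh_G_and_S_cingul-Ant	limbic
rh_G_and_S_cingul-Mid-Ant	limbic
rh_G_and_S_cingul-Mid-Post	limbic
rh_G_cingul-Post-dorsal	limbic
rh_G_cingul-Post-ventral	limbic
rh_G_cuneus	occipital
rh_G_front_inf-Opercular	frontal
rh_G_front_inf-Orbital	frontal
rh_G_front_inf-Triangul	frontal
rh_G_front_middle	frontal
rh_G_front_sup	frontal
rh_G_Ins_lg_and_S_cent_ins	insula
rh_G_insular_short	insula
rh_G_occipital_middle	occipital
rh_G_occipital_sup	occipital
rh_G_oc-temp_lat-fusifor	temporal
rh_G_oc-temp_med-Lingual	occipital
rh_G_oc-temp_med-Parahip	limbic
rh_G_orbital	frontal
rh_G_pariet_inf-Angular	parietal
rh_G_pariet_inf-Supramar	parietal
rh_G_parietal_sup	parietal
rh_G_postcentral	parietal
rh_G_precentral	frontal
rh_G_precuneus	parietal
rh_G_rectus	frontal
rh_G_subcallosal	limbic
rh_G_temp_sup-G_T_transv	temporal
rh_G_temp_sup-Lateral	temporal
rh_G_temp_sup-Plan_polar	temporal
rh_G_temp_sup-Plan_tempo	temporal
rh_G_temporal_inf	temporal
rh_G_temporal_middle	temporal
rh_Lat_Fis-ant-Horizont	frontal
rh_Lat_Fis-ant-Vertical	frontal
rh_Lat_Fis-post	temporal
rh_Pole_occipital	occipital
rh_Pole_temporal	temporal
rh_S_calcarine	occipital
rh_S_central	frontal
rh_S_cingul-Marginalis	limbic
rh_S_circular_insula_ant	insula
rh_S_circular_insula_inf	insula
rh_S_circular_insula_sup	insula
rh_S_collat_transv_ant	temporal
rh_S_collat_transv_post	occipital
rh_S_front_inf	frontal
rh_S_front_middle	frontal
rh_S_front_sup	frontal
rh_S_interm_prim-Jensen	parietal
rh_S_intrapariet_and_P_trans	parietal
rh_S_oc_middle_and_Lunatus	occipital
rh_S_oc_sup_and_transversal	occipital
rh_S_occipital_ant	occipital
rh_S_oc-temp_lat	temporal
rh_S_oc-temp_med_and_Lingual	temporal
rh_S_orbital_lateral	frontal
rh_S_orbital_med-olfact	frontal
rh_S_orbital-H_Shaped	frontal
rh_S_parieto_occipital	occipital
rh_S_pericallosal	limbic
rh_S_postcentral	parietal
rh_S_precentral-inf-part	frontal
rh_S_precentral-sup-part	frontal
rh_S_suborbital	frontal
rh_S_subparietal	parietal
rh_S_temporal_inf	temporal
rh_S_temporal_sup	temporal
rh_S_temporal_transverse	temporal
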