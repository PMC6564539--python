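lh_G_and_S_frontomargin
lh_G_and_S_occipital_inf
lh_G_and_S_paracentral
lh_G_and_S_subcentral
lh_G_and_S_transv_frontopol
lh_G_and_S_cingul-Ant
lh_G_and_S_cingul-Mid-Ant
lh_G_and_S_cingul-Mid-Post
lh_G_cingul-Post-dorsal
lh_G_cingul-Post-ventral
lh_G_cuneus
lh_G_front_inf-Opercular
lh_G_front_inf-Orbital
lh_G_front_inf-Triangul
lh_G_front_middle
lh_G_front_sup
lh_G_Ins_lg_and_S_cent_ins
lh_G_insular_short
lh_G_occipital_middle
lh_G_occipital_sup
lh_G_oc-temp_lat-fusifor
lh_G_oc-temp_med-Lingual
lh_G_oc-temp_med-Parahip
lh_G_orbital
lh_G_pariet_inf-Angular
lh_G_pariet_inf-Supramar
lh_G_parietal_sup
lh_G_postcentral
lh_G_precentral
lh_G_precuneus
lh_G_rectus
lh_G_subcallosal
lh_G_temp_sup-G_T_transv
lh_G_temp_sup-Lateral
lh_G_temp_sup-Plan_polar
lh_G_temp_sup-Plan_tempo
lh_G_temporal_inf
lh_G_temporal_middle
lh_Lat_Fis-ant-Horizont
lh_Lat_Fis-ant-Vertical
lh_Lat_Fis-post
lh_Pole_occipital
lh_Pole_temporal
lh_S_calcarine
lh_S_central
lh_S_cingul-Marginalis
lh_S_circular_insula_ant
lh_S_circular_insula_inf
lh_S_circular_insula_sup
lh_S_collat_transv_ant
lh_S_collat_transv_post
lh_S_front_inf
lh_S_front_middle
lh_S_front_sup
lh_S_interm_prim-Jensen
lh_S_intrapariet_and_P_trans
lh_S_oc_middle_and_Lunatus
lh_S_oc_sup_and_transversal
lh_S_occipital_ant
lh_S_oc-temp_lat
lh_S_oc-temp_med_and_Lingual
lh_S_orbital_lateral
lh_S_orbital_med-olfact
lh_S_orbital-H_Shaped
lh_S_parieto_occipital
lh_S_pericallosal
lh_S_postcentral
lh_S_precentral-inf-part
lh_S_precentral-sup-part
lh_S_suborbital
lh_S_subparietal
lh_S_temporal_inf
lh_S_temporal_sup
lh_S_temporal_transverse
rh_G_and_S_frontomargin
rh_G_and_S_occipital_inf
rh_G_and_S_paracentral
rh_G_and_S_subcentral
rh_G_and_S_transv_frontopol
rh_G_and_S_cingul-Ant
rh_G_and_S_cingul-Mid-Ant
rh_G_and_S_cingul-Mid-Post
rh_G_cingul-Post-dorsal
rh_G_cingul-Post-ventral
rh_G_cuneus
rh_G_front_inf-Opercular
rh_G_front_inf-Orbital
rh_G_front_inf-Triangul
rh_G_front_middle
rh_G_front_sup
rh_G_Ins_lg_and_S_cent_ins
rh_G_insular_short
rh_G_occipital_middle
rh_G_occipital_sup
rh_G_oc-temp_lat-fusifor
rh_G_oc-temp_med-Lingual
rh_G_oc-temp_med-Parahip
rh_G_orbital
rh_G_pariet_inf-Angular
rh_G_pariet_inf-Supramar
rh_G_parietal_sup
rh_G_postcentral
rh_G_precentral
rh_G_precuneus
rh_G_rectus
rh_G_subcallosal
rh_G_temp_sup-G_T_transv
rh_G_temp_sup-Lateral
rh_G_temp_sup-Plan_polar
rh_G_temp_sup-Plan_tempo
rh_G_temporal_inf
rh_G_temporal_middle
rh_Lat_Fis-ant-Horizont
rh_Lat_Fis-ant-Vertical
rh_Lat_Fis-post
rh_Pole_occipital
rh_Pole_temporal
rh_S_calcarine
rh_S_central
rh_S_cingul-Marginalis
rh_S_circular_insula_ant
rh_S_circular_insula_inf
rh_S_circular_insula_sup
rh_S_collat_transv_ant
rh_S_collat_transv_post
rh_S_front_inf
rh_S_front_middle
rh_S_front_sup
rh_S_interm_prim-Jensen
rh_S_intrapariet_and_P_trans
rh_S_oc_middle_and_Lunatus
rh_S_oc_sup_and_transversal
rh_S_occipital_ant
rh_S_oc-temp_lat
rh_S_oc-temp_med_and_Lingual
rh_S_orbital_lateral
rh_S_orbital_med-olfact
rh_S_orbital-H_Shaped
rh_S_parieto_occipital
rh_S_pericallosal
rh_S_postcentral
rh_S_precentral-inf-part
rh_S_precentral-sup-part
rh_S_suborbital
rh_S_subparietal
rh_S_temporal_inf
rh_S_temporal_sup
rh_S_temporal_transverse
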