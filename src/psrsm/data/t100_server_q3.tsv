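id	length	psrsm_q3	deepcnf_q3
5K4W_A	321	96.88	85.67
5Y5Z_A	578	82.70	80.45
5MOI_A	223	80.27	68.61
6B2N_A	263	71.10	87.07
5MOJ_A	223	89.24	78.30
6BT3_C	220	85.00	73.64
5MOK_	223	89.24	77.58
6F0E_A	312	86.86	80.45
5NA1_A	408	76.47	79.66
6F1T_G	376	82.45	80.85
5O7K_A	96	80.21	86.46
6F40_A	1460	75.75	74.79
5QAN_A	243	91.77	78.60
5GZJ_A	359	85.24	88.30
5UB4_A	280	83.93	84.29
5BK1_H	236	93.22	80.93
5VSA_A	314	86.62	83.44
5GZI_B	359	84.68	87.74
6AOK_A	217	85.71	75.12
5K4Y_A	320	97.19	86.56
6FEL_A	236	94.07	89.83
5LCP_B	20	95.00	NA
6F2L_A	304	70.07	85.53
5LH4_A	223	99.55	87.44
6F0Z_A	317	80.13	87.70
5MB5_A	330	88.18	81.82
6EM0_	581	78.83	85.20
5MR9_A	102	81.37	71.57
6EHH_A	176	94.89	85.80
5NXG_A	257	98.05	83.27
5QAE_A	243	92.18	79.84
5O5I_A	92	72.83	90.22
5QAK_A	243	92.18	79.84
5V6F_A	138	76.81	76.81
6AX2_A	46	73.91	82.61
5WHI_A	161	93.79	90.06
6AZ2_A	229	91.70	81.22
5WXE_A	28	60.71	60.71
6B5G_A	493	94.32	89.86
6F1D_A	117	94.87	88.03
6B7Z_A	966	86.54	85.09
5KDB_A	393	96.18	86.01
6BB5_A	139	94.96	84.89
5KDY_A	393	95.42	86.26
6BBQ_A	520	76.73	89.62
5N2O_A	70	88.57	92.86
6FD3_A	300	80.67	85.33
5NEC_A	741	84.48	86.64
6B3G_A	99	87.88	87.88
5O3U_A	724	91.99	83.70
5XXR_A	132	87.12	88.64
5O6V_A	496	70.36	74.19
5WVM_	509	84.68	80.16
5OQZ_A	18	77.78	NA
5WCT_A	187	63.64	73.80
5OYD_A	396	89.39	85.10
5W30_A	180	79.44	79.44
5UG6_A	149	91.28	87.25
5MZV_B	198	80.81	80.81
5UOE_A	990	94.24	86.77
6F73_B	574	62.02	78.22
5UOZ_A	21	71.43	NA
6BVC_A	177	83.62	81.92
5V23_A	98	78.57	86.73
5M3U_	416	91.35	83.17
5VDF_A	73	94.52	87.67
5BJZ_B	398	97.24	85.18
5W92_A	197	71.07	78.68
5LUH_A	270	90.74	79.26
5WAT_A	315	82.22	86.36
5MOP_	223	90.13	83.41
5WOT_A	198	93.43	80.30
5MR5_A	102	80.39	72.55
5WOZ_A	138	89.86	92.03
5NXP_A	258	98.45	83.33
5WPX_A	89	79.78	78.65
5XEE_A	98	76.53	77.55
5XBK_A	416	80.77	81.01
5YPK_A	242	91.32	83.88
5M88_A	136	89.71	92.65
5YQW_A	532	87.41	79.89
5MNV_A	407	89.19	87.71
5YWZ_A	242	73.55	80.17
5MOS_A	223	99.55	87.44
5Z0T_A	637	94.03	80.38
5MVO_A	291	70.45	75.95
6AX6_A	235	79.15	81.28
5N1D_A	353	90.37	84.99
6BGN_A	60	98.33	83.33
5N1N_A	353	88.95	88.67
6C2I_A	411	74.21	79.08
5O5C_A	519	82.08	84.39
6C8S_A	379	88.13	78.63
5OQ1_A	137	85.40	81.02
5WDD_A	168	93.45	91.07
5ORK_B	352	78.41	85.51
6AVD_A	40	70.00	80.00
5OTY_A	342	73.39	77.49
6FO0_N	480	88.75	87.28
5URT_A	21	71.43	NA
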