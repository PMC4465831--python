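threshold	dG_pou_s_apo	err_pou_s_apo	dG_pou_hd_apo	err_pou_hd_apo	dG_pou_s_sox2	err_pou_s_sox2	dG_pou_hd_sox2	err_pou_hd_sox2	printed_cooperativity	printed_cooperativity_err
3.1	-14.05	0.05	-12.94	0.12	-13.40	0.10	-12.63	0.11	0.96	0.20
3.3	-14.34	0.05	-16.14	0.08	-16.72	0.07	-15.76	0.09	-2.00	0.15
3.5	-14.51	0.05	-16.74	0.07	-17.25	0.07	-16.59	0.11	-2.59	0.16
3.7	-14.69	0.05	-17.13	0.05	-17.71	0.06	-17.60	0.13	-3.49	0.16
3.9	-14.87	0.05	-17.32	0.05	-18.01	0.06	-18.69	0.07	-4.51	0.12
4.1	-14.06	0.05	-17.47	0.05	-18.21	0.06	-19.05	0.07	-4.73	0.12
4.3	-14.29	0.05	-17.59	0.05	-18.38	0.06	-19.29	0.07	-4.79	0.12
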