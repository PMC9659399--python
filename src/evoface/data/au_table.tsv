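core_index	facs_name	au_number
0	inner_brow_raiser	1
1	outer_brow_raiser	2
2	brow_lowerer	4
3	upper_lid_raiser	5
4	cheek_raiser	6
5	lid_tightener	7
6	nose_wrinkler	9
7	upper_lip_raiser	10
8	nasolabial_deepener	11
9	lip_corner_puller	12
10	sharp_lip_puller	13
11	dimpler	14
12	lip_corner_depressor	15
13	lower_lip_depressor	16
14	chin_raiser	17
15	lip_pucker	18
16	lip_stretcher	20
17	lip_funneler	22
18	lip_tightener	23
19	lip_pressor	24
20	lips_part	25
21	jaw_drop	26
22	mouth_stretch	27
23	lip_suck	28
24	nostril_dilator	38
25	nostril_compressor	39
26	lid_droop	41
27	eyes_closed	43
28	outer_brow_raiser_left	2
29	outer_brow_raiser_right	2
30	brow_lowerer_left	4
31	brow_lowerer_right	4
32	upper_lid_raiser_left	5
33	upper_lid_raiser_right	5
34	cheek_raiser_left	6
35	cheek_raiser_right	6
36	lid_tightener_left	7
37	lid_tightener_right	7
38	lip_corner_puller_left	12
39	lip_corner_puller_right	12
40	lip_corner_depressor_left	15
41	lip_corner_depressor_right	15
42	lip_stretcher_left	20
43	lip_stretcher_right	20
44	jaw_thrust	29
45	jaw_clencher	31
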