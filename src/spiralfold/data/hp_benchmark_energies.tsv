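instance	size	lbfe	pss_best	pss_avg	ss_best	ss_avg	ri_ss_printed	ga_best	ga_avg	ri_ga_printed
F90_1	90	-168	-168	-166	-168	-167	0	-168	-166	0
F90_2	90	-168	-168	-166	-167	-164	50	-168	-165	33
F90_3	90	-167	-167	-165	-167	-165	0	-167	-164	33
F90_4	90	-168	-168	-166	-168	-165	33	-168	-165	33
F90_5	90	-167	-167	-165	-167	-165	0	-167	-166	0
S1	135	-357	-355	-350	-355	-347	30	-355	-348	22
S2	151	-360	-356	-351	-354	-347	31	-356	-349	18
S3	162	-367	-360	-354	-359	-350	26	-361	-349	28
S4	164	-370	-364	-358	-358	-350	40	-364	-352	33
F180_1	180	-378	-359	-344	-357	-340	11	-351	-341	8
F180_2	180	-381	-364	-352	-359	-345	19	-362	-346	17
F180_3	180	-378	-368	-356	-362	-353	12	-361	-350	21
R1	200	-384	-366	-353	-359	-345	21	-355	-346	18
R2	200	-383	-368	-355	-358	-346	24	-360	-346	24
R3	200	-385	-369	-353	-365	-345	20	-363	-344	22
3mse	179	-323	-296	-285	-289	-280	12	-290	-279	14
3mr7	189	-355	-332	-319	-328	-313	14	-328	-316	8
3mqz	215	-474	-430	-414	-420	-402	17	-427	-410	6
3no6	229	-455	-429	-407	-411	-391	25	-420	-400	13
3no3	258	-494	-422	-404	-412	-393	11	-421	-402	2
3on7	279	NA	-516	-500	-512	-485	NA	-515	-485	NA
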