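sample_id	strain	serial	gender	tissue	replicate	total_reads	mapped_reads	chrm_reads	usable_reads	pct_usable	tss_enrichment	reproducible_peaks
ATAC-1	C57BL/6J	1	Female	Adrenal gland	1	98,303,382	96,954,685	23,288,521	16,098,792	16.38	17.21	23,296
ATAC-2	C57BL/6J	1	Female	Adrenal gland	2	148,416,230	146,416,001	25,259,955	24,542,678	16.54	17.83	23,296
ATAC-3	C57BL/6J	1	Female	Cerebrum	1	150,254,776	148,205,698	1,773,531	116,676,430	77.65	18.35	93,546
ATAC-4	C57BL/6J	1	Female	Cerebrum	2	132,170,414	130,467,930	1,749,710	108,546,212	82.13	19.17	93,546
ATAC-5	C57BL/6J	1	Female	Cerebellum	1	44,251,998	43,732,156	254,745	35,315,756	79.81	13.90	32,337
ATAC-6	C57BL/6J	1	Female	Cerebellum	2	180,555,698	178,313,881	2,085,323	136,439,604	75.57	14.51	32,337
ATAC-7	C57BL/6J	1	Female	Abdominal fat	1	170,643,536	166,598,249	1,204,915	61,090,112	35.80	13.03	28,827
ATAC-8	C57BL/6J	1	Female	Abdominal fat	2	165,896,236	135,431,464	1,175,420	61,493,964	37.07	12.63	28,827
ATAC-9	C57BL/6J	1	Female	Brown fat	1	134,023,704	129,656,384	14,098,291	49,198,612	36.71	16.75	66,620
ATAC-10	C57BL/6J	1	Female	Brown fat	2	160,942,400	156,016,214	13,541,729	59,910,266	37.22	16.71	66,620
ATAC-11	C57BL/6J	1	Female	Mesenteric fat	1	157,502,400	154,297,472	1,228,888	93,224,318	59.19	8.10	34,851
ATAC-12	C57BL/6J	1	Female	Mesenteric fat	2	162,615,494	159,625,229	1,252,759	103,453,218	63.62	7.44	34,851
ATAC-13	C57BL/6J	1	Female	Heart	1	238,728,090	229,371,653	14,280,715	116,609,704	48.85	7.82	38,875
ATAC-14	C57BL/6J	1	Female	Heart	2	268,182,264	259,270,286	18,497,755	132,829,548	49.53	7.11	38,875
ATAC-15	C57BL/6J	1	Female	Kidney	1	90,269,090	88,799,485	1,190,916	67,126,022	74.36	13.93	57,348
ATAC-16	C57BL/6J	1	Female	Kidney	2	108,421,198	106,752,478	1,697,128	77,533,954	71.51	13.54	57,348
ATAC-17	C57BL/6J	1	Female	Liver	1	137,779,770	135,420,287	647,765	103,420,718	75.06	7.56	49,444
ATAC-18	C57BL/6J	1	Female	Liver	2	138,236,344	135,957,141	603,586	103,420,718	74.81	7.24	49,444
ATAC-19	C57BL/6J	1	Female	Lung	1	181,243,756	178,738,131	1,480,812	135,096,206	74.54	12.98	74,408
ATAC-20	C57BL/6J	1	Female	Lung	2	123,570,800	121,933,521	1,153,158	96,071,108	77.75	13.55	74,408
ATAC-21	C57BL/6J	1	Female	Ovary	1	110,371,234	109,170,446	3,960,686	63,119,950	57.19	13.61	22,300
ATAC-22	C57BL/6J	1	Female	Ovary	2	39,326,846	38,875,707	1,497,720	24,585,734	62.52	17.13	22,300
ATAC-23	C57BL/6J	1	Female	Pancreas	1	35,838,048	34,832,716	153,844	25,314,950	70.64	12.88	37,012
ATAC-24	C57BL/6J	1	Female	Pancreas	2	107,196,410	104,421,905	523,370	76,018,760	70.92	12.55	37,012
ATAC-25	C57BL/6J	1	Female	Skeletal muscle	1	133,254,164	131,716,403	2,973,082	63,522,884	47.67	6.39	16,386
ATAC-26	C57BL/6J	1	Female	Skeletal muscle	2	166,638,990	164,664,788	3,405,553	75,588,356	45.36	6.04	16,386
ATAC-27	C57BL/6J	1	Female	Spleen	1	94,226,804	93,372,274	697,988	58,659,642	62.25	7.55	18,659
ATAC-28	C57BL/6J	1	Female	Spleen	2	106,958,878	106,110,973	727,572	74,085,722	69.27	7.75	18,659
ATAC-29	C57BL/6J	1	Female	Thymus	1	70,619,572	69,042,929	629,068	49,965,476	70.75	11.87	35,092
ATAC-30	C57BL/6J	1	Female	Thymus	2	89,598,654	87,444,974	844,626	62,271,590	69.50	11.50	35,092
ATAC-31	C57BL/6J	1	Female	Uterus	1	66,931,470	66,424,809	200,619	50,479,508	75.42	5.71	12,249
ATAC-32	C57BL/6J	1	Female	Uterus	2	90,829,474	74,837,342	286,587	68,853,698	75.81	6.24	12,249
ATAC-33	C57BL/6J	2	Male	Adrenal gland	1	98,233,400	94,112,150	4,507,302	23,763,636	24.19	15.52	24,953
ATAC-34	C57BL/6J	2	Male	Adrenal gland	2	214,082,112	198,861,218	14,028,173	40,427,112	18.88	21.83	24,953
ATAC-35	C57BL/6J	2	Male	Bladder	1	84,715,186	83,692,447	5,340,505	39,154,858	46.22	9.15	21,940
ATAC-36	C57BL/6J	2	Male	Bladder	2	212,395,310	209,869,802	16,551,961	79,600,948	37.48	9.98	21,940
ATAC-37	C57BL/6J	2	Male	Cerebrum	1	235,561,686	191,218,996	4,553,350	155,453,764	65.99	25.43	117,909
ATAC-38	C57BL/6J	2	Male	Cerebrum	2	191,218,996	188,304,479	3,834,757	130,871,008	68.44	25.58	117,909
ATAC-39	C57BL/6J	2	Male	Cerebellum	1	53,952,860	53,152,913	981,941	41,135,886	76.24	15.42	41,280
ATAC-40	C57BL/6J	2	Male	Cerebellum	2	158,893,266	156,816,876	2,293,222	107,582,560	67.71	19.42	41,280
ATAC-41	C57BL/6J	2	Male	Brown fat	1	173,258,824	166,021,269	19,132,852	24,004,880	13.85	17.70	43,306
ATAC-42	C57BL/6J	2	Male	Brown fat	2	136,328,522	132,274,503	11,522,990	45,461,724	33.35	17.81	43,306
ATAC-43	C57BL/6J	2	Male	Mesenteric fat	1	155,269,780	151,746,361	1,090,769	100,616,020	64.80	8.65	41,494
ATAC-44	C57BL/6J	2	Male	Mesenteric fat	2	202,037,768	198,044,341	1,146,229	136,190,834	67.41	9.22	41,494
ATAC-45	C57BL/6J	2	Male	Heart	1	157,868,844	154,946,940	21,384,649	61,621,604	39.03	8.34	31,248
ATAC-46	C57BL/6J	2	Male	Heart	2	136,265,518	133,201,038	13,707,672	55,085,754	40.43	8.77	31,248
ATAC-47	C57BL/6J	2	Male	Large intestine	1	125,102,346	123,612,014	6,647,001	78,928,576	63.09	9.93	54,282
ATAC-48	C57BL/6J	2	Male	Large intestine	2	59,245,938	58,534,297	3,079,504	39,391,956	66.49	9.89	54,282
ATAC-49	C57BL/6J	2	Male	Small intestine	1	119,605,280	118,172,060	549,819	83,043,494	69.43	12.31	30,671
ATAC-50	C57BL/6J	2	Male	Small intestine	2	126,897,090	125,503,611	556,836	90,393,490	71.23	11.70	30,671
ATAC-51	C57BL/6J	2	Male	Kidney	1	75,598,616	74,377,104	2,570,404	54,471,070	72.05	19.32	74,760
ATAC-52	C57BL/6J	2	Male	Kidney	2	128,285,640	126,411,530	4,825,675	87,433,334	68.16	17.13	74,760
ATAC-53	C57BL/6J	2	Male	Liver	1	206,730,874	202,279,412	2,800,887	146,461,186	70.85	13.31	78,775
ATAC-54	C57BL/6J	2	Male	Liver	2	194,636,430	190,999,768	3,353,166	140,032,146	71.95	13.07	78,775
ATAC-55	C57BL/6J	2	Male	Lung	1	108,547,670	107,297,270	1,127,842	78,808,372	72.60	13.78	64,002
ATAC-56	C57BL/6J	2	Male	Lung	2	156,741,782	155,063,216	1,616,305	113,767,728	72.58	13.15	64,002
ATAC-57	C57BL/6J	2	Male	Pancreas	1	91,983,866	89,773,673	819,185	65,257,644	70.94	17.81	54,658
ATAC-58	C57BL/6J	2	Male	Pancreas	2	238,980,976	232,982,918	3,255,911	162,801,402	68.12	16.01	54,658
ATAC-59	C57BL/6J	2	Male	Skeletal muscle	1	117,557,552	115,960,450	1,920,255	44,835,398	38.14	6.32	14,722
ATAC-60	C57BL/6J	2	Male	Skeletal muscle	2	214,824,060	211,626,739	2,469,962	42,681,444	19.87	9.52	14,722
ATAC-61	C57BL/6J	2	Male	Spleen	1	96,385,558	95,252,958	708,544	63,986,222	66.39	11.09	21,189
ATAC-62	C57BL/6J	2	Male	Spleen	2	99,268,666	98,104,994	736,929	67,856,328	68.36	11.95	21,189
ATAC-63	C57BL/6J	2	Male	Stomach	1	146,138,130	144,325,578	1,901,264	96,815,264	66.25	10.05	34,443
ATAC-64	C57BL/6J	2	Male	Stomach	2	53,691,468	52,961,106	1,045,366	37,522,232	69.88	13.43	34,443
ATAC-65	C57BL/6J	2	Male	Thymus	1	108,290,790	106,397,126	1,095,779	78,782,088	72.75	14.54	42,037
ATAC-66	C57BL/6J	2	Male	Thymus	2	131,298,716	128,823,646	1,286,797	93,295,128	71.06	14.16	42,037
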