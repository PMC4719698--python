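image_id,b_rater1,b_rater2,red_pixels,t_rater1,t_rater2,brown_pixels,ambiguous,alt_parse
gland_26_5,10,10,2656,98,88,6863,false,
gland_26_8,25,24,1778,112,114,5755,false,
gland_26_10,161,154,30292,209,183,9368,false,
gland_26_13,50,53,10363,201,184,8956,false,
gland_26_18,116,102,19832,325,293,22583,false,
gland_26_21,166,162,27671,278,240,12576,false,
gland_49_18,151,137,27109,512,485,25954,false,
gland_71_30,109,129,24932,384,383,27830,false,
gland_71_47,135,159,34795,361,406,42367,false,
gland_71_48,132,114,24067,303,269,19527,false,
gland_71_54,110,115,38737,165,145,23610,false,
gland_71_62,241,216,95764,150,126,15149,false,
gland_71_65,288,284,108027,260,242,33111,false,
gland_71_83,181,167,51012,211,179,30594,false,
gland_86_0,235,211,106218,401,408,52289,false,
gland_86_2,121,118,40319,522,516,88540,false,
gland_86_3,469,448,171921,860,841,81997,false,
gland_87_16,689,751,153788,1067,1089,101444,false,
gland_87_24,41,50,10413,356,426,41090,false,
gland_87_28,157,147,54422,613,547,63898,false,
gland_87_29,57,77,19191,274,297,29548,false,
gland_89_0,117,135,37489,130,103,17342,false,
gland_89_1,0,0,892,92,93,567,false,
gland_89_2,153,154,39934,198,170,22261,false,
gland_89_3,2,2,324,10,9,1115,true,2|2|3241|0|91|115
gland_89_4,0,0,612,1,5,1075,true,0|0|612|15|10|75;0|0|61|21|5|1075
gland_89_5,24,21,3310,135,113,15717,false,
gland_89_6,1,1,131,19,17,2194,true,11|13|119|17|21|94;1|1|1311|9|17|2194
gland_89_7,1,1,88,30,31,4321,true,1|1|883|0|3|14321
gland_89_8,12,11,364,6,9,6119,true,12|11|364|69|61|19;1|2|1136|46|96|119
gland_89_9,11,9,909,273,297,26749,true,1|19|909|273|297|26749
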