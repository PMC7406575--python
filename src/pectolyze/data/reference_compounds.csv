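# Reference inventory of unsaturated pectic oligosaccharides observed in
# pectin lyase digests of apple, citrus and sugar beet pectin (positive-mode
# ammonium adducts).  Printed cells are preserved verbatim; three rows carry
# internally inconsistent cells (see composition.KNOWN_INCONSISTENCIES).
# An asterisk in the source labels (positive_only=1) marks compounds seen in
# positive mode only.
name,mw,gala,methyl,acetyl,charge,observed_mz,positive_only
gA_2_m_1,366,2,1,0,1,384,0
gA_2_m_1_a_1,408,2,1,1,1,426,0
gA_2_m_2_a_1,422,2,2,1,1,440,1
gA_3_m_1 #1,542,3,1,0,1,560,0
gA_3_m_1 #2,542,3,1,0,1,560,0
gA_3_m_2 #1,556,3,2,0,1,574,0
gA_3_m_2 #2,556,3,2,0,1,574,0
gA_3_m_2_a_1 #1,598,3,2,1,1,616,0
gA_3_m_2_a_1 #2,598,3,2,1,1,616,0
gA_3_m_2_a_2,640,3,2,2,1,658,0
gA_3_m_3,570,3,3,0,1,588,0
gA_3_m_3_a_1,612,3,3,1,1,630,1
gA_3_m_3_a_2,654,3,3,2,1,672,1
gA_4_m_2 #1,732,4,2,0,1,750,0
gA_4_m_2 #2,732,4,2,0,1,750,0
gA_4_m_2_a_1,774,4,2,1,1,792,0
gA_4_m_2_a_2,816,4,2,2,1,834,0
gA_4_m_3,746,4,3,0,1,746,0
gA_4_m_3_a_1 #1,788,4,3,1,1,806,0
gA_4_m_3_a_1 #2,788,4,3,1,1,806,0
gA_4_m_3_a_2,830,4,3,2,1,848,0
gA_4_m_4,760,4,4,0,1,778,0
gA_4_m_4_a_1 #1,802,4,4,1,1,820,1
gA_4_m_4_a_1 #2,802,4,4,1,1,820,1
gA_4_m_4_a_2,844,4,4,2,1,862,1
gA_5_m_3,922,5,3,0,2,479,0
gA_5_m_3_a_1,964,5,3,1,1/2,982/500,0
gA_5_m_3_a_2,1006,5,3,2,2,521,0
gA_5_m_4,936,5,4,0,1/2,954/486,0
gA_5_m_4_a_1,978,5,4,1,2,507,0
gA_5_m_4_a_2,1020,5,4,2,2,528,0
gA_5_m_5,950,5,5,0,1/2,968/493,1
gA_5_m_5_a_1,992,5,5,1,2,514,1
gA_6_m_3,1098,6,3,0,2,567,0
gA_6_m_4,1112,6,4,0,2,574,0
gA_6_m_4_a_1,1154,6,4,1,2,595,0
gA_6_m_4_a_2,1196,6,4,2,2,616,1
gA_6_m_5,1126,6,5,0,2,581,0
gA_6_m_5_a_1,1168,6,5,1,2,602,1
gA_6_m_5_a_2,1210,6,5,2,2,623,1
gA_6_m_6,1140,6,6,0,2,588,1
gA_7_m_4,1288,7,4,0,2,662,0
gA_7_m_5,1302,7,5,0,2,669,0
gA_7_m_6,1335,7,6,0,2,676,1
gA_7_m_6_a_1,1358,7,6,1,2,697,0
gA_7_m_7,1330,7,7,0,2,683,1
gA_8_m_6,1492,8,6,0,2,764,0
gA_8_m_7,1506,9,6,0,2,771,1
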