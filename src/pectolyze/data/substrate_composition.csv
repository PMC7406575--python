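# Average monosaccharide composition (umol per g pectin dry matter) and
# degrees of acetylation/methoxylation of the three commercial pectins.
source,fuc,ara,rha,gal,glc,xyl,man,gala,glca,dac,dm
apple,6,157,110,281,237,51,5,3875,8,2,69
citrus,4,98,152,478,71,15,4,4195,5,1,53
sugarbeet,5,512,264,532,30,11,3,2940,33,19,56
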